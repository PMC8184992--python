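"""Gene-level allelic count tables: I/O, validation, aggregation, resampling.

The basic observation unit is a table with one row per gene carrying the
number of reads assigned to the maternal and paternal haplotype of that
gene in one sequencing library.  Allelic imbalance (AI) of a gene is the
maternal fraction M / (M + P).  All downstream noise estimation operates
on aligned sets of such tables, one per technical replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_COL = "gene_id"
MAT_COL = "maternal_count"
PAT_COL = "paternal_count"
SNP_COL = "snp_id"

_COUNT_COLS = (MAT_COL, PAT_COL)


class SchemaError(ValueError):
    """Input table violates the expected column/uniqueness schema."""


class UndefinedAIError(ValueError):
    """AI requested for a gene with zero total allelic coverage."""


def _validate_counts(table: pd.DataFrame, *, context: str = "table") -> pd.DataFrame:
    missing = [c for c in (GENE_COL, MAT_COL, PAT_COL) if c not in table.columns]
    if missing:
        raise SchemaError(f"{context}: missing required column(s) {missing}")
    out = table.copy()
    for col in _COUNT_COLS:
        vals = out[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            raise ValueError(f"{context}: non-numeric values in {col!r}")
        if not np.allclose(numeric, np.round(numeric)):
            raise ValueError(f"{context}: non-integer counts in {col!r}")
        if (numeric < 0).any():
            raise ValueError(f"{context}: negative counts in {col!r}")
        out[col] = numeric.astype(np.int64)
    if out[GENE_COL].isna().any() or (out[GENE_COL].astype(str) == "").any():
        raise SchemaError(f"{context}: empty gene_id")
    return out


def validate_gene_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-level count table; returns a normalized copy.

    Requires unique gene identifiers and non-negative integer counts.
    """
    out = _validate_counts(table, context="gene counts")
    dup = out[GENE_COL].duplicated()
    if dup.any():
        raise SchemaError(
            f"gene counts: duplicated gene_id(s): {sorted(out.loc[dup, GENE_COL].unique())[:5]}"
        )
    return out.reset_index(drop=True)[[GENE_COL, MAT_COL, PAT_COL]]


def read_gene_counts(path, *, gene_col: str = GENE_COL, maternal_col: str = MAT_COL,
                     paternal_col: str = PAT_COL) -> pd.DataFrame:
    """Read a tab-separated gene-level allelic count table.

    Expected columns (header names configurable): gene identifier,
    maternal count, paternal count.
    """
    raw = pd.read_csv(path, sep="\t", dtype={gene_col: str})
    rename = {gene_col: GENE_COL, maternal_col: MAT_COL, paternal_col: PAT_COL}
    missing = [c for c in rename if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(raw.columns)}")
    return validate_gene_counts(raw.rename(columns=rename))


def write_gene_counts(table: pd.DataFrame, path) -> None:
    table[[GENE_COL, MAT_COL, PAT_COL]].to_csv(path, sep="\t", index=False)


def read_snp_counts(path, *, snp_col: str = SNP_COL, gene_col: str = GENE_COL,
                    maternal_col: str = MAT_COL, paternal_col: str = PAT_COL) -> pd.DataFrame:
    """Read a SNP-level allelic count table (snp_id, gene_id, counts)."""
    raw = pd.read_csv(path, sep="\t", dtype={snp_col: str, gene_col: str})
    rename = {snp_col: SNP_COL, gene_col: GENE_COL,
              maternal_col: MAT_COL, paternal_col: PAT_COL}
    missing = [c for c in rename if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = _validate_counts(raw.rename(columns=rename), context="snp counts")
    return out.reset_index(drop=True)[[SNP_COL, GENE_COL, MAT_COL, PAT_COL]]


def aggregate_snp_to_gene(snp_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum phased SNP-level allelic counts over the gene model.

    Per gene: M_g = sum of maternal SNP counts, and the total
    C_g = sum over SNPs of maternal + paternal counts.
    """
    tab = _validate_counts(snp_counts, context="snp counts")
    if tab.empty:
        return pd.DataFrame({GENE_COL: pd.Series(dtype=str),
                             MAT_COL: pd.Series(dtype=np.int64),
                             PAT_COL: pd.Series(dtype=np.int64)})
    agg = (tab.groupby(GENE_COL, sort=True)[[MAT_COL, PAT_COL]]
           .sum().reset_index())
    return agg


def total_counts(table: pd.DataFrame) -> pd.Series:
    """Per-gene total allelic coverage C_g = M_g + P_g."""
    return table[MAT_COL] + table[PAT_COL]


def filter_min_coverage(table: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes with total allelic coverage >= ``min_total`` (default 10)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = total_counts(table) >= min_total
    return table.loc[keep].reset_index(drop=True)


def compute_ai(table: pd.DataFrame) -> pd.Series:
    """Allelic imbalance point estimate AI_g = M_g / C_g per gene.

    Raises :class:`UndefinedAIError` if any gene has zero total coverage;
    filter on coverage first.
    """
    tot = total_counts(table)
    if (tot == 0).any():
        raise UndefinedAIError("AI undefined for genes with zero total coverage")
    return table[MAT_COL] / tot


def split_half_replicates(table: pd.DataFrame, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split each gene's reads into two equal halves without replacement.

    Emulates randomly dividing the reads of one library into two
    half-replicates: of the C_g reads (M_g maternal), floor(C_g/2) are
    drawn hypergeometrically into half 1 and the remainder go to half 2.
    Per-allele totals are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    m = table[MAT_COL].to_numpy()
    p = table[PAT_COL].to_numpy()
    tot = m + p
    n_draw = tot // 2
    m1 = rng.hypergeometric(np.maximum(m, 0), np.maximum(p, 0), n_draw)
    # hypergeometric with ngood+nbad==0 is invalid; zero-coverage genes stay zero
    zero = tot == 0
    if zero.any():
        m1 = np.where(zero, 0, m1)
    p1 = n_draw - m1
    half1 = table.copy()
    half2 = table.copy()
    half1[MAT_COL], half1[PAT_COL] = m1, p1
    half2[MAT_COL], half2[PAT_COL] = m - m1, p - p1
    return half1, half2


def subsample_counts(table: pd.DataFrame, fraction: float, seed) -> pd.DataFrame:
    """Binomially thin each allele count with retention probability ``fraction``."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    out[MAT_COL] = rng.binomial(table[MAT_COL].to_numpy(), fraction)
    out[PAT_COL] = rng.binomial(table[PAT_COL].to_numpy(), fraction)
    return out


@dataclass
class ReplicateSet:
    """Aligned gene-level count tables for M >= 1 technical replicates.

    All tables share the same ordered gene universe; genes absent from a
    replicate are represented with zero counts so that pooling and pairwise
    comparison are always defined.
    """

    replicates: list[pd.DataFrame]
    gene_ids: pd.Index = field(init=False)

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError("ReplicateSet requires at least one replicate")
        ref = self.replicates[0][GENE_COL]
        for rep in self.replicates[1:]:
            if not rep[GENE_COL].equals(ref):
                raise ValueError("replicates not aligned on the same gene universe; "
                                 "use align_replicates()")
        self.gene_ids = pd.Index(ref)

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)

    def __getitem__(self, i) -> pd.DataFrame:
        return self.replicates[i]

    def pooled(self) -> pd.DataFrame:
        """Per-gene sum of counts over all replicates."""
        out = self.replicates[0][[GENE_COL]].copy()
        out[MAT_COL] = sum(r[MAT_COL].to_numpy() for r in self.replicates)
        out[PAT_COL] = sum(r[PAT_COL].to_numpy() for r in self.replicates)
        return out

    def totals(self) -> np.ndarray:
        """Library sizes (sum of allelic counts) per replicate."""
        return np.array([int(total_counts(r).sum()) for r in self.replicates])


def align_replicates(tables: Sequence[pd.DataFrame]) -> ReplicateSet:
    """Align count tables on the union of gene identifiers (zero-filling)."""
    tables = [validate_gene_counts(t) for t in tables]
    universe: pd.Index = pd.Index([])
    for t in tables:
        universe = universe.union(pd.Index(t[GENE_COL]), sort=False)
    universe = universe.sort_values()
    aligned = []
    for t in tables:
        a = (t.set_index(GENE_COL)
             .reindex(universe, fill_value=0)
             .reset_index(names=GENE_COL))
        a[MAT_COL] = a[MAT_COL].astype(np.int64)
        a[PAT_COL] = a[PAT_COL].astype(np.int64)
        aligned.append(a)
    return ReplicateSet(aligned)


def depth_match(replicates: ReplicateSet, seed) -> ReplicateSet:
    """Thin all replicates to the depth of the smallest library.

    Noise calibration compares replicates at equal depth; each larger
    library is binomially thinned so its expected total matches the
    smallest library's total.
    """
    totals = replicates.totals()
    target = totals.min()
    rng = np.random.default_rng(seed)
    out = []
    for rep, tot in zip(replicates, totals):
        if tot <= target:
            out.append(rep.copy())
        else:
            out.append(subsample_counts(rep, target / tot, rng.integers(2**31)))
    return ReplicateSet(out)
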