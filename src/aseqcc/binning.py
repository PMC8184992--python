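"""Geometric coverage binning for the discretized allelic-imbalance model.

Genes are grouped into narrow coverage bins so that within a bin the
binomial sampling noise of AI estimates is approximately homogeneous.
Bin boundaries are rounded-up powers of a base b (default 1.05); each
gene is assigned by the mean of its total counts in the two replicates
to the half-open interval (C_{i-1}, C_i].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import GENE_COL, total_counts


@dataclass
class CoverageBinning:
    """Bin boundaries, per-gene bin assignment, and geometric bin centers.

    Attributes
    ----------
    base : the geometric base b > 1.
    boundaries : strictly increasing integer boundaries ceil(b^k), with
        consecutive duplicates collapsed; boundaries[0] is the lower edge
        of the first bin.
    assignment : integer bin index per gene (aligned with the input
        tables), -1 for genes outside the binned range.
    centers : geometric centers sqrt(C_{i-1} * C_i) per bin.
    """

    base: float
    boundaries: np.ndarray
    assignment: np.ndarray
    mean_coverage: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.boundaries[:-1].astype(float) * self.boundaries[1:])

    def bin_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.n_bins, dtype=int)
        inside = self.assignment >= 0
        idx, cnt = np.unique(self.assignment[inside], return_counts=True)
        sizes[idx] = cnt
        return sizes

    def genes_in_bin(self, i: int) -> np.ndarray:
        """Positional indices of genes assigned to bin i."""
        return np.nonzero(self.assignment == i)[0]


def geometric_boundaries(base: float, max_coverage: float) -> np.ndarray:
    """Boundary sequence {ceil(b^k)} k=0,1,2,... up to max_coverage, deduplicated."""
    if base <= 1:
        raise ValueError("bin base must be > 1")
    bounds = []
    k = 0
    while True:
        c = int(np.ceil(base ** k))
        if not bounds or c > bounds[-1]:
            bounds.append(c)
        if c > max_coverage:
            break
        k += 1
        if k > 10_000:  # base barely above 1 with huge coverage; give up
            raise ValueError("bin base too close to 1 for this coverage range")
    return np.asarray(bounds, dtype=np.int64)


def assign_bins(rep1: pd.DataFrame, rep2: pd.DataFrame, base: float = 1.05) -> CoverageBinning:
    """Assign each gene to a coverage bin by its mean total count.

    Gene g with (C_1g + C_2g)/2 in (C_{i-1}, C_i] goes to bin i
    (upper-inclusive).  Genes with mean coverage <= boundaries[0] or
    above the last boundary get assignment -1.
    """
    if not rep1[GENE_COL].equals(rep2[GENE_COL]):
        raise ValueError("replicate tables must be aligned on the same gene universe")
    mean_cov = (total_counts(rep1).to_numpy() + total_counts(rep2).to_numpy()) / 2.0
    max_cov = mean_cov.max() if len(mean_cov) else 1.0
    bounds = geometric_boundaries(base, max_cov)
    # np.searchsorted with side='left' on the upper edges gives the
    # upper-inclusive convention: mean == C_i maps to bin i.
    idx = np.searchsorted(bounds[1:], mean_cov, side="left")
    assignment = idx.astype(np.int64)
    outside = (mean_cov <= bounds[0]) | (mean_cov > bounds[-1])
    assignment[outside] = -1
    return CoverageBinning(base=base, boundaries=bounds,
                           assignment=assignment, mean_coverage=mean_cov)
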