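"""Quality Correction Coefficient (QCC) estimation from replicate libraries.

The QCC quantifies how much wider the observed between-replicate AI
differences (dAI) are than the purely binomial expectation.  Per
coverage bin, quantiles of the observed |dAI| distribution are compared
with quantiles of a simulated binomial expectation under the fitted
beta-binomial mixture; the ratio observed/expected is approximately
constant across bins and quantile levels, and its constant (least
squares, i.e. mean) fit is the QCC.  QCC = 1 means purely binomial
noise; real libraries typically show QCC > 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import counts as cnt
from .binning import CoverageBinning, assign_bins
from .em import MixtureFit, fit_mixture_em

logger = logging.getLogger(__name__)

DEFAULT_QUANTILES = (0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.95)


class EstimationError(RuntimeError):
    """Raised when the data do not support a QCC estimate."""


@dataclass
class QCCConfig:
    """Tuning knobs of the QCC pipeline.

    bin_base : geometric base of the coverage bins.
    quantiles : quantile levels at which observed and expected |dAI|
        are compared.
    min_fit_coverage : minimal pooled (two-replicate) total count for a
        gene to enter the mixture fit and quantile comparison; 50 is a
        practical default for mouse crosses (30 suits typical human
        heterozygosity).
    min_bin_genes : minimal number of genes per retained bin.
    n_sim : simulated genes per bin for the expected-dAI distribution.
    min_ratio_pairs : minimal number of (bin, quantile) ratios required
        for the constant fit.
    depth_match : thin the deeper replicate so both libraries have the
        same expected total before comparison.
    """

    bin_base: float = 1.05
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    min_fit_coverage: int = 50
    min_bin_genes: int = 40
    n_sim: int = 5000
    min_ratio_pairs: int = 5
    em_tol: float = 1e-6
    em_max_iter: int = 10_000
    depth_match: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.bin_base <= 1:
            raise ValueError("bin_base must be > 1")
        q = np.asarray(self.quantiles, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "bin_base": self.bin_base,
            "quantiles": list(self.quantiles),
            "min_fit_coverage": self.min_fit_coverage,
            "min_bin_genes": self.min_bin_genes,
            "n_sim": self.n_sim,
            "min_ratio_pairs": self.min_ratio_pairs,
            "em_tol": self.em_tol,
            "em_max_iter": self.em_max_iter,
            "depth_match": self.depth_match,
            "seed": self.seed,
        }


@dataclass
class QCCEstimate:
    """A fitted QCC with its per-(bin, quantile) diagnostics.

    ratio_table has one row per retained (bin, quantile) pair with the
    observed and expected |dAI| quantiles and their ratio; qcc is the
    mean ratio.  For multi-replicate estimates, pairwise holds the
    per-pair values and qcc their mean.
    """

    qcc: float
    ratio_table: pd.DataFrame
    config: QCCConfig
    pairwise: pd.DataFrame | None = None
    mixture: MixtureFit | None = field(default=None, repr=False)
    binning: CoverageBinning | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {"qcc": self.qcc, "n_ratio_pairs": int(len(self.ratio_table)),
               "config": self.config.to_dict()}
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def _retained_bins(binning: CoverageBinning, pooled_total: np.ndarray,
                   config: QCCConfig) -> dict[int, np.ndarray]:
    """Gene indices per bin after the fit-coverage and bin-size filters."""
    ok_gene = pooled_total >= config.min_fit_coverage
    retained = {}
    for i in range(binning.n_bins):
        idx = binning.genes_in_bin(i)
        idx = idx[ok_gene[idx]]
        if len(idx) >= config.min_bin_genes:
            retained[i] = idx
        elif len(idx) > 0:
            logger.debug("bin %d dropped: %d genes < %d", i, len(idx), config.min_bin_genes)
    return retained


def observed_delta_ai(rep1: pd.DataFrame, rep2: pd.DataFrame,
                      bins: dict[int, np.ndarray],
                      q_set=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Quantiles of observed |AI_1 - AI_2| per retained coverage bin.

    Genes with zero coverage in either replicate have undefined AI and
    are excluded (logged).
    """
    q = np.asarray(q_set, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    t1 = cnt.total_counts(rep1).to_numpy()
    t2 = cnt.total_counts(rep2).to_numpy()
    m1 = rep1[cnt.MAT_COL].to_numpy()
    m2 = rep2[cnt.MAT_COL].to_numpy()
    rows = []
    for i, idx in bins.items():
        ok = (t1[idx] > 0) & (t2[idx] > 0)
        if not ok.all():
            logger.debug("bin %d: %d genes with zero coverage in one replicate excluded",
                         i, int((~ok).sum()))
        sel = idx[ok]
        dai = np.abs(m1[sel] / t1[sel] - m2[sel] / t2[sel])
        qs = np.quantile(dai, q)
        for lvl, val in zip(q, qs):
            rows.append({"bin_index": i, "q": lvl, "Q_obs": val})
    return pd.DataFrame(rows)


def expected_delta_ai(fit: MixtureFit, bins: dict[int, np.ndarray],
                      centers: np.ndarray, n_sim: int = 5000,
                      q_set=DEFAULT_QUANTILES, seed=0) -> pd.DataFrame:
    """Quantiles of simulated binomial |dAI| under the fitted mixture.

    Per bin: draw n_sim true proportions from the fitted two-component
    symmetric Beta mixture, then two replicate AI values from
    Binomial(C, p)/C at the bin center C; report quantiles of the
    absolute difference.
    """
    q = np.asarray(q_set, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for i in sorted(bins):
        if i not in fit:
            continue
        bf = fit[i]
        c_int = max(int(round(centers[i])), 1)
        comp = rng.random(n_sim) < bf.w1
        p = np.where(comp,
                     rng.beta(bf.a1, bf.a1, size=n_sim),
                     rng.beta(bf.a2, bf.a2, size=n_sim))
        xi1 = rng.binomial(c_int, p) / c_int
        xi2 = rng.binomial(c_int, p) / c_int
        qs = np.quantile(np.abs(xi1 - xi2), q)
        for lvl, val in zip(q, qs):
            rows.append({"bin_index": i, "q": lvl, "Q_exp": val})
    return pd.DataFrame(rows)


def fit_qcc_constant(ratio_table: pd.DataFrame, min_ratio_pairs: int = 5) -> float:
    """Constant least-squares fit (the mean) of the quantile ratios."""
    ratios = ratio_table["ratio"].to_numpy()
    if len(ratios) < min_ratio_pairs:
        raise EstimationError(
            f"insufficient data for QCC: {len(ratios)} (bin, quantile) ratios "
            f"< required {min_ratio_pairs}")
    return float(np.mean(ratios))


def estimate_qcc_pair(rep1: pd.DataFrame, rep2: pd.DataFrame,
                      config: QCCConfig | None = None) -> QCCEstimate:
    """Estimate QCC from one pair of replicate count tables.

    Pipeline: optional depth matching -> coverage binning of mean counts
    -> beta-binomial mixture EM on pooled AI per bin -> observed vs
    simulated-expected |dAI| quantiles -> constant fit of their ratios.
    """
    config = config or QCCConfig()
    if not rep1[cnt.GENE_COL].equals(rep2[cnt.GENE_COL]):
        rs = cnt.align_replicates([rep1, rep2])
        rep1, rep2 = rs[0], rs[1]
    if config.depth_match:
        rs = cnt.depth_match(cnt.ReplicateSet([rep1, rep2]), seed=config.seed)
        rep1, rep2 = rs[0], rs[1]

    binning = assign_bins(rep1, rep2, base=config.bin_base)
    pooled_m = rep1[cnt.MAT_COL].to_numpy() + rep2[cnt.MAT_COL].to_numpy()
    pooled_t = (cnt.total_counts(rep1).to_numpy() + cnt.total_counts(rep2).to_numpy())
    bins = _retained_bins(binning, pooled_t, config)
    if not bins:
        raise EstimationError("insufficient data for QCC: no coverage bin retained")

    centers = binning.centers
    pooled_ai = {i: pooled_m[idx] / pooled_t[idx] for i, idx in bins.items()}
    fit = fit_mixture_em(pooled_ai, {i: centers[i] for i in bins},
                         tol=config.em_tol, max_iter=config.em_max_iter)

    obs = observed_delta_ai(rep1, rep2, bins, q_set=config.quantiles)
    exp = expected_delta_ai(fit, bins, centers, n_sim=config.n_sim,
                            q_set=config.quantiles, seed=config.seed)
    table = obs.merge(exp, on=["bin_index", "q"])
    table["C_hat"] = centers[table["bin_index"].to_numpy()]
    zero = table["Q_exp"] <= 0
    if zero.any():
        logger.debug("%d (bin, q) pairs with zero expected quantile dropped", int(zero.sum()))
    table = table.loc[~zero].reset_index(drop=True)
    table["ratio"] = table["Q_obs"] / table["Q_exp"]
    qcc = fit_qcc_constant(table, config.min_ratio_pairs)
    return QCCEstimate(qcc=qcc, ratio_table=table[["bin_index", "C_hat", "q",
                                                   "Q_obs", "Q_exp", "ratio"]],
                       config=config, mixture=fit, binning=binning)


def estimate_qcc_multi(replicates: cnt.ReplicateSet,
                       config: QCCConfig | None = None,
                       outlier_factor: float = 1.5) -> QCCEstimate:
    """Pairwise QCC over all C(M, 2) replicate pairs and their pooled mean.

    Pairs whose QCC deviates from the median by more than
    ``outlier_factor`` (ratio-wise) are flagged so outlier replicates can
    be excluded and the estimate rerun.
    """
    config = config or QCCConfig()
    m = len(replicates)
    if m < 2:
        raise EstimationError("QCC requires at least two replicates")
    rows = []
    tables = []
    for i, j in itertools.combinations(range(m), 2):
        est = estimate_qcc_pair(replicates[i], replicates[j], config)
        rows.append({"rep_i": i, "rep_j": j, "qcc": est.qcc})
        t = est.ratio_table.copy()
        t["rep_i"], t["rep_j"] = i, j
        tables.append(t)
    pairwise = pd.DataFrame(rows)
    med = pairwise["qcc"].median()
    pairwise["outlier"] = ((pairwise["qcc"] > med * outlier_factor)
                           | (pairwise["qcc"] < med / outlier_factor))
    pooled = float(pairwise["qcc"].mean())
    return QCCEstimate(qcc=pooled, ratio_table=pd.concat(tables, ignore_index=True),
                       config=config, pairwise=pairwise)


@dataclass
class AbundanceOverdispersionFit:
    """Log-linear fit of count dispersion vs mean expression.

    Dispersion is the per-gene variance/mean ratio of total allelic
    counts across replicates; under Poisson sampling it is 1 at all
    expression levels.  overdispersion = exp(intercept) of the
    regression of log dispersion on log mean.
    """

    slope: float
    intercept: float
    overdispersion: float
    n_genes: int
    table: pd.DataFrame = field(repr=False)


def abundance_overdispersion(replicates: cnt.ReplicateSet,
                             n_bins: int = 25,
                             qcc: float = 1.0) -> AbundanceOverdispersionFit:
    """Measure extra-Poisson dispersion of total counts across replicates.

    Per gene, the mean and variance of total counts over the M >= 2
    replicates are computed; genes are grouped into geometric bins of the
    mean and the mean dispersion (variance/mean) per bin is regressed
    log-log on the bin's mean expression.  Binning before taking logs
    avoids the Jensen bias of per-gene log dispersion at small M.
    Passing a QCC divides each gene's dispersion by QCC^2 first (used to
    check that QCC accounts for the abundance overdispersion).
    """
    if len(replicates) < 2:
        raise ValueError("abundance overdispersion requires >= 2 replicates")
    totals = np.column_stack([cnt.total_counts(r).to_numpy() for r in replicates])
    mean = totals.mean(axis=1)
    var = totals.var(axis=1, ddof=1) / qcc**2
    ok = mean > 0
    mean, var = mean[ok], var[ok]
    if len(mean) < 2 or np.allclose(var, 0):
        raise EstimationError("degenerate fit: no variation of totals across replicates")
    edges = np.geomspace(mean.min(), mean.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 3:
            continue
        disp = var[sel].mean() / mean[sel].mean()
        if disp > 0:
            rows.append({"mean": mean[sel].mean(), "dispersion": disp,
                         "n_genes": int(sel.sum())})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise EstimationError("degenerate fit: too few informative expression bins")
    # weight bins by occupancy: sparse edge bins carry very noisy
    # dispersion estimates and sit closest to the mean=1 intercept
    slope, intercept = np.polyfit(np.log(table["mean"]), np.log(table["dispersion"]),
                                  deg=1, w=np.sqrt(table["n_genes"]))
    return AbundanceOverdispersionFit(slope=float(slope),
                                      intercept=float(intercept),
                                      overdispersion=float(np.exp(intercept)),
                                      n_genes=int(table["n_genes"].sum()),
                                      table=table)
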