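"""QCC-corrected confidence intervals and hypothesis tests for allelic imbalance.

The correction treats a gene's AI estimate as if it came from QCC^2
times fewer reads: both the maternal and the total count are divided by
QCC^2 before a one- or two-sample proportion test.  The scaled counts
are generally non-integer, so the tests are the chi-square score test
with Yates continuity correction and the Wilson score interval, both of
which are algebraically well-defined for real-valued counts (and agree
with the conventional proportion test on integers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import counts as cnt
from .counts import ReplicateSet

BIASED_MATERNAL = "biased_maternal"
BIASED_PATERNAL = "biased_paternal"
UNBIASED = "unbiased"


def _z_quantile(conf: float) -> float:
    if not (0 < conf < 1):
        raise ValueError("confidence level must be in (0, 1)")
    return stats.norm.ppf((1 + conf) / 2)


def wilson_interval(x, n, conf: float = 0.95, correct: bool = True,
                    null_p=None):
    """Wilson score interval for x successes of n trials (real-valued allowed).

    With ``correct`` the Yates continuity correction 0.5 is applied,
    clamped to the deviation |x - n*null_p| when a null proportion is
    given — the exact behavior of the conventional proportion test,
    whose continuity correction never exceeds the tested deviation.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("total must be > 0")
    z = _z_quantile(conf)
    p_hat = x / n
    if not correct:
        yates = 0.0
    elif null_p is None:
        yates = 0.5
    else:
        yates = np.minimum(0.5, np.abs(x - n * np.asarray(null_p, dtype=float)))
    z22n = z**2 / (2 * n)
    p_c = p_hat + yates / n
    upper = np.where(p_c >= 1, 1.0,
                     (p_c + z22n + z * np.sqrt(p_c * (1 - p_c) / n + z22n / (2 * n)))
                     / (1 + 2 * z22n))
    p_c = p_hat - yates / n
    lower = np.where(p_c <= 0, 0.0,
                     (p_c + z22n - z * np.sqrt(p_c * (1 - p_c) / n + z22n / (2 * n)))
                     / (1 + 2 * z22n))
    return np.clip(lower, 0, 1), np.clip(upper, 0, 1)


def score_test_pvalue(x, n, p0, correct: bool = True):
    """Two-sided chi-square score test of a proportion against p0.

    Continuity-corrected statistic (|x - n p0| - min(0.5, |x - n p0|))^2
    summed over the two cells, referred to chi-square with 1 df.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), x.shape) if x.shape else np.asarray(p0, float)
    dev = np.abs(x - n * p0)
    yates = np.minimum(0.5, dev) if correct else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = (dev - yates) ** 2 / (n * p0) + (dev - yates) ** 2 / (n * (1 - p0))
    return stats.chi2.sf(statistic, df=1)


def corrected_proportion_test(maternal, total, qcc: float, null_ai=0.5,
                              conf: float = 0.95, correct: bool = True):
    """QCC-corrected one-sample proportion test for allelic imbalance.

    Both counts are divided by QCC^2 (effective coverage) before testing
    maternal/total against ``null_ai`` and building the Wilson interval.
    At QCC = 1 this is exactly the uncorrected proportion test.

    Returns (p_value, ci_low, ci_high); all three broadcast over arrays.
    """
    maternal = np.asarray(maternal, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total must be > 0; filter zero-coverage genes first")
    if qcc <= 0:
        raise ValueError("qcc must be > 0")
    if qcc < 1:
        warnings.warn("QCC < 1 implies sub-binomial noise; proceeding, but the "
                      "estimate is likely unreliable", stacklevel=2)
    x = maternal / qcc**2
    n = total / qcc**2
    p = score_test_pvalue(x, n, null_ai, correct=correct)
    lo, hi = wilson_interval(x, n, conf=conf, correct=correct, null_p=null_ai)
    return p, lo, hi


def two_sample_proportion_test(x1, n1, x2, n2, correct: bool = True):
    """Two-sided two-sample proportion test (2x2 chi-square with Yates).

    Accepts real-valued counts; symmetric in the two samples.
    """
    x1, n1, x2, n2 = (np.asarray(v, dtype=float) for v in (x1, n1, x2, n2))
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("totals must be > 0")
    # expected cell counts of the 2x2 table under homogeneity
    tot = n1 + n2
    col1 = x1 + x2
    e11 = n1 * col1 / tot
    dev = np.abs(x1 - e11)  # all four cells deviate by the same amount
    yates = np.minimum(0.5, dev) if correct else 0.0
    e12 = n1 - e11
    e21 = n2 * col1 / tot
    e22 = n2 - e21
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = (dev - yates) ** 2 * (1 / e11 + 1 / e12 + 1 / e21 + 1 / e22)
    return stats.chi2.sf(statistic, df=1)


def _n_tested_threshold(p_raw: np.ndarray, alpha: float, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return p_raw < alpha / len(p_raw)
    if correction == "fdr_bh":
        order = np.argsort(p_raw)
        m = len(p_raw)
        ranked = p_raw[order] * m / np.arange(1, m + 1)
        passed = np.zeros(m, dtype=bool)
        below = np.nonzero(ranked <= alpha)[0]
        if len(below):
            passed[order[: below[-1] + 1]] = True
        return passed
    if correction == "none":
        return p_raw < alpha
    raise ValueError(f"unknown correction {correction!r}")


def test_point_ai(replicates: ReplicateSet, qcc: float, null_ai=0.5,
                  alpha: float = 0.05, correction: str = "bonferroni",
                  min_total: int = 10, conf: float = 0.95,
                  correct: bool = True) -> pd.DataFrame:
    """Per-gene test of AI against a null value, with QCC-corrected CIs.

    Replicates are pooled for the point estimates; genes with pooled
    total below ``min_total`` are not tested.  ``null_ai`` may be a
    scalar or a per-gene mapping (dict / Series keyed by gene_id).
    Multiple testing over all tested genes (Bonferroni by default).
    """
    pooled = cnt.filter_min_coverage(replicates.pooled(), min_total)
    if pooled.empty:
        return pd.DataFrame(columns=["gene_id", "maternal", "total", "ai", "null_ai",
                                     "effective_total", "ci_low", "ci_high",
                                     "p_value", "significant"])
    m = pooled[cnt.MAT_COL].to_numpy(dtype=float)
    t = cnt.total_counts(pooled).to_numpy(dtype=float)
    ai = m / t
    if isinstance(null_ai, (dict, pd.Series)):
        null_vec = pooled[cnt.GENE_COL].map(null_ai).to_numpy(dtype=float)
        if np.isnan(null_vec).any():
            raise ValueError("per-gene null_ai missing for some tested genes")
    else:
        null_vec = np.full(len(pooled), float(null_ai))
    p, lo, hi = corrected_proportion_test(m, t, qcc, null_ai=null_vec,
                                          conf=conf, correct=correct)
    sig = _n_tested_threshold(p, alpha, correction)
    return pd.DataFrame({
        "gene_id": pooled[cnt.GENE_COL],
        "maternal": m.astype(np.int64),
        "total": t.astype(np.int64),
        "ai": ai,
        "null_ai": null_vec,
        "effective_total": t / qcc**2,
        "ci_low": lo,
        "ci_high": hi,
        "p_value": p,
        "significant": sig,
    })


def test_differential_ai(sample1: ReplicateSet, sample2: ReplicateSet,
                         qcc1: float, qcc2: float, alpha: float = 0.05,
                         correction: str = "bonferroni",
                         min_effect: float | None = None,
                         min_total: int = 10,
                         correct: bool = True) -> pd.DataFrame:
    """Differential AI between two samples, each corrected by its own QCC.

    Per shared gene with sufficient pooled coverage in both samples, a
    two-sample proportion test on the QCC^2-scaled counts; significance
    after multiple-testing correction, optionally also requiring
    |AI_1 - AI_2| >= ``min_effect``.
    """
    if qcc1 is None or qcc2 is None:
        raise ValueError("both samples need a QCC estimate")
    p1 = sample1.pooled()
    p2 = sample2.pooled()
    rs = cnt.align_replicates([p1, p2])
    p1, p2 = rs[0], rs[1]
    t1 = cnt.total_counts(p1).to_numpy(dtype=float)
    t2 = cnt.total_counts(p2).to_numpy(dtype=float)
    keep = (t1 >= min_total) & (t2 >= min_total)
    p1, p2, t1, t2 = p1[keep], p2[keep], t1[keep], t2[keep]
    if not keep.any():
        return pd.DataFrame(columns=["gene_id", "ai_1", "ai_2", "delta_ai",
                                     "p_value", "significant"])
    m1 = p1[cnt.MAT_COL].to_numpy(dtype=float)
    m2 = p2[cnt.MAT_COL].to_numpy(dtype=float)
    ai1, ai2 = m1 / t1, m2 / t2
    p = two_sample_proportion_test(m1 / qcc1**2, t1 / qcc1**2,
                                   m2 / qcc2**2, t2 / qcc2**2, correct=correct)
    sig = _n_tested_threshold(p, alpha, correction)
    if min_effect is not None:
        sig = sig & (np.abs(ai1 - ai2) >= min_effect)
    return pd.DataFrame({
        "gene_id": p1[cnt.GENE_COL].to_numpy(),
        "ai_1": ai1,
        "ai_2": ai2,
        "delta_ai": ai1 - ai2,
        "p_value": p,
        "significant": sig,
    })


def classify_bias(result: pd.DataFrame) -> pd.Series:
    """Label each tested gene as biased toward one allele or unbiased.

    Direction follows the sign of (ai - null_ai) among significant genes.
    """
    direction = np.where(result["ai"].to_numpy() > result["null_ai"].to_numpy(),
                         BIASED_MATERNAL, BIASED_PATERNAL)
    labels = np.where(result["significant"].to_numpy(), direction, UNBIASED)
    return pd.Series(labels, index=result["gene_id"].to_numpy(), name="bias")


@dataclass
class ConcordanceSummary:
    """How bias calls agree between two replicates (or analyses).

    Concordance is the fraction of genes called biased in the same
    direction in both, among genes called biased in at least one.
    """

    n_biased_both: int
    n_biased_only_1: int
    n_biased_only_2: int
    n_opposite_direction: int

    @property
    def n_biased_any(self) -> int:
        return (self.n_biased_both + self.n_biased_only_1
                + self.n_biased_only_2 + self.n_opposite_direction)

    @property
    def concordance(self) -> float:
        any_ = self.n_biased_any
        return self.n_biased_both / any_ if any_ else float("nan")


def concordance(labels_a: pd.Series, labels_b: pd.Series) -> ConcordanceSummary:
    """Summarize agreement of per-gene bias labels over a shared gene set."""
    common = labels_a.index.intersection(labels_b.index)
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    a_biased = a != UNBIASED
    b_biased = b != UNBIASED
    both = a_biased & b_biased
    same = both & (a == b)
    return ConcordanceSummary(
        n_biased_both=int(same.sum()),
        n_biased_only_1=int((a_biased & ~b_biased).sum()),
        n_biased_only_2=int((~a_biased & b_biased).sum()),
        n_opposite_direction=int((both & (a != b)).sum()),
    )
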