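"""EM fitting of a two-component symmetric beta-binomial mixture per coverage bin.

Within a coverage bin with geometric center C, the pooled-replicate AI
values are modeled as a mixture of two symmetric beta-binomial
distributions on support 2C (the pooled coverage):

    a ~ BetaBin(2C, a1, a1) / 2C   with probability w1   (a1 > 1, narrow)
    a ~ BetaBin(2C, a2, a2) / 2C   with probability w2   (a2 in (0,1), wide)

The narrow component captures the near-balanced bulk of genes, the wide
component the strongly imbalanced tail.  Both components are symmetric
around AI = 0.5, so the shape update reduces to matching the weighted
second moment around C, which has a closed form.  The moment update is
accepted whenever it does not lower the observed log-likelihood; when
it would (it is not an exact maximizer of the EM surrogate), the shape
update falls back to direct 1-D maximization of the expected
complete-data log-likelihood, so the log-likelihood trace is
non-decreasing as in a standard EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln

EPS = 1e-6
ALPHA1_CAP = 1e6

# initial values for (w1, a1, a2)
INIT_W1 = 0.5
INIT_A1 = 10.0
INIT_A2 = 1.0 / 50.0


def betabinom_sym_logpmf(x, n: int, alpha) -> np.ndarray:
    """log pmf of the symmetric beta-binomial BetaBin(n, alpha, alpha)."""
    x = np.asarray(x, dtype=float)
    return (gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
            + betaln(x + alpha, n - x + alpha) - betaln(alpha, alpha))


@dataclass
class BinFit:
    """Fitted mixture parameters for one coverage bin."""

    bin_index: int
    center: float          # geometric bin center C
    support: int           # 2C rounded, the beta-binomial support
    n_genes: int
    w1: float
    a1: float
    a2: float
    converged: bool
    degenerate: bool       # a1 hit its cap (zero-variance narrow component)
    n_iter: int
    loglik: np.ndarray = field(repr=False)  # per-iteration log-likelihood


@dataclass
class MixtureFit:
    """Per-bin mixture fits keyed by bin index."""

    fits: dict[int, BinFit]

    def __getitem__(self, i: int) -> BinFit:
        return self.fits[i]

    def __contains__(self, i: int) -> bool:
        return i in self.fits

    @property
    def bin_indices(self) -> list[int]:
        return sorted(self.fits)


def _alpha_from_moment(sigma: float, c_hat: float) -> float:
    """Closed-form shape from the second moment around C.

    For x ~ BetaBin(2C, a, a), Var(x) = C(C + a)/(2a + 1); solving
    Sigma = (4*C*a + (2C)^2) / (8a + 4) for a gives
    a = ((2C)^2 - 4*Sigma) / (8*Sigma - 4*C).
    """
    num = (2 * c_hat) ** 2 - 4 * sigma
    den = 8 * sigma - 4 * c_hat
    if den <= 0:
        # Sigma at or below the binomial floor C/2: zero-width component
        return np.inf if num > 0 else EPS
    return num / den


def _maximize_q_alpha(xu, wts, support, lo, hi, guess):
    """Exact shape M-step: maximize the weighted log-likelihood over alpha."""
    def neg_q(t):
        return -float(np.dot(wts, betabinom_sym_logpmf(xu, support, np.exp(t))))
    res = minimize_scalar(neg_q, bounds=(np.log(lo), np.log(hi)),
                          method="bounded", options={"xatol": 1e-10})
    a = float(np.exp(res.x))
    return a if np.isfinite(a) else guess


def fit_bin_em(ai: np.ndarray, center: float, *, tol: float = 1e-6,
               max_iter: int = 10_000) -> tuple[float, float, float, bool, bool, int, np.ndarray]:
    """Fit (w1, a1, a2) by EM for one bin; returns the trace of the log-likelihood.

    ``ai`` are pooled AI values for the genes in the bin; they are
    converted to integer observations x = round(ai * 2C) on the
    beta-binomial support 2C.
    """
    support = int(round(2 * center))
    c_hat = support / 2.0
    x = np.clip(np.round(np.asarray(ai, dtype=float) * support), 0, support).astype(np.int64)
    # counts collapse to few unique values per bin; evaluate pmfs once per value
    xu, cnt = np.unique(x, return_counts=True)
    n = len(x)

    def loglik_parts(w1, a1, a2):
        l1u = betabinom_sym_logpmf(xu, support, a1)
        l2u = betabinom_sym_logpmf(xu, support, a2)
        mx = np.maximum(l1u, l2u)
        p1u = w1 * np.exp(l1u - mx)
        p2u = (1 - w1) * np.exp(l2u - mx)
        denom = p1u + p2u
        ll = float(np.dot(cnt, mx + np.log(denom)))
        return ll, p1u / denom

    w1, a1, a2 = INIT_W1, INIT_A1, INIT_A2
    ll, g1u = loglik_parts(w1, a1, a2)
    logliks = [ll]
    converged = False
    n_iter = 0
    dev2 = (xu - c_hat) ** 2
    for n_iter in range(1, max_iter + 1):
        # M-step: weights from responsibilities, shapes from the weighted
        # second moment around the bin center (closed form)
        wts1 = cnt * g1u
        wts2 = cnt * (1 - g1u)
        s1 = wts1.sum()
        s2 = wts2.sum()
        w1_new = s1 / n
        sig1 = np.dot(wts1, dev2) / s1 if s1 > 0 else np.inf
        sig2 = np.dot(wts2, dev2) / s2 if s2 > 0 else np.inf
        a1_new = float(np.clip(_alpha_from_moment(sig1, c_hat), 1 + EPS, ALPHA1_CAP))
        a2_new = float(np.clip(_alpha_from_moment(sig2, c_hat), EPS, 1 - EPS))

        ll_new, g1u_new = loglik_parts(w1_new, a1_new, a2_new)
        if ll_new < ll - 1e-10 * max(1.0, abs(ll)):
            # moment step overshoots the surrogate maximizer here; do the
            # exact per-component M-step instead (guarantees ascent)
            a1_new = _maximize_q_alpha(xu, wts1, support, 1 + EPS, ALPHA1_CAP, a1_new)
            a2_new = _maximize_q_alpha(xu, wts2, support, EPS, 1 - EPS, a2_new)
            ll_new, g1u_new = loglik_parts(w1_new, a1_new, a2_new)

        delta = max(abs(w1_new - w1), abs(a1_new - a1), abs(a2_new - a2))
        improvement = ll_new - ll
        w1, a1, a2 = float(w1_new), a1_new, a2_new
        ll, g1u = ll_new, g1u_new
        logliks.append(ll)
        if delta < tol:
            converged = True
            break
        # parameters pinned at bounds (or alternating between the moment
        # and exact updates) can move below the likelihood's resolution
        if n_iter > 2 and abs(improvement) < 1e-12 * max(1.0, abs(ll)):
            converged = True
            break

    degenerate = a1 >= ALPHA1_CAP * (1 - 1e-9)
    return w1, a1, a2, converged, degenerate, n_iter, np.asarray(logliks)


def fit_mixture_em(pooled_ai_by_bin: dict[int, np.ndarray], centers: dict[int, float],
                   *, tol: float = 1e-6, max_iter: int = 10_000) -> MixtureFit:
    """Fit the beta-binomial mixture independently in each retained bin."""
    fits = {}
    for i, ai in pooled_ai_by_bin.items():
        c = centers[i]
        w1, a1, a2, conv, degen, n_iter, ll = fit_bin_em(ai, c, tol=tol, max_iter=max_iter)
        fits[i] = BinFit(bin_index=i, center=c, support=int(round(2 * c)),
                         n_genes=len(ai), w1=w1, a1=a1, a2=a2,
                         converged=conv, degenerate=degen, n_iter=n_iter, loglik=ll)
    return MixtureFit(fits=fits)
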