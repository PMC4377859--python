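"""Vectorized beta-binomial likelihood machinery shared by the DE test.

Everything here operates on arrays shaped (genes, replicates) so that a full
study can be tested in a handful of numpy passes.  Proportion MLEs are found
by golden-section search on the logit scale, where the log-likelihood
curvature is of order of the total count and a fixed iteration budget gives
machine-level accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
# logit-scale search bracket: pi in (~1e-14, ~1 - 1e-14)
_LOGIT_LO = -32.3
_LOGIT_HI = 32.3
_N_ITER = 100


def bb_loglik(c: np.ndarray, n: np.ndarray, pi: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Beta-binomial log-likelihood per gene, summed over replicates.

    ``c``/``n`` are (G, R); ``pi`` and ``rho`` are (G,).  ``rho`` is the
    within-replicate beta intra-class correlation; ``rho == 0`` degenerates
    to the binomial.  Terms constant in ``pi`` are dropped (they cancel in
    likelihood ratios).
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.clip(np.asarray(pi, dtype=float), 1e-300, 1.0 - 1e-16)[:, None]
    rho = np.asarray(rho, dtype=float)[:, None]
    binom = np.sum(c * np.log(pi) + (n - c) * np.log1p(-pi), axis=1)
    bb_rows = rho[:, 0] > 1e-12
    if not bb_rows.any():
        return binom
    out = binom
    r = rho[bb_rows]
    a = pi[bb_rows] * (1.0 - r) / r
    b = (1.0 - pi[bb_rows]) * (1.0 - r) / r
    cb, nb = c[bb_rows], n[bb_rows]
    ll = np.sum(betaln(cb + a, nb - cb + b) - betaln(a, b), axis=1)
    out = out.copy()
    out[bb_rows] = ll
    return out


def _maximize_pi(c: np.ndarray, n: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene MLE of the proportion and its log-likelihood.

    Binomial rows have the closed form sum(c)/sum(n); beta-binomial rows are
    maximized by golden-section search on logit(pi).
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    rho = np.asarray(rho, dtype=float)
    G = c.shape[0]
    pi_hat = np.empty(G)
    csum = c.sum(axis=1)
    nsum = n.sum(axis=1)
    pi_hat = np.where(nsum > 0, csum / np.maximum(nsum, 1.0), 0.0)

    bb = rho > 1e-12
    if bb.any():
        cb, nb, rb = c[bb], n[bb], rho[bb]
        lo = np.full(bb.sum(), _LOGIT_LO)
        hi = np.full(bb.sum(), _LOGIT_HI)

        def f(eta):
            p = 1.0 / (1.0 + np.exp(-eta))
            return bb_loglik(cb, nb, p, rb)

        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1, f2 = f(x1), f(x2)
        for _ in range(_N_ITER):
            take_left = f1 >= f2
            hi = np.where(take_left, x2, hi)
            lo = np.where(take_left, lo, x1)
            x1 = hi - _GOLDEN * (hi - lo)
            x2 = lo + _GOLDEN * (hi - lo)
            f1, f2 = f(x1), f(x2)
        eta = 0.5 * (lo + hi)
        pi_hat[bb] = 1.0 / (1.0 + np.exp(-eta))

    ll = bb_loglik(c, n, pi_hat, rho)
    return pi_hat, ll


def bb_lrt(
    ko_counts: np.ndarray,
    ko_totals: np.ndarray,
    wt_counts: np.ndarray,
    wt_totals: np.ndarray,
    rho: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-group beta-binomial LRT.

    All count arrays are (G, R_group).  Returns ``(stat, pi_ko, pi_wt)``
    where ``stat`` is the likelihood-ratio statistic (>= 0) referred to
    chi-square with 1 df by the caller.
    """
    ko_counts = np.atleast_2d(np.asarray(ko_counts, dtype=float))
    wt_counts = np.atleast_2d(np.asarray(wt_counts, dtype=float))
    ko_totals = np.atleast_2d(np.asarray(ko_totals, dtype=float))
    wt_totals = np.atleast_2d(np.asarray(wt_totals, dtype=float))
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if (ko_counts > ko_totals).any() or (wt_counts > wt_totals).any():
        raise ValueError("counts exceed totals")
    if (ko_counts < 0).any() or (wt_counts < 0).any():
        raise ValueError("counts must be non-negative")
    if ((rho < 0) | (rho >= 1)).any():
        raise ValueError("dispersion must lie in [0, 1)")
    all_tot = np.concatenate([ko_totals, wt_totals], axis=1)
    if (all_tot.sum(axis=1) <= 0).any():
        raise ValueError("all-zero totals")

    pi_ko, l_ko = _maximize_pi(ko_counts, ko_totals, rho)
    pi_wt, l_wt = _maximize_pi(wt_counts, wt_totals, rho)
    c_all = np.concatenate([ko_counts, wt_counts], axis=1)
    _, l_0 = _maximize_pi(c_all, all_tot, rho)
    stat = np.maximum(2.0 * (l_ko + l_wt - l_0), 0.0)
    return stat, pi_ko, pi_wt
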