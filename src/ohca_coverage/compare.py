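"""Paired comparison of bystander-AED versus ambulance times.

The Wilcoxon signed-rank test is implemented from first principles: exact
null enumeration (a convolution over rank contributions, conditional on the
observed tie pattern) for n <= 25 paired differences, and the
normal approximation with tie-corrected variance and continuity correction
for larger n.  The z sign convention is negative when the first vector
(AED times) tends below the second (ambulance times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

EXACT_N_MAX = 25


def exact_signed_rank_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of W+ = sum of positive-difference ranks.

    ``ranks`` are the (mid)ranks of |d|; half-integer midranks are doubled
    internally so the support is integral.  Returns (support, pmf) on the
    original (possibly half-integer) scale.
    """
    r2 = np.round(2.0 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(total + 1) / 2.0
    return support, pmf


@dataclass(frozen=True)
class PairedComparison:
    n_pairs: int
    aed_s: np.ndarray
    ambulance_s: np.ndarray
    median_aed: float
    iqr_aed: tuple[float, float]
    median_ambulance: float
    iqr_ambulance: tuple[float, float]
    wilcoxon_W: float
    z: float
    p_value: float
    method: str  # {exact, normal-approx}


def _normal_z(w_plus: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts ** 3 - counts)[counts > 1]).sum()) / 48.0
    if var <= 0:
        raise ValueError("degenerate data: zero variance of signed ranks")
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    return float((diff - cc) / np.sqrt(var)) if diff != 0 else 0.0


def wilcoxon_signed_rank(x, y) -> PairedComparison:
    """Wilcoxon signed-rank test of paired samples (d = x - y).

    Zero differences are dropped; ties in |d| get midranks.  Exact
    enumeration for n <= 25 non-zero pairs, otherwise the tie-corrected
    normal approximation with continuity correction.  Two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate data: all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    z = _normal_z(w_plus, ranks)

    if n <= EXACT_N_MAX:
        support, pmf = exact_signed_rank_pmf(ranks)
        p_lo = float(pmf[support <= w_plus + 1e-9].sum())
        p_hi = float(pmf[support >= w_plus - 1e-9].sum())
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "exact"
    else:
        p = float(2.0 * norm.sf(abs(z)))
        method = "normal-approx"

    q_x = np.percentile(x, [25, 50, 75])
    q_y = np.percentile(y, [25, 50, 75])
    return PairedComparison(
        n_pairs=len(x),
        aed_s=x,
        ambulance_s=y,
        median_aed=float(q_x[1]),
        iqr_aed=(float(q_x[0]), float(q_x[2])),
        median_ambulance=float(q_y[1]),
        iqr_ambulance=(float(q_y[0]), float(q_y[2])),
        wilcoxon_W=w_plus,
        z=z,
        p_value=p,
        method=method,
    )


def summarize_pair(aed_s, ambulance_s) -> dict:
    """Location/scale summaries of both vectors and their difference."""
    a = np.asarray(aed_s, dtype=float)
    b = np.asarray(ambulance_s, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")

    def stats(v: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }

    return {"aed": stats(a), "ambulance": stats(b), "difference": stats(a - b)}


def violin_quantiles(values, probs=None) -> np.ndarray:
    """Quantiles at 1%..99% (default) for external violin/box plotting."""
    if probs is None:
        probs = np.arange(1, 100)
    return np.percentile(np.asarray(values, dtype=float), probs)
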