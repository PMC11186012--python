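"""Uncertainty machinery for correlated MD observables.

Three tools are used across the package:

* Flyvbjerg–Petersen blocking for the standard error of the mean of a
  correlated scalar series (``block_analysis``).  Successive pairwise block
  averaging removes serial correlation; the SE estimate rises with block
  size until it reaches a plateau, which is the unbiased SE.
* A weighted-mean confidence interval with the Cochran ratio-variance SE
  (Gatz–Smith form), used when instances sampled for different durations
  are pooled with weights proportional to sampling time.
* Plain first-order ratio error propagation.

All confidence intervals are 95% two-sided with a Student-t reference
distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import AnalysisError

__all__ = ["BlockResult", "WeightedMeanResult", "block_analysis",
           "weighted_mean_ci", "ratio_with_error"]

#: Stop blocking when fewer than this many blocks remain.
MIN_BLOCKS = 8


@dataclass
class BlockResult:
    mean: float
    block_levels: list            # dicts: block_size, se_estimate, se_of_se
    plateau_se: float
    plateau_level: int
    ci_halfwidth: float
    n_effective: float
    no_plateau: bool = False


@dataclass
class WeightedMeanResult:
    mean: float
    se: float
    ci_halfwidth: float
    weights: np.ndarray = field(repr=False, default=None)
    ci_defined: bool = True


def _block_levels(x: np.ndarray):
    """Pairwise-blocking SE ladder for a 2-D array (series along axis 1).

    Returns lists of (block_size, m_blocks, se, se_of_se) shared across rows,
    with se/se_of_se arrays of shape (n_series,).
    """
    x = np.asarray(x, dtype=float)
    levels = []
    size = 1
    while x.shape[1] >= MIN_BLOCKS:
        m = x.shape[1]
        c0 = x.var(axis=1)                      # biased variance over blocks
        se = np.sqrt(c0 / (m - 1))
        se_of_se = se / np.sqrt(2.0 * (m - 1))
        levels.append((size, m, se, se_of_se))
        if m // 2 < MIN_BLOCKS:
            break
        x = 0.5 * (x[:, : 2 * (m // 2) : 2] + x[:, 1: 2 * (m // 2): 2])
        size *= 2
    return levels


def _plateau(levels, series_idx=None):
    """Apply the plateau rule to one series of a level ladder.

    Plateau = smallest level L with se(L+1) - se(L) < se_of_se(L); if the SE
    is still rising when fewer than MIN_BLOCKS blocks remain, the maximum SE
    is reported and flagged.
    """
    sel = (lambda a: a) if series_idx is None else (lambda a: a[series_idx])
    for L in range(len(levels) - 1):
        se_l, sos_l = sel(levels[L][2]), sel(levels[L][3])
        se_next = sel(levels[L + 1][2])
        if se_next - se_l < sos_l:
            return L, float(se_l), False
    ses = [float(sel(lv[2])) for lv in levels]
    L = int(np.argmax(ses))
    return L, ses[L], True


def block_analysis(series, confidence: float = 0.95) -> BlockResult:
    """Blocking SE and t-based CI of the mean of a correlated scalar series."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 16:
        raise AnalysisError(f"block analysis needs n >= 16 (got {n})")
    mean = float(x.mean())
    if np.ptp(x) == 0.0:
        warnings.warn("constant series: SE is zero", stacklevel=2)
        lv = _block_levels(x[None, :])
        levels = [{"block_size": s, "m_blocks": m, "se_estimate": 0.0,
                   "se_of_se": 0.0} for s, m, _, _ in lv]
        return BlockResult(mean, levels, 0.0, 0, 0.0, float(n))
    lv = _block_levels(x[None, :])
    L, plateau_se, no_plateau = _plateau(lv, series_idx=0)
    m = lv[L][1]
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, m - 1)
    se0 = float(lv[0][2][0])
    n_eff = n * (se0 / plateau_se) ** 2 if plateau_se > 0 else float(n)
    levels = [{"block_size": s, "m_blocks": mm, "se_estimate": float(se[0]),
               "se_of_se": float(ss[0])} for s, mm, se, ss in lv]
    return BlockResult(mean, levels, float(plateau_se), L,
                       float(tcrit * plateau_se), float(n_eff), no_plateau)


def blocked_se_matrix(x: np.ndarray, confidence: float = 0.95):
    """Plateau SE and CI halfwidth for each row of a 2-D series array.

    Vectorized companion of :func:`block_analysis` used for per-bin
    histogram uncertainties.  Returns (se, ci_halfwidth) arrays.
    """
    x = np.asarray(x, dtype=float)
    lv = _block_levels(x)
    n_series = x.shape[0]
    se = np.empty(n_series)
    ci = np.empty(n_series)
    for i in range(n_series):
        if np.ptp(x[i]) == 0.0:
            se[i] = ci[i] = 0.0
            continue
        L, s, _ = _plateau(lv, series_idx=i)
        m = lv[L][1]
        se[i] = s
        ci[i] = sps.t.ppf(0.5 + confidence / 2.0, m - 1) * s
    return se, ci


def weighted_mean_ci(values, weights, confidence: float = 0.95) -> WeightedMeanResult:
    """Weighted mean with the Cochran ratio-variance SE (Gatz–Smith form).

    With equal weights this reduces exactly to the ordinary mean with its
    t-based confidence interval.
    """
    x = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if x.size != w.size:
        raise AnalysisError("values and weights must have the same length")
    if np.any(w <= 0):
        raise AnalysisError("weights must be positive")
    n = x.size
    if n == 0:
        raise AnalysisError("empty input")
    mean = float(np.sum(w * x) / np.sum(w))
    if n == 1:
        return WeightedMeanResult(mean, float("nan"), float("nan"), w, False)
    wbar = w.mean()
    # Cochran ratio-variance estimator of the SE of a weighted mean
    a = w * x - wbar * mean
    s2 = (n / ((n - 1) * np.sum(w) ** 2)) * (
        np.sum(a ** 2)
        - 2.0 * mean * np.sum((w - wbar) * a)
        + mean ** 2 * np.sum((w - wbar) ** 2)
    )
    se = float(np.sqrt(max(s2, 0.0)))
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, n - 1)
    return WeightedMeanResult(mean, se, float(tcrit * se), w, True)


def ratio_with_error(a: float, sa: float, b: float, sb: float) -> dict:
    """a/b with first-order propagated uncertainty."""
    if b == 0:
        raise AnalysisError("ratio denominator is zero")
    ratio = a / b
    if a == 0:
        s = abs(sa / b)
    else:
        s = abs(ratio) * np.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    return {"ratio": float(ratio), "s_ratio": float(s)}
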