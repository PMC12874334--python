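"""Shared statistical primitives.

Two-group Welch's t-test, Pearson correlation with t-based p-value, and
Benjamini-Hochberg FDR adjustment.  Every downstream stage funnels its
hypothesis testing through these three functions so conventions (two-sided
p-values, degenerate-input handling) are defined in exactly one place.

Conventions for degenerate inputs:

* Welch with both groups zero-variance: p = 1 if the means are equal,
  p = 0 otherwise (preserves ranking instead of propagating NaN).
* Pearson with |r| = 1: p clamped to 0 (legitimately reachable at n = 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TTestResult",
    "CorrResult",
    "PValueSet",
    "welch_t_test",
    "welch_t_test_rows",
    "pearson_corr_test",
    "bh_adjust",
]


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


class CorrResult(NamedTuple):
    r: float
    p: float


@dataclass(frozen=True)
class PValueSet:
    """Raw and BH-adjusted p-values, aligned by index."""

    raw_p: np.ndarray
    adjusted_p: np.ndarray

    def __post_init__(self) -> None:
        if self.raw_p.shape != self.adjusted_p.shape:
            raise ValueError("raw and adjusted vectors must have equal length")


def welch_t_test_rows(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch's t-test between two matrices.

    Parameters
    ----------
    a, b : arrays of shape (n_features, n_a) and (n_features, n_b)
        Observations for group A and group B.  Each group needs >= 2
        columns.

    Returns
    -------
    (t, df, p) arrays of length n_features, two-sided p-values.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("Welch's t-test requires >= 2 observations per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa2, sb2 = va / na, vb / nb
    denom = np.sqrt(sa2 + sb2)
    diff = ma - mb

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))

    # degenerate rows: both groups constant
    degen = denom == 0
    equal = degen & (diff == 0)
    unequal = degen & (diff != 0)
    t = np.where(equal, 0.0, t)
    t = np.where(unequal, np.where(diff > 0, np.inf, -np.inf), t)
    df = np.where(degen, float(na + nb - 2), df)

    p = np.empty_like(t)
    ok = ~degen
    p[ok] = 2.0 * _sps.t.sf(np.abs(t[ok]), df[ok])
    p[equal] = 1.0
    p[unequal] = 0.0
    return t, df, p


def welch_t_test(values_a, values_b) -> TTestResult:
    """Two-sided Welch's t-test for one pair of groups.

    Degenerate convention: both groups zero-variance with equal means gives
    (t=0, p=1); zero-variance with unequal means gives p=0.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    t, df, p = welch_t_test_rows(a[None, :], b[None, :])
    return TTestResult(float(t[0]), float(df[0]), float(p[0]))


def pearson_corr_test(x, y) -> CorrResult:
    """Pearson product-moment correlation with two-sided t-test p-value.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 clamps p to 0.  Constant input raises ValueError
    (undefined correlation; the caller decides how to exclude the feature).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation test requires n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = float(np.sqrt(np.sum(xd**2)))
    sy = float(np.sqrt(np.sum(yd**2)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.dot(xd, yd) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if 1.0 - r * r <= 1e-15:
        return CorrResult(float(np.sign(r)), 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return CorrResult(r, p)


def bh_adjust(raw_p) -> PValueSet:
    """Benjamini-Hochberg step-up FDR adjustment.

    Standard step-up with monotonicity enforcement; order-invariant and
    length preserving.  Values outside [0, 1] raise ValueError.
    """
    p = np.asarray(raw_p, dtype=float).ravel()
    if p.size == 0:
        return PValueSet(p.copy(), p.copy())
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adj_sorted
    return PValueSet(p.copy(), adjusted)
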