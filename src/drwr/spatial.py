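"""Correlation between surrogate scores with spatial autocorrelation correction.

Gridded complementarity scores are spatially autocorrelated, so the nominal
sample size of a Pearson correlation between two score maps overstates the
information available.  The modified t-test of Dutilleul (1993) replaces n by
an effective sample size M estimated from the spatial autocovariance of the
two variables: with B the centering matrix and S_x, S_y the estimated
spatial correlation matrices,

    M = 1 + tr(B S_x B) tr(B S_y B) / tr(B S_x B S_y B)

and the test statistic t = r sqrt((M - 2) / (1 - r^2)) is referred to a
t-distribution with M - 2 degrees of freedom.  For spatially independent
data S_x = S_y = I and M reduces exactly to n.

Autocovariances are estimated from equal-width Euclidean distance classes on
cell-center coordinates (default 12 classes spanning distances up to half
the maximum pairwise distance; pairs beyond that receive zero correlation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .grids import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CorrelationTest", "pearson", "dutilleul_test", "correlation_report"]


@dataclass
class CorrelationTest:
    """Result of a (possibly spatially corrected) correlation test."""

    r: float
    n: int
    effective_sample_size: float
    t_statistic: float
    p_value: float
    method: str = "dutilleul"


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("zero variance: correlation undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _t_statistic(r: float, df: float) -> float:
    one_minus = 1.0 - r * r
    if one_minus <= 0.0:
        return float(np.inf) if r > 0 else float(-np.inf)
    return float(r * np.sqrt(df / one_minus))


def _classic_test(r: float, n: int) -> CorrelationTest:
    df = n - 2
    t_stat = _t_statistic(r, df)
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return CorrelationTest(r, n, float(n), t_stat, float(p), "classic")


def _spatial_corr_matrix(
    z: np.ndarray, class_idx: np.ndarray, n_classes: int
) -> np.ndarray:
    """Estimated spatial correlation matrix from distance-class means.

    ``z`` is the standardized variable; ``class_idx`` assigns each site pair
    (condensed form) a distance class, with -1 for pairs beyond the modelled
    range whose correlation is taken as 0.
    """
    prods = z[:, None] * z[None, :]
    cond = squareform(prods, checks=False)
    corr = np.zeros(n_classes)
    for h in range(n_classes):
        sel = class_idx == h
        if sel.any():
            corr[h] = cond[sel].mean()
    vals = np.where(class_idx >= 0, corr[np.maximum(class_idx, 0)], 0.0)
    S = squareform(vals)
    np.fill_diagonal(S, 1.0)
    return S


def dutilleul_test(x, y, coords, n_classes: int = 12) -> CorrelationTest:
    """Pearson correlation with Dutilleul's modified t-test.

    ``coords`` are per-site (row, col) or (x, y) cell-center coordinates and
    must be unique.  If the trace formula degenerates (non-positive
    denominator or M <= 2) the classic test is returned with a warning.  The
    effective sample size is capped at n, so the corrected test is never
    more liberal than the classic one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError("Dutilleul's test needs at least 10 sites")
    if coords.shape != (n, 2):
        raise ValidationError("coords must have shape (n, 2)")
    if len({tuple(c) for c in coords}) != n:
        raise ValidationError("site coordinates must be unique")
    r = pearson(x, y)

    d = pdist(coords)
    d_max = d.max() / 2.0
    width = d_max / n_classes
    class_idx = np.where(d <= d_max, np.minimum((d / width).astype(int), n_classes - 1), -1)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    Sx = _spatial_corr_matrix(zx, class_idx, n_classes)
    Sy = _spatial_corr_matrix(zy, class_idx, n_classes)

    # double-center: D = B S B with B = I - J/n
    def _center(S: np.ndarray) -> np.ndarray:
        row = S.mean(axis=0, keepdims=True)
        return S - row - row.T + S.mean()

    Dx = _center(Sx)
    Dy = _center(Sy)
    denom = float(np.sum(Dx * Dy))
    num = float(np.trace(Dx) * np.trace(Dy))
    if not np.isfinite(denom) or denom <= 0 or num <= 0:
        warnings.warn(
            "degenerate spatial covariance estimate; falling back to the "
            "classic t-test",
            stacklevel=2,
        )
        return _classic_test(r, n)
    m_hat = 1.0 + num / denom
    m_hat = min(m_hat, float(n))
    if m_hat <= 2.0:
        warnings.warn(
            "effective sample size <= 2; falling back to the classic t-test",
            stacklevel=2,
        )
        return _classic_test(r, n)
    df = m_hat - 2.0
    t_stat = _t_statistic(r, df)
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return CorrelationTest(r, n, float(m_hat), t_stat, float(p), "dutilleul")


def correlation_report(
    score_vectors: dict[str, np.ndarray],
    coords: np.ndarray,
    alpha: float = 0.05,
    n_classes: int = 12,
) -> pd.DataFrame:
    """Lower-triangular matrix of pairwise r with corrected significance.

    Each cell holds the Pearson r between two score maps, marked with ``*``
    when significant at ``alpha`` under the Dutilleul-corrected test.
    """
    names = list(score_vectors)
    rows = []
    for i, a in enumerate(names[1:], start=1):
        row: dict[str, str] = {"method": a}
        for b in names[:i]:
            res = dutilleul_test(
                score_vectors[a], score_vectors[b], coords, n_classes
            )
            mark = "*" if res.p_value < alpha else ""
            row[b] = f"{res.r:.2f}{mark}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("method").fillna("")
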