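"""Species-accumulation curves and the Species Accumulation Index (SAI).

A surrogate ranking is scored by accumulating sites from the top of the
ranking and counting species represented at least once (the S curve), then
comparing against an optimal ordering (O, from the reverse-greedy or RWR
ranking of the true inventory) and the mean of many random orderings (R):

    SAI = (S - R) / (O - R)

evaluated at a set of protection fractions (by default 15%, 20%, 25%, 30%
and 35% of sites) and averaged.  SAI is 1 for an optimal surrogate, 0 for
random performance, and negative when worse than random; it is undefined at
a fraction where O = R.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complementarity import (
    ComplementarityVector,
    SelectionRanking,
    ranking_from_scores,
    rwr,
    zonation_ranking,
)
from .grids import OccurrenceMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AccumulationCurve",
    "SAIResult",
    "DEFAULT_FRACTIONS",
    "accumulation_curve",
    "optimum_curve",
    "random_mean_curve",
    "cells_for_fraction",
    "sai",
]

DEFAULT_FRACTIONS = (0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass
class AccumulationCurve:
    """Represented-species counts at every prefix size 0..n_sites.

    ``counts`` may be fractional for the mean random curve; ``sd`` (when
    present) is the pointwise standard deviation across random replicates and
    ``replicates`` optionally retains the per-replicate counts.
    """

    counts: np.ndarray
    source_tag: str = ""
    sd: np.ndarray | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError("curve counts must be a nonempty 1-d array")
        if counts[0] != 0 or np.any(np.diff(counts) < -1e-9):
            raise ValidationError("curve must start at 0 and be nondecreasing")
        self.counts = counts

    @property
    def n_sites(self) -> int:
        return self.counts.size - 1

    def at(self, m: int) -> float:
        return float(self.counts[m])


@dataclass
class SAIResult:
    """Per-fraction S, O, R and SAI values plus their mean.

    Fractions where O = R are flagged undefined (NaN) and excluded from the
    mean.  ``sai_quantiles`` optionally reports per-replicate SAI quantiles
    (an uncertainty extension beyond the mean-curve estimator).
    """

    fractions: list[float]
    m_cells: list[int]
    S: np.ndarray
    O: np.ndarray
    R: np.ndarray
    R_sd: np.ndarray
    sai_values: np.ndarray
    mean_sai: float
    n_random_reps: int
    o_method: str = "zonation"
    method_tag: str = ""
    sai_quantiles: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def undefined_fractions(self) -> list[float]:
        return [f for f, v in zip(self.fractions, self.sai_values) if np.isnan(v)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "fraction": self.fractions,
                "m_cells": self.m_cells,
                "S": self.S,
                "O": self.O,
                "R": self.R,
                "R_sd": self.R_sd,
                "SAI": self.sai_values,
            }
        )
        mean_row = pd.DataFrame(
            {
                "fraction": ["mean"],
                "m_cells": [""],
                "S": [""],
                "O": [""],
                "R": [""],
                "R_sd": [""],
                "SAI": [self.mean_sai],
            }
        )
        return pd.concat([df, mean_row], ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def accumulation_curve(
    ranking: SelectionRanking, occ_eval: OccurrenceMatrix
) -> AccumulationCurve:
    """Species represented in every prefix of a ranking, against ``occ_eval``."""
    if set(ranking.order) != set(occ_eval.sites):
        raise ValidationError("ranking and evaluation matrix cover different sites")
    pos = occ_eval.site_index()
    order_idx = np.array([pos[s] for s in ranking.order])
    covered = np.cumsum(occ_eval.incidence[order_idx], axis=0) > 0
    counts = np.concatenate(([0], covered.sum(axis=1)))
    return AccumulationCurve(counts, f"S:{ranking.method_tag}")


def optimum_curve(occ_eval: OccurrenceMatrix, method: str = "zonation") -> AccumulationCurve:
    """Accumulation curve of the optimal ordering of the true inventory.

    ``method='zonation'`` uses the reverse-greedy core-area ranking;
    ``method='rwr'`` ranks by rarity-weighted richness.  Both are heuristics
    for the (NP-hard) maximum-coverage optimum; on published datasets they
    have produced identical curves, but this is empirical, not guaranteed.
    """
    if method == "zonation":
        ranking = zonation_ranking(occ_eval)
    elif method == "rwr":
        ranking = ranking_from_scores(rwr(occ_eval), occ_eval)
    else:
        raise ValidationError(f"unknown optimum method {method!r}")
    curve = accumulation_curve(ranking, occ_eval)
    curve.source_tag = f"O:{method}"
    return curve


def random_mean_curve(
    occ_eval: OccurrenceMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    keep_replicates: bool = False,
) -> AccumulationCurve:
    """Pointwise mean (and SD) of ``n_reps`` random accumulation curves.

    A species first appears at the minimum permutation position of its
    occupied sites, so each replicate curve is computed from first-appearance
    positions rather than explicit prefix unions.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2 for a mean random curve")
    n = occ_eval.n_sites
    rng = np.random.default_rng(seed)
    occupied = [np.flatnonzero(col) for col in occ_eval.incidence.T]
    reps = np.zeros((n_reps, n + 1))
    for rep in range(n_reps):
        posn = np.empty(n, dtype=np.int64)
        posn[rng.permutation(n)] = np.arange(n)
        first = np.array([posn[cells].min() for cells in occupied if cells.size])
        reps[rep, 1:] = np.cumsum(np.bincount(first, minlength=n))
    curve = AccumulationCurve(
        reps.mean(axis=0),
        "R:mean",
        sd=reps.std(axis=0, ddof=1),
        replicates=reps if keep_replicates else None,
    )
    return curve


def cells_for_fraction(fraction: float, n_sites: int) -> int:
    """Protection fraction -> cell count: round half up, minimum 1 cell."""
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, int(np.floor(fraction * n_sites + 0.5)))


def sai(
    surrogate_curve: AccumulationCurve,
    optimum: AccumulationCurve,
    random_mean: AccumulationCurve,
    fractions=DEFAULT_FRACTIONS,
    mode: str = "levels",
    o_method: str = "zonation",
    n_random_reps: int | None = None,
) -> SAIResult:
    """Species Accumulation Index of a surrogate ranking.

    ``mode='levels'`` (default) evaluates ``(S-R)/(O-R)`` at each protection
    fraction and averages the defined values; ``mode='auc'`` uses the areas
    under the three curves instead, reported as a single value.
    """
    n = surrogate_curve.n_sites
    if optimum.n_sites != n or random_mean.n_sites != n:
        raise ValidationError("curves are defined over different numbers of sites")
    fractions = sorted(fractions)
    if mode == "auc":
        s_area = surrogate_curve.counts.sum()
        o_area = optimum.counts.sum()
        r_area = random_mean.counts.sum()
        if o_area == r_area:
            raise ValidationError("optimum and random areas coincide; SAI undefined")
        value = (s_area - r_area) / (o_area - r_area)
        return SAIResult(
            fractions=[1.0], m_cells=[n],
            S=np.array([s_area]), O=np.array([o_area]),
            R=np.array([r_area]), R_sd=np.array([np.nan]),
            sai_values=np.array([value]), mean_sai=float(value),
            n_random_reps=n_random_reps or 0, o_method=o_method,
            method_tag=surrogate_curve.source_tag,
        )
    if mode != "levels":
        raise ValidationError(f"unknown SAI mode {mode!r}")

    m_cells = [cells_for_fraction(f, n) for f in fractions]
    S = np.array([surrogate_curve.at(m) for m in m_cells])
    O = np.array([optimum.at(m) for m in m_cells])
    R = np.array([random_mean.at(m) for m in m_cells])
    R_sd = np.array(
        [random_mean.sd[m] if random_mean.sd is not None else np.nan for m in m_cells]
    )
    values = np.full(len(fractions), np.nan)
    defined = O != R
    values[defined] = (S[defined] - R[defined]) / (O[defined] - R[defined])
    if not defined.all():
        bad = [f for f, d in zip(fractions, defined) if not d]
        warnings.warn(
            f"SAI undefined (O = R) at fraction(s) {bad}; excluded from the mean",
            stacklevel=2,
        )
    if not defined.any():
        mean_sai = float("nan")
    else:
        mean_sai = float(values[defined].mean())

    quantiles: dict[float, np.ndarray] = {}
    if random_mean.replicates is not None:
        # per-replicate SAI distribution (extension): R replaced by each
        # random replicate's own curve
        reps = random_mean.replicates[:, m_cells]
        with np.errstate(divide="ignore", invalid="ignore"):
            rep_sai = (S[None, :] - reps) / (O[None, :] - reps)
        valid = np.isfinite(rep_sai)
        counts = valid.sum(axis=1)
        sums = np.where(valid, rep_sai, 0.0).sum(axis=1)
        rep_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for q in (0.025, 0.5, 0.975):
            quantiles[q] = np.nanquantile(rep_mean, q)

    return SAIResult(
        fractions=list(fractions), m_cells=m_cells,
        S=S, O=O, R=R, R_sd=R_sd,
        sai_values=values, mean_sai=mean_sai,
        n_random_reps=n_random_reps or 0, o_method=o_method,
        method_tag=surrogate_curve.source_tag, sai_quantiles=quantiles,
    )
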