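"""Rarity scores, rarity-weighted richness, and site-ranking algorithms.

Rarity-weighted richness (RWR) scores each site as the sum, over species
present there, of the inverse of each species' occupied-site count: a species
found in a single cell contributes 1, one found in 20 cells contributes 0.05.
Ranking sites by RWR, or by the reverse-greedy core-area removal heuristic
(the Zonation-style ranking), yields near-optimal complementary site sets;
an exhaustive-enumeration optimum is provided as a certifying oracle for
small instances.

Score ties are broken by ascending site-ID lexicographic order (the removal
heuristic interposes a rarity-mass criterion first; see
:func:`zonation_ranking`), so every ranking is a deterministic total order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import OccurrenceMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRarity",
    "ComplementarityVector",
    "SelectionRanking",
    "rarity_scores",
    "rwr",
    "zonation_ranking",
    "ranking_from_scores",
    "ranking_to_scores",
    "random_rankings",
    "exhaustive_optimum",
]


@dataclass
class SpeciesRarity:
    """Per-species inverse-occupancy rarity: ``rarity = 1 / c``.

    ``c`` is the occupied-site count.  Species with ``c = 0`` break the
    formula and are excluded from scoring; they are listed in
    ``zero_occurrence``.
    """

    species: list[str]
    c: np.ndarray
    rarity: np.ndarray
    zero_occurrence: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, self.rarity))


@dataclass
class ComplementarityVector:
    """Per-site nonnegative priority scores with a method tag."""

    sites: list[str]
    scores: np.ndarray
    method_tag: str = "RWR"

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.sites),):
            raise ValidationError("scores length does not match number of sites")
        if not np.all(np.isfinite(scores)) or np.any(scores < 0):
            raise ValidationError("scores must be finite and nonnegative")
        self.scores = scores

    def as_series(self):
        import pandas as pd

        return pd.Series(self.scores, index=self.sites, name=self.method_tag)


@dataclass
class SelectionRanking:
    """A total priority order over sites (best first) with prefix coverage.

    ``prefix_counts[m]`` is the number of species represented at least once in
    the top-``m`` sites (``prefix_counts[0] == 0``); by construction the top-m
    set is nested within the top-m' set for m < m'.
    """

    order: list[str]
    prefix_counts: np.ndarray
    method_tag: str = "ranking"

    def __post_init__(self) -> None:
        self.order = list(self.order)
        pc = np.asarray(self.prefix_counts)
        if pc.shape != (len(self.order) + 1,):
            raise ValidationError("prefix_counts must have length n_sites + 1")
        if pc[0] != 0 or np.any(np.diff(pc) < 0):
            raise ValidationError("prefix_counts must start at 0 and be nondecreasing")
        self.prefix_counts = pc

    @property
    def n_sites(self) -> int:
        return len(self.order)

    def top(self, m: int) -> list[str]:
        return self.order[:m]


def _lex_rank(sites: list[str]) -> np.ndarray:
    """Position of each site in ascending lexicographic order of its ID."""
    order = sorted(range(len(sites)), key=lambda i: sites[i])
    rank = np.empty(len(sites), dtype=np.int64)
    rank[order] = np.arange(len(sites))
    return rank


def _prefix_counts(order_idx: np.ndarray, incidence: np.ndarray) -> np.ndarray:
    """Species represented at least once in every prefix of an ordering."""
    covered = np.cumsum(incidence[order_idx], axis=0) > 0
    counts = covered.sum(axis=1)
    return np.concatenate(([0], counts))


def rarity_scores(occ: OccurrenceMatrix) -> SpeciesRarity:
    """Inverse-occupancy rarity of every species with at least one presence."""
    if occ.n_species == 0 or occ.n_sites == 0:
        raise ValidationError("occurrence matrix is empty")
    counts = occ.occupancy_counts()
    scorable = counts > 0
    if not scorable.any():
        raise ValidationError("no scorable species: every species has zero presences")
    zero = [sp for sp, ok in zip(occ.species, scorable) if not ok]
    if zero:
        logger.warning(
            "%d species with zero presences excluded from rarity scoring: %s",
            len(zero), ", ".join(zero[:10]),
        )
    species = [sp for sp, ok in zip(occ.species, scorable) if ok]
    c = counts[scorable].astype(np.int64)
    return SpeciesRarity(species, c, 1.0 / c, zero)


def rwr(occ: OccurrenceMatrix) -> ComplementarityVector:
    """Rarity-weighted richness of every site.

    ``score(site) = sum over species present in site of 1 / c_species``; an
    empty site scores 0.  Summed over all sites each scorable species
    contributes exactly 1, so total RWR equals the number of species with at
    least one presence.
    """
    rar = rarity_scores(occ)
    cols = [occ.species.index(sp) for sp in rar.species]
    scores = occ.incidence[:, cols].astype(float) @ rar.rarity
    return ComplementarityVector(list(occ.sites), scores, "RWR")


def zonation_ranking(occ: OccurrenceMatrix) -> SelectionRanking:
    """Reverse-greedy core-area removal ranking (basic formulation).

    Starting from all sites retained, iteratively remove the site whose loss
    least harms the worst-off species: for each remaining site ``i`` the
    marginal value is ``delta_i = max over species present in i of
    1 / (remaining occupied-site count)``, and the site with minimal
    ``delta_i`` is removed.  Ties on ``delta`` are broken by the site's total
    remaining rarity mass (sum of the same inverse counts), so that when every
    candidate holds some last-refuge species the one contributing least
    overall is dropped first; remaining ties fall back to ascending site ID.
    The emitted order is the removal order reversed, so the last-removed site
    ranks first and each top-m set is nested in every larger top-m' set.
    """
    counts = occ.occupancy_counts()
    if not (counts > 0).any():
        raise ValidationError("no represented species to rank against")
    n = occ.n_sites
    inc = occ.incidence
    lex = _lex_rank(occ.sites)
    remaining = np.ones(n, dtype=bool)
    c = counts.astype(float)
    removal: list[int] = []
    active = np.arange(n)
    for _ in range(n):
        w = np.where(c > 0, 1.0 / np.maximum(c, 1.0), 0.0)
        sub = inc[active]
        weighted = sub * w
        delta = weighted.max(axis=1)
        rarity_mass = weighted.sum(axis=1)
        pick = active[np.lexsort((lex[active], rarity_mass, delta))[0]]
        removal.append(int(pick))
        remaining[pick] = False
        c -= inc[pick]
        active = active[active != pick]
    order_idx = np.array(removal[::-1])
    return SelectionRanking(
        [occ.sites[i] for i in order_idx],
        _prefix_counts(order_idx, inc),
        "zonation",
    )


def ranking_to_scores(ranking: SelectionRanking) -> ComplementarityVector:
    """Per-site rank value in (0, 1]: 1 for the top site, 1/n for the last.

    Matches the convention that values close to one mark cells removed last
    by the reverse-greedy process.
    """
    n = ranking.n_sites
    scores = (n - np.arange(n)) / n
    return ComplementarityVector(list(ranking.order), scores, ranking.method_tag)


def ranking_from_scores(
    scores: ComplementarityVector, occ: OccurrenceMatrix
) -> SelectionRanking:
    """Rank sites by descending surrogate score, accumulating coverage in ``occ``.

    The score vector and the evaluation matrix must cover the same site set;
    equal scores fall back to ascending site-ID order.
    """
    if set(scores.sites) != set(occ.sites):
        raise ValidationError(
            "score vector and occurrence matrix cover different site sets"
        )
    pos = {s: i for i, s in enumerate(scores.sites)}
    vals = np.array([scores.scores[pos[s]] for s in occ.sites])
    lex = _lex_rank(occ.sites)
    order_idx = np.lexsort((lex, -vals))
    return SelectionRanking(
        [occ.sites[i] for i in order_idx],
        _prefix_counts(order_idx, occ.incidence),
        scores.method_tag,
    )


def random_rankings(
    occ: OccurrenceMatrix, n_reps: int, seed: int
) -> list[SelectionRanking]:
    """Independent uniform permutations of the sites, reproducible by seed."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        order_idx = rng.permutation(occ.n_sites)
        out.append(
            SelectionRanking(
                [occ.sites[i] for i in order_idx],
                _prefix_counts(order_idx, occ.incidence),
                "random",
            )
        )
    return out


def exhaustive_optimum(
    occ: OccurrenceMatrix, m: int, max_combinations: int = 10**6
) -> tuple[tuple[str, ...], int]:
    """The m-site subset maximizing represented species, by full enumeration.

    Ties are broken lexicographically on the sorted site-ID tuple.  Refuses
    instances with more than ``max_combinations`` candidate subsets.
    """
    n = occ.n_sites
    if not 0 < m <= n:
        raise ValidationError(f"m must be in 1..{n}, got {m}")
    n_comb = math.comb(n, m)
    if n_comb > max_combinations:
        raise ValidationError(
            f"C({n}, {m}) = {n_comb} exceeds the enumeration guard of "
            f"{max_combinations}; use a heuristic ranking instead"
        )
    # species bitmask per site, in lexicographic site order for tie-breaking
    site_order = sorted(range(n), key=lambda i: occ.sites[i])
    masks = []
    for i in site_order:
        bits = 0
        for j in np.flatnonzero(occ.incidence[i]):
            bits |= 1 << int(j)
        masks.append(bits)
    best_count = -1
    best: tuple[int, ...] = ()
    for combo in itertools.combinations(range(n), m):
        agg = 0
        for i in combo:
            agg |= masks[i]
        cnt = agg.bit_count()
        if cnt > best_count:
            best_count, best = cnt, combo
    sites = tuple(occ.sites[site_order[i]] for i in best)
    return sites, best_count
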