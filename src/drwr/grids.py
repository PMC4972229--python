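"""Nested-grid data model and plain-text I/O.

The planning landscape is a rectangular grid of fine cells, each belonging to
exactly one coarse cell (a ``k x k`` block of fine cells; edge blocks may be
partial).  Species data live in boolean site-by-species occurrence matrices at
either resolution; environmental predictors live in site-by-variable tables;
range maps are per-species sets of fine-cell indices.

Fine cells are indexed row-major and 0-based; the canonical site ID of the
cell in row ``r``, column ``c`` is ``"r{r}c{c}"`` at both resolutions (the
``resolution_tag`` of a matrix disambiguates).  All tables are read and
written as UTF-8 comma-delimited text with sites as rows.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "GridSpec",
    "OccurrenceMatrix",
    "EnvTable",
    "RangeMapSet",
    "read_occurrence",
    "write_occurrence",
    "read_env_table",
    "write_env_table",
    "read_range_masks",
    "write_range_masks",
    "ranges_from_geojson",
    "aggregate_to_coarse",
    "rasterize_ranges",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValidationError):
    """Raised when a delimited-text input cannot be interpreted."""


_SITE_ID_RE = re.compile(r"^r(\d+)c(\d+)$")


def parse_site_id(site_id: str) -> tuple[int, int]:
    """Return the (row, col) encoded in a canonical ``r{row}c{col}`` site ID."""
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise ValidationError(f"site ID {site_id!r} is not of the form 'r<row>c<col>'")
    return int(m.group(1)), int(m.group(2))


def site_coords(site_ids: Sequence[str]) -> np.ndarray:
    """(row, col) coordinates for a sequence of canonical site IDs, shape (n, 2)."""
    return np.array([parse_site_id(s) for s in site_ids], dtype=float)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a nested coarse/fine rectangular grid.

    Parameters
    ----------
    n_rows_fine, n_cols_fine
        Fine-grid dimensions.
    block_factor
        Number of fine cells per coarse-cell side (``k``).  Coarse dimensions
        are ``ceil(n_rows_fine / k) x ceil(n_cols_fine / k)``; edge blocks may
        be partial and are treated as full-fledged coarse sites.
    cell_size_fine, origin
        Informational geometry: side length of a fine cell and the (x, y)
        center of fine cell (0, 0).
    """

    n_rows_fine: int
    n_cols_fine: int
    block_factor: int = 1
    cell_size_fine: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("n_rows_fine", "n_cols_fine", "block_factor"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n_rows_coarse(self) -> int:
        return math.ceil(self.n_rows_fine / self.block_factor)

    @property
    def n_cols_coarse(self) -> int:
        return math.ceil(self.n_cols_fine / self.block_factor)

    @property
    def n_fine(self) -> int:
        return self.n_rows_fine * self.n_cols_fine

    @property
    def n_coarse(self) -> int:
        return self.n_rows_coarse * self.n_cols_coarse

    def fine_site_ids(self) -> list[str]:
        return [
            f"r{r}c{c}"
            for r in range(self.n_rows_fine)
            for c in range(self.n_cols_fine)
        ]

    def coarse_site_ids(self) -> list[str]:
        return [
            f"r{r}c{c}"
            for r in range(self.n_rows_coarse)
            for c in range(self.n_cols_coarse)
        ]

    def block_of(self, fine_row: int, fine_col: int) -> tuple[int, int]:
        """Coarse (row, col) containing a fine cell; total on the fine grid."""
        if not (0 <= fine_row < self.n_rows_fine and 0 <= fine_col < self.n_cols_fine):
            raise ValidationError(
                f"fine cell ({fine_row}, {fine_col}) outside "
                f"{self.n_rows_fine}x{self.n_cols_fine} grid"
            )
        return fine_row // self.block_factor, fine_col // self.block_factor

    def fine_block_index(self) -> np.ndarray:
        """Flat coarse-cell index of every fine cell, in row-major fine order."""
        rows = np.repeat(np.arange(self.n_rows_fine), self.n_cols_fine)
        cols = np.tile(np.arange(self.n_cols_fine), self.n_rows_fine)
        return (rows // self.block_factor) * self.n_cols_coarse + (
            cols // self.block_factor
        )

    def fine_cell_centers(self) -> np.ndarray:
        """(x, y) centers of fine cells in row-major order, shape (n_fine, 2)."""
        rows = np.repeat(np.arange(self.n_rows_fine), self.n_cols_fine)
        cols = np.tile(np.arange(self.n_cols_fine), self.n_rows_fine)
        x0, y0 = self.origin
        return np.column_stack(
            (x0 + cols * self.cell_size_fine, y0 + rows * self.cell_size_fine)
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} ID {dup!r}")


@dataclass
class OccurrenceMatrix:
    """Boolean site-by-species incidence with ordered identifiers.

    Species with zero presences are representable (all-absent columns) but are
    flagged by :meth:`zero_occurrence_species`; rarity scoring excludes them
    because the inverse-occupancy formula is undefined at zero.
    """

    sites: list[str]
    species: list[str]
    incidence: np.ndarray
    resolution_tag: str = "fine"

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        self.species = list(self.species)
        _check_unique(self.sites, "site")
        _check_unique(self.species, "species")
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.sites), len(self.species)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        if inc.dtype != bool:
            vals = np.unique(inc)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValidationError("incidence must contain only 0/1 values")
            inc = inc.astype(bool)
        self.incidence = inc
        if self.resolution_tag not in ("coarse", "fine"):
            raise ValidationError(
                f"resolution_tag must be 'coarse' or 'fine', got {self.resolution_tag!r}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def occupancy_counts(self) -> np.ndarray:
        """Occupied-site count per species (column sums)."""
        return self.incidence.sum(axis=0)

    def zero_occurrence_species(self) -> list[str]:
        counts = self.occupancy_counts()
        return [sp for sp, c in zip(self.species, counts) if c == 0]

    def site_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sites)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence.astype(int), index=self.sites, columns=self.species
        )


@dataclass
class EnvTable:
    """Site-by-variable numeric table; NaN marks missing values."""

    sites: list[str]
    variables: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        self.variables = list(self.variables)
        _check_unique(self.sites, "site")
        _check_unique(self.variables, "variable")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.sites), len(self.variables)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sites)} sites x {len(self.variables)} variables"
            )
        self.values = vals

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def constant_variables(self) -> list[str]:
        """Variables with no finite variance over non-missing sites."""
        out = []
        for j, name in enumerate(self.variables):
            col = self.values[:, j]
            col = col[np.isfinite(col)]
            if col.size < 2 or np.nanstd(col) == 0.0:
                out.append(name)
        return out

    def complete_rows(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of sites with no missing value in the given variables."""
        cols = self._column_indices(variables)
        return np.isfinite(self.values[:, cols]).all(axis=1)

    def subset(self, variables: Sequence[str]) -> "EnvTable":
        cols = self._column_indices(variables)
        return EnvTable(self.sites, [self.variables[j] for j in cols],
                        self.values[:, cols])

    def _column_indices(self, variables: Sequence[str] | None) -> list[int]:
        if variables is None:
            return list(range(len(self.variables)))
        index = {v: j for j, v in enumerate(self.variables)}
        missing = [v for v in variables if v not in index]
        if missing:
            raise ValidationError(f"unknown environmental variable(s): {missing}")
        return [index[v] for v in variables]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.variables)


@dataclass
class RangeMapSet:
    """Per-species fine-cell masks (any partial overlap of a range counts).

    Masks are stored as sorted arrays of flat fine-cell indices.  A species
    whose range lies entirely outside the grid has an empty mask and is
    excluded from downstream scoring.
    """

    species: list[str]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = list(self.species)
        _check_unique(self.species, "species")
        clean: dict[str, np.ndarray] = {}
        for sp in self.species:
            cells = np.unique(np.asarray(self.masks.get(sp, []), dtype=np.int64))
            if cells.size and cells[0] < 0:
                raise ValidationError(f"negative cell index in mask for {sp!r}")
            clean[sp] = cells
        self.masks = clean

    @property
    def n_species(self) -> int:
        return len(self.species)

    def nonempty_species(self) -> list[str]:
        return [sp for sp in self.species if self.masks[sp].size > 0]


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_occurrence(path: str | Path, resolution_tag: str = "fine") -> OccurrenceMatrix:
    """Read a sites-as-rows 0/1 occurrence table (first column = site ID)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str)
    sites = [str(s) for s in df.index]
    species = [str(c) for c in df.columns]
    inc = np.empty(df.shape, dtype=bool)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "0":
                inc[i, j] = False
            elif cell == "1":
                inc[i, j] = True
            else:
                raise ParseError(
                    f"{path.name}: malformed cell {cell!r} at site {sites[i]!r}, "
                    f"species {species[j]!r} (expected 0 or 1)"
                )
    occ = OccurrenceMatrix(sites, species, inc, resolution_tag)
    logger.info(
        "read %s: %d sites, %d species, %d presences",
        path.name, occ.n_sites, occ.n_species, int(occ.incidence.sum()),
    )
    return occ


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.to_frame().to_csv(Path(path), index_label="site_id")


def read_env_table(path: str | Path) -> EnvTable:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: non-numeric environmental value ({exc})") from exc
    return EnvTable([str(s) for s in df.index], [str(c) for c in df.columns], values)


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.to_frame().to_csv(Path(path), index_label="site_id")


def read_range_masks(path: str | Path) -> RangeMapSet:
    """Read per-species masks from a two-column table: species_id, cell_id."""
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] != 2:
        raise ParseError(f"{path.name}: expected two columns (species_id, cell_id)")
    df.columns = ["species_id", "cell_id"]
    masks: dict[str, list[int]] = {}
    for sp, cell in zip(df["species_id"], df["cell_id"]):
        try:
            idx = int(cell)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path.name}: malformed cell index {cell!r} for species {sp!r}"
            ) from exc
        masks.setdefault(str(sp), []).append(idx)
    species = sorted(masks)
    return RangeMapSet(species, {sp: np.array(masks[sp]) for sp in species})


def write_range_masks(ranges: RangeMapSet, path: str | Path) -> None:
    rows = [
        (sp, int(cell)) for sp in ranges.species for cell in ranges.masks[sp]
    ]
    pd.DataFrame(rows, columns=["species_id", "cell_id"]).to_csv(
        Path(path), index=False
    )


def ranges_from_geojson(path: str | Path, grid: GridSpec) -> RangeMapSet:
    """Rasterize GeoJSON polygon ranges to fine-cell masks.

    A fine cell belongs to a species' mask if its square has a nonzero-area
    intersection with any of that species' polygons.  Features must carry a
    ``species_id`` property.  Cell squares are centered on
    :meth:`GridSpec.fine_cell_centers` with side ``cell_size_fine``.
    """
    import json

    from shapely.geometry import box, shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    if not feats:
        raise ValidationError(f"{path}: no features in GeoJSON")
    half = grid.cell_size_fine / 2.0
    centers = grid.fine_cell_centers()
    masks: dict[str, set[int]] = {}
    for feat in feats:
        sp = feat.get("properties", {}).get("species_id")
        if sp is None:
            raise ValidationError(f"{path}: feature without a species_id property")
        geom = shape(feat["geometry"])
        acc = masks.setdefault(str(sp), set())
        minx, miny, maxx, maxy = geom.bounds
        # candidate cells by bounding box, then exact area test
        for idx, (cx, cy) in enumerate(centers):
            if cx + half < minx or cx - half > maxx:
                continue
            if cy + half < miny or cy - half > maxy:
                continue
            cell = box(cx - half, cy - half, cx + half, cy + half)
            if geom.intersection(cell).area > 0.0:
                acc.add(idx)
    species = sorted(masks)
    return RangeMapSet(species, {sp: np.array(sorted(masks[sp])) for sp in species})


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def aggregate_to_coarse(occ_fine: OccurrenceMatrix, grid: GridSpec) -> OccurrenceMatrix:
    """Block-wise logical OR of fine presences into coarse presences.

    A species is present in a coarse cell if it is present in any member fine
    cell, mirroring how range-map or atlas presence is recorded for a coarse
    cell at least partially overlapped.  ``occ_fine`` may cover a subset of
    the grid's fine cells (e.g. a land mask); the coarse matrix then contains
    exactly the coarse cells with at least one member fine site, in row-major
    order.
    """
    n_cols_coarse = grid.n_cols_coarse
    block_flat = np.empty(occ_fine.n_sites, dtype=np.int64)
    for i, sid in enumerate(occ_fine.sites):
        r, c = parse_site_id(sid)
        if r >= grid.n_rows_fine or c >= grid.n_cols_fine:
            raise ValidationError(
                f"fine site {sid!r} outside {grid.n_rows_fine}x{grid.n_cols_fine} grid"
            )
        block_flat[i] = (r // grid.block_factor) * n_cols_coarse + (
            c // grid.block_factor
        )
    order = np.argsort(block_flat, kind="stable")
    blocks, starts = np.unique(block_flat[order], return_index=True)
    inc_sorted = occ_fine.incidence[order]
    coarse_inc = np.logical_or.reduceat(inc_sorted, starts, axis=0)
    coarse_ids = [
        f"r{b // n_cols_coarse}c{b % n_cols_coarse}" for b in blocks
    ]
    return OccurrenceMatrix(coarse_ids, occ_fine.species, coarse_inc, "coarse")


def rasterize_ranges(
    ranges: RangeMapSet, grid: GridSpec, resolution: str = "fine"
) -> OccurrenceMatrix:
    """Turn per-species fine-cell masks into an occurrence matrix.

    At fine resolution, ``incidence(site, sp)`` is mask membership; at coarse
    resolution the fine matrix is aggregated block-wise afterwards.
    """
    if ranges.n_species == 0:
        raise ValidationError("empty RangeMapSet: no species to rasterize")
    if resolution not in ("coarse", "fine"):
        raise ValidationError(f"resolution must be 'coarse' or 'fine', got {resolution!r}")
    n_fine = grid.n_fine
    inc = np.zeros((n_fine, ranges.n_species), dtype=bool)
    for j, sp in enumerate(ranges.species):
        cells = ranges.masks[sp]
        if cells.size and cells[-1] >= n_fine:
            raise ValidationError(
                f"mask for {sp!r} references cell {int(cells[-1])} outside grid "
                f"of {n_fine} fine cells"
            )
        inc[cells, j] = True
    occ = OccurrenceMatrix(grid.fine_site_ids(), ranges.species, inc, "fine")
    if resolution == "coarse":
        return aggregate_to_coarse(occ, grid)
    return occ
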