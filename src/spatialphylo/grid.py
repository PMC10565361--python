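"""Gridding occurrence records into a presence–absence matrix.

Cells are axis-aligned 0.1° (configurable) squares on the WGS84 graticule,
identified by integer (ix, iy) = (floor(lon/res), floor(lat/res)) so that a
cell id means the same thing across datasets; intervals are half-open
[edge, edge + res).  Only occupied cells are retained.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylo import Phylogeny, match_species

__all__ = [
    "GridSpec",
    "OccurrenceReport",
    "PresenceMatrix",
    "BranchIncidence",
    "read_occurrences",
    "assign_cell",
    "build_presence_matrix",
    "build_branch_incidence",
    "sampling_redundancy",
    "regrid",
]

# guard against float noise at cell edges: points within 1e-9 cell-widths of
# an upper edge still land in the lower cell (half-open convention)
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Graticule-aligned square grid in decimal degrees (WGS84)."""

    resolution: float = 0.1

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def cell_of(self, lon: float, lat: float) -> tuple:
        ix = math.floor(lon / self.resolution + _EDGE_EPS)
        iy = math.floor(lat / self.resolution + _EDGE_EPS)
        return (ix, iy)

    def lower_left(self, cell: tuple) -> tuple:
        return (cell[0] * self.resolution, cell[1] * self.resolution)


def assign_cell(lon: float, lat: float, grid: GridSpec) -> tuple:
    """Cell id of a point: (floor(lon/res), floor(lat/res))."""
    return grid.cell_of(lon, lat)


@dataclass
class OccurrenceReport:
    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: dict = field(default_factory=dict)

    def note(self, reason: str):
        self.n_rejected += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def read_occurrences(
    path,
    species_col: str = "species",
    lon_col: str = "decimalLongitude",
    lat_col: str = "decimalLatitude",
):
    """Read (species, lon, lat) records from CSV.

    Rows with missing or non-numeric coordinates, |lat| > 90 or |lon| > 180
    are dropped and tallied in the returned :class:`OccurrenceReport`.

    Returns ``(records, report)``.
    """
    records = []
    report = OccurrenceReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError("no records: empty occurrence file")
        missing = [c for c in (species_col, lon_col, lat_col) if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
        for row in reader:
            report.n_read += 1
            sp = (row.get(species_col) or "").strip()
            if not sp:
                report.note("empty species")
                continue
            try:
                lon = float(row[lon_col])
                lat = float(row[lat_col])
            except (TypeError, ValueError):
                report.note("non-numeric coordinates")
                continue
            if not (math.isfinite(lon) and math.isfinite(lat)):
                report.note("non-finite coordinates")
                continue
            if abs(lat) > 90 or abs(lon) > 180:
                report.note("coordinates out of bounds")
                continue
            records.append((sp, lon, lat))
            report.n_kept += 1
    if report.n_read == 0:
        raise ValueError("no records: empty occurrence file")
    return records, report


@dataclass
class PresenceMatrix:
    """Binary cells × species incidence plus raw per-cell record tallies."""

    cells: list  # ordered (ix, iy) tuples
    species: list  # ordered labels
    incidence: np.ndarray  # bool, (n_cells, n_species)
    record_count: np.ndarray  # int, per cell
    grid: GridSpec

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=bool)
        self.record_count = np.asarray(self.record_count, dtype=np.int64)
        if self.incidence.shape != (len(self.cells), len(self.species)):
            raise ValueError("incidence shape does not match cells × species")
        if len(self.cells) and not self.incidence.any(axis=1).all():
            raise ValueError("retained cells must each contain at least one species")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def richness(self) -> np.ndarray:
        """Per-cell species richness SR (row sums)."""
        return self.incidence.sum(axis=1)

    @property
    def range_size(self) -> np.ndarray:
        """Per-species range in cells occupied (column sums)."""
        return self.incidence.sum(axis=0)

    def cell_index(self, cell) -> int:
        try:
            return self.cells.index(tuple(cell))
        except ValueError:
            raise KeyError(f"unknown cell {cell!r}") from None

    def subset_species(self, keep) -> "PresenceMatrix":
        """Restrict to a species subset; cells left empty are dropped.

        record_count keeps the raw tallies of surviving cells.
        """
        keep = set(keep)
        cols = [j for j, s in enumerate(self.species) if s in keep]
        inc = self.incidence[:, cols]
        rows = np.flatnonzero(inc.any(axis=1))
        return PresenceMatrix(
            cells=[self.cells[i] for i in rows],
            species=[self.species[j] for j in cols],
            incidence=inc[rows],
            record_count=self.record_count[rows],
            grid=self.grid,
        )

    # -- exports -----------------------------------------------------------

    def to_triplets(self):
        """Sparse (cell_id, species, 1) triplets."""
        out = []
        for i, cell in enumerate(self.cells):
            for j in np.flatnonzero(self.incidence[i]):
                out.append((cell, self.species[j], 1))
        return out

    def write_triplet_csv(self, path):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_ix", "cell_iy", "species", "presence"])
            for (ix, iy), sp, v in self.to_triplets():
                w.writerow([ix, iy, sp, v])

    def write_mtx(self, path_stem):
        """Matrix Market file plus row/column label sidecars."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(f"{path_stem}.mtx", csr_matrix(self.incidence.astype(np.int8)))
        with open(f"{path_stem}.rows.txt", "w", encoding="utf-8") as fh:
            for ix, iy in self.cells:
                fh.write(f"{ix},{iy}\n")
        with open(f"{path_stem}.cols.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.species) + "\n")

    def cells_geojson(self) -> dict:
        """Cell squares as a GeoJSON FeatureCollection."""
        res = self.grid.resolution
        feats = []
        for ix, iy in self.cells:
            x0, y0 = ix * res, iy * res
            ring = [[x0, y0], [x0 + res, y0], [x0 + res, y0 + res], [x0, y0 + res], [x0, y0]]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"cell_ix": ix, "cell_iy": iy},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.cells_geojson(), fh)


def build_presence_matrix(records, grid: GridSpec, extent=None) -> PresenceMatrix:
    """Grid records into a presence matrix.

    Duplicate (species, cell) pairs collapse to a single presence while
    ``record_count`` keeps the raw tallies.  ``extent``, if given, is a
    (lon_min, lat_min, lon_max, lat_max) filter applied before gridding.
    """
    if not records:
        raise ValueError("no records")
    cell_species: dict = {}
    cell_records: dict = {}
    for sp, lon, lat in records:
        if extent is not None:
            x0, y0, x1, y1 = extent
            if not (x0 <= lon <= x1 and y0 <= lat <= y1):
                continue
        cell = grid.cell_of(lon, lat)
        cell_species.setdefault(cell, set()).add(sp)
        cell_records[cell] = cell_records.get(cell, 0) + 1
    if not cell_species:
        raise ValueError("no cells retained: all records outside configured extent")
    cells = sorted(cell_species)
    species = sorted({sp for s in cell_species.values() for sp in s})
    sp_index = {s: j for j, s in enumerate(species)}
    inc = np.zeros((len(cells), len(species)), dtype=bool)
    for i, cell in enumerate(cells):
        for sp in cell_species[cell]:
            inc[i, sp_index[sp]] = True
    counts = np.array([cell_records[c] for c in cells], dtype=np.int64)
    return PresenceMatrix(cells, species, inc, counts, grid)


@dataclass
class BranchIncidence:
    """Binary cells × branches incidence derived from a presence matrix.

    A branch is present in a cell iff at least one of its descendant tips
    is; its range R_b is the number of cells it occupies.  Branch columns
    follow the tree's branch order; tip columns therefore equal the species
    columns of the presence matrix they came from.
    """

    cells: list
    branch_ids: list
    incidence: np.ndarray  # bool, (n_cells, n_branches)
    branch_length: np.ndarray  # L_b per branch
    species: list  # species actually mapped onto the tree
    ancestry: np.ndarray  # bool, (n_species, n_branches)

    @property
    def branch_range(self) -> np.ndarray:
        """R_b: cells occupied per branch."""
        return self.incidence.sum(axis=0)

    def cell_index(self, cell) -> int:
        try:
            return self.cells.index(tuple(cell))
        except ValueError:
            raise KeyError(f"unknown cell {cell!r}") from None


def build_branch_incidence(pm: PresenceMatrix, tree: Phylogeny) -> BranchIncidence:
    """Derive branch incidences as the union of descendant-tip presences.

    Species not on the tree are dropped with a warning; cells left empty by
    that drop are excluded.
    """
    report = match_species(tree, pm.species)
    if not report.matched:
        raise ValueError("no species shared between presence matrix and tree")
    if report.occurrences_only:
        warnings.warn(
            f"{len(report.occurrences_only)} species not on the tree dropped "
            "from branch incidence",
            stacklevel=2,
        )
        pm = pm.subset_species(report.matched_occurrence)
    # pm species names may differ from tree labels in normalization only
    occ_to_tree = dict(zip(report.matched_occurrence, report.matched_tree))
    anc = tree.descendant_tip_matrix([occ_to_tree[s] for s in pm.species])
    inc = pm.incidence @ anc  # bool matmul: OR over descendant tips
    return BranchIncidence(
        cells=list(pm.cells),
        branch_ids=tree.branch_ids(),
        incidence=inc,
        branch_length=tree.lengths[tree.branch_indices()].copy(),
        species=list(pm.species),
        ancestry=anc,
    )


def sampling_redundancy(pm: PresenceMatrix) -> np.ndarray:
    """Per-cell inventory completeness proxy: 1 − SR / records, in [0, 1]."""
    sr = pm.richness
    if np.any(pm.record_count < sr):
        raise ValueError("record_count cannot be below richness")
    return 1.0 - sr / pm.record_count


def regrid(pm: PresenceMatrix, factor: int) -> PresenceMatrix:
    """Aggregate to a coarser grid: presence = OR over the factor × factor
    block of fine cells, record counts summed."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("regrid factor must be a positive integer")
    if factor == 1:
        return pm
    coarse_grid = GridSpec(resolution=pm.grid.resolution * factor)
    mapping: dict = {}
    for i, (ix, iy) in enumerate(pm.cells):
        coarse = (ix // factor, iy // factor)
        mapping.setdefault(coarse, []).append(i)
    cells = sorted(mapping)
    inc = np.zeros((len(cells), pm.n_species), dtype=bool)
    counts = np.zeros(len(cells), dtype=np.int64)
    for k, cell in enumerate(cells):
        rows = mapping[cell]
        inc[k] = pm.incidence[rows].any(axis=0)
        counts[k] = pm.record_count[rows].sum()
    return PresenceMatrix(cells, list(pm.species), inc, counts, coarse_grid)
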