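"""Planning grid, presence-background dataset variants, and related utilities.

The landscape is a rectangular grid of square planning units (default side
11 km) on a planar km coordinate system.  Point records are converted to
unit-level presences by five rules: raw points, 50-km buffer, 150-km buffer,
bounding box, and bounding box filtered by the species' elevation range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

VARIANTS = ("points", "buffer50", "buffer150", "bbox", "elevation")


@dataclass
class PlanningGrid:
    """Rectangular grid of square planning units on planar km coordinates.

    Unit ids run row-major: ``unit = ix + iy * n_x``.  Adjacency is rook
    (shared edges); edges on the outer perimeter are counted separately so
    the prioritization boundary penalty can weight them by an edge factor.
    """

    n_x: int
    n_y: int
    side: float = 11.0

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_units(self) -> int:
        return self.n_x * self.n_y

    @property
    def unit_ids(self) -> np.ndarray:
        return np.arange(self.n_units)

    @property
    def centroids(self) -> np.ndarray:
        ix = np.arange(self.n_units) % self.n_x
        iy = np.arange(self.n_units) // self.n_x
        return np.column_stack([(ix + 0.5) * self.side, (iy + 0.5) * self.side])

    @property
    def adjacency(self) -> list[tuple[int, int]]:
        """Rook-neighbor unit pairs (u < v)."""
        pairs = []
        for u in range(self.n_units):
            ix, iy = u % self.n_x, u // self.n_x
            if ix + 1 < self.n_x:
                pairs.append((u, u + 1))
            if iy + 1 < self.n_y:
                pairs.append((u, u + self.n_x))
        return pairs

    @property
    def n_neighbors(self) -> np.ndarray:
        counts = np.zeros(self.n_units, dtype=int)
        for u, v in self.adjacency:
            counts[u] += 1
            counts[v] += 1
        return counts

    @property
    def outer_edges(self) -> np.ndarray:
        """Number of cell sides each unit exposes on the grid's outer perimeter."""
        return 4 - self.n_neighbors

    def unit_of_point(self, x: float, y: float) -> int:
        """Half-open cell membership ``[x0, x1) x [y0, y1)``.

        Points on the outermost upper/right boundary are clamped into the
        last cell; points outside the grid return -1.
        """
        if not (0.0 <= x <= self.n_x * self.side and 0.0 <= y <= self.n_y * self.side):
            return -1
        ix = min(int(x // self.side), self.n_x - 1)
        iy = min(int(y // self.side), self.n_y - 1)
        return ix + iy * self.n_x

    def to_geojson(self, path=None) -> dict:
        feats = []
        for u in range(self.n_units):
            ix, iy = u % self.n_x, u // self.n_x
            x0, y0 = ix * self.side, iy * self.side
            x1, y1 = x0 + self.side, y0 + self.side
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"unit_id": int(u)},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                        ],
                    },
                }
            )
        gj = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(gj, fh)
        return gj


@dataclass
class PresenceMatrix:
    """Binary species x planning-unit presences for one dataset variant."""

    species: list[str]
    matrix: np.ndarray  # (S, M) of {0, 1}
    variant: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, [0, 1]).all():
            raise ValueError("presence matrix must be binary")
        self.matrix = self.matrix.astype(np.int8)
        if self.matrix.shape[0] != len(self.species):
            raise ValueError("species list and matrix rows do not match")

    @property
    def empty_species(self) -> list[str]:
        """Species present in zero units (flagged, not dropped)."""
        return [s for s, row in zip(self.species, self.matrix) if row.sum() == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.species, name="species"),
            columns=[f"unit_{u}" for u in range(self.matrix.shape[1])],
        )


def _records_by_species(records: pd.DataFrame, species: list[str]):
    unknown = sorted(set(records["species"]) - set(species))
    if unknown:
        raise ValueError(f"unknown species in records: {unknown}")
    return {
        sp: grp[["x_km", "y_km"]].to_numpy(float)
        for sp, grp in records.groupby("species")
    }


def assign_points_to_units(
    records: pd.DataFrame, grid: PlanningGrid, species: list[str]
) -> tuple[PresenceMatrix, pd.DataFrame]:
    """Raw-points variant: a unit is present iff >= 1 record falls in it.

    Returns the presence matrix and a frame of dropped (out-of-bounds)
    records.
    """
    by_sp = _records_by_species(records, species)
    M = grid.n_units
    mat = np.zeros((len(species), M), dtype=np.int8)
    dropped = []
    for i, sp in enumerate(species):
        for x, y in by_sp.get(sp, np.empty((0, 2))):
            u = grid.unit_of_point(x, y)
            if u < 0:
                dropped.append({"species": sp, "x_km": x, "y_km": y})
            else:
                mat[i, u] = 1
    return PresenceMatrix(species, mat, "points"), pd.DataFrame(
        dropped, columns=["species", "x_km", "y_km"]
    )


def buffer_presence(
    records: pd.DataFrame, grid: PlanningGrid, radius_km: float, species: list[str]
) -> PresenceMatrix:
    """Unit present iff its centroid lies within ``radius_km`` of any record."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    by_sp = _records_by_species(records, species)
    cents = grid.centroids
    mat = np.zeros((len(species), grid.n_units), dtype=np.int8)
    for i, sp in enumerate(species):
        pts = by_sp.get(sp)
        if pts is None or len(pts) == 0:
            continue
        d = cdist(cents, pts)
        mat[i] = (d.min(axis=1) <= radius_km).astype(np.int8)
    variant = f"buffer{int(radius_km)}" if radius_km in (50.0, 150.0) else "buffer"
    return PresenceMatrix(species, mat, variant)


def bbox_presence(
    records: pd.DataFrame, grid: PlanningGrid, species: list[str]
) -> PresenceMatrix:
    """Unit present iff its centroid lies in the closed bounding box of records."""
    by_sp = _records_by_species(records, species)
    cents = grid.centroids
    mat = np.zeros((len(species), grid.n_units), dtype=np.int8)
    for i, sp in enumerate(species):
        pts = by_sp.get(sp)
        if pts is None or len(pts) == 0:
            continue
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        inside = (
            (cents[:, 0] >= lo[0])
            & (cents[:, 0] <= hi[0])
            & (cents[:, 1] >= lo[1])
            & (cents[:, 1] <= hi[1])
        )
        mat[i] = inside.astype(np.int8)
        # the bbox always contains the units holding the records themselves
        for x, y in pts:
            u = grid.unit_of_point(x, y)
            if u >= 0:
                mat[i, u] = 1
    return PresenceMatrix(species, mat, "bbox")


def elevation_presence(
    records: pd.DataFrame,
    grid: PlanningGrid,
    unit_elev_range: np.ndarray,
    species_elev_range: dict,
    species: list[str],
    base: str = "bbox",
) -> PresenceMatrix:
    """Elevation-filtered variant.

    Starting from the bounding-box variant (or raw points with
    ``base='points'``), a unit is retained iff its elevation interval
    overlaps the species' recorded elevation range (closed intervals).
    """
    if base == "bbox":
        pm = bbox_presence(records, grid, species)
    elif base == "points":
        pm, _ = assign_points_to_units(records, grid, species)
    else:
        raise ValueError(f"unknown base variant {base!r}")
    unit_elev_range = np.asarray(unit_elev_range, float)
    mat = pm.matrix.copy()
    for i, sp in enumerate(species):
        if sp not in species_elev_range:
            continue
        lo, hi = species_elev_range[sp]
        if lo > hi:
            raise ValueError(f"species {sp}: elevation min {lo} > max {hi}")
        overlap = (unit_elev_range[:, 0] <= hi) & (unit_elev_range[:, 1] >= lo)
        mat[i] &= overlap.astype(np.int8)
    return PresenceMatrix(species, mat, "elevation")


def make_variants(
    records: pd.DataFrame,
    grid: PlanningGrid,
    unit_elev_range: np.ndarray,
    species_elev_range: dict,
    species: list[str],
) -> dict[str, PresenceMatrix]:
    """All five presence-background variants from one set of point records."""
    points, _ = assign_points_to_units(records, grid, species)
    return {
        "points": points,
        "buffer50": buffer_presence(records, grid, 50.0, species),
        "buffer150": buffer_presence(records, grid, 150.0, species),
        "bbox": bbox_presence(records, grid, species),
        "elevation": elevation_presence(
            records, grid, unit_elev_range, species_elev_range, species
        ),
    }


@dataclass
class EnvSelection:
    selected: list[str]
    variance_explained: np.ndarray  # fraction of total variance per axis
    correlations: pd.DataFrame = field(repr=False, default=None)


def env_select_pca(env_table: pd.DataFrame, n_axes: int = 3) -> EnvSelection:
    """Pick the variable most correlated with each leading PC axis.

    The table is z-scored, a PCA is run, and for each of the first
    ``n_axes`` axes the variable with the greatest absolute Pearson
    correlation with the axis scores is selected (ties broken by column
    order; a variable already selected for an earlier axis is skipped so
    the selection contains distinct variables).
    """
    if env_table.shape[1] < n_axes:
        raise ValueError("need at least as many variables as axes")
    if env_table.shape[0] < n_axes + 1:
        raise ValueError("need more units than axes")
    X = env_table.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < n_axes:
        raise ValueError(f"environmental table has rank < {n_axes}")
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(Z)
    cors = np.zeros((env_table.shape[1], n_axes))
    for j in range(env_table.shape[1]):
        col = Z[:, j]
        if col.std() == 0:
            continue
        for a in range(n_axes):
            cors[j, a] = np.corrcoef(col, scores[:, a])[0, 1]
    selected = []
    for a in range(n_axes):
        order = np.argsort(-np.abs(cors[:, a]), kind="stable")
        pick = next(
            j for j in order if env_table.columns[j] not in selected
        )
        selected.append(env_table.columns[pick])
    return EnvSelection(
        selected=selected,
        variance_explained=pca.explained_variance_ratio_.copy(),
        correlations=pd.DataFrame(
            cors, index=env_table.columns, columns=[f"PC{a+1}" for a in range(n_axes)]
        ),
    )


def rarity_quartiles(variants: dict[str, PresenceMatrix]) -> pd.Series:
    """Rarity quartile (1 = rarest) from mean presence counts across variants.

    Quartiles are assigned by rank of the mean count; tied means share the
    lower (rarer) quartile.
    """
    mats = list(variants.values())
    species = mats[0].species
    for pm in mats[1:]:
        if pm.species != species:
            raise ValueError("variants must share an identical species order")
    means = np.mean([pm.matrix.sum(axis=1) for pm in mats], axis=0)
    S = len(species)
    ranks = pd.Series(means).rank(method="min")  # 1-based, ties -> lower rank
    quart = np.ceil(4 * ranks / S).astype(int).clip(1, 4)
    return pd.Series(quart.to_numpy(), index=pd.Index(species, name="species"), name="quartile")


def mean_presences(variants: dict[str, PresenceMatrix]) -> float:
    """Species mean number of unit presences across the dataset variants."""
    return float(
        np.mean([pm.matrix.sum(axis=1) for pm in variants.values()])
    )
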