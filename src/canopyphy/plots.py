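"""Mapped census plots and exact neighborhood richness.

The individual species-area relationship (ISAR) of a focal species is the
expected number of *other* species found within nested circular
neighborhoods around an average conspecific individual.  This module holds
the data model for a mapped plot (a rectangular window plus a stem table)
and the exact, non-randomized parts of the ISAR computation: focal
eligibility under an edge buffer, neighborhood species sets, and the
observed mean-richness curve.

Distances are Euclidean meters; disc membership is closed (``d <= r``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TreeRecord",
    "CensusPlot",
    "RadiusGrid",
    "ISAR_RADII",
    "IPAR_RADII",
    "eligible_focals",
    "neighborhood_species",
    "isar_curve",
]


@dataclass(frozen=True)
class TreeRecord:
    """A single mapped stem: identity, species, location (m), dbh (cm)."""

    stem_id: str
    species_id: str
    x: float
    y: float
    dbh: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"stem {self.stem_id}: non-finite coordinates")
        if not self.dbh > 0:
            raise ValueError(f"stem {self.stem_id}: dbh must be > 0, got {self.dbh}")


class CensusPlot:
    """A rectangular plot window plus its mapped, identified stems.

    Parameters
    ----------
    window : tuple of float
        ``(xmin, ymin, xmax, ymax)`` in meters.
    stems : iterable of TreeRecord
        All mapped stems; every stem must lie inside the window
        (boundary inclusive).

    Stems are stored internally as flat numpy arrays for speed; the
    record view is available through :meth:`to_frame` and ``iter_stems``.
    """

    def __init__(self, window: tuple[float, float, float, float],
                 stems: Iterable[TreeRecord]):
        xmin, ymin, xmax, ymax = map(float, window)
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate window {window}")
        self.window = (xmin, ymin, xmax, ymax)

        stems = list(stems)
        if not stems:
            raise ValueError("a census plot needs at least one stem")
        self.stem_ids = np.array([s.stem_id for s in stems], dtype=object)
        self.species = np.array([s.species_id for s in stems], dtype=object)
        self.x = np.array([s.x for s in stems], dtype=float)
        self.y = np.array([s.y for s in stems], dtype=float)
        self.dbh = np.array([s.dbh for s in stems], dtype=float)

        inside = ((self.x >= xmin) & (self.x <= xmax)
                  & (self.y >= ymin) & (self.y <= ymax))
        if not inside.all():
            bad = self.stem_ids[~inside][:5]
            raise ValueError(f"stems outside window: {list(bad)} ...")

        self._kdtree: cKDTree | None = None

    # -- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return self.x.size

    @property
    def n_stems(self) -> int:
        return self.x.size

    @property
    def species_ids(self) -> list[str]:
        """Sorted unique species identities present in the plot."""
        return sorted(set(self.species.tolist()))

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def abundance(self) -> pd.Series:
        return pd.Series(self.species).value_counts().sort_index()

    def iter_stems(self):
        for i in range(len(self)):
            yield TreeRecord(self.stem_ids[i], self.species[i],
                             self.x[i], self.y[i], self.dbh[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stem_id": self.stem_ids, "species": self.species,
            "x": self.x, "y": self.y, "dbh": self.dbh,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   window: tuple[float, float, float, float]) -> "CensusPlot":
        stems = [TreeRecord(str(r.stem_id), str(r.species), float(r.x),
                            float(r.y), float(r.dbh))
                 for r in df.itertuples(index=False)]
        return cls(window, stems)

    # -- filters -------------------------------------------------------
    def filter(self, dbh_min: float = 0.0, abundance_min: int = 0) -> "CensusPlot":
        """Return a new plot keeping stems with ``dbh >= dbh_min`` and
        species with at least ``abundance_min`` such stems.

        The dbh filter runs first, so the abundance threshold counts only
        stems that pass it (the census variants this mirrors count
        individuals at or above the size cut).
        """
        keep = self.dbh >= dbh_min
        if abundance_min > 0:
            counts = pd.Series(self.species[keep]).value_counts()
            ok = set(counts.index[counts >= abundance_min])
            keep &= np.array([s in ok for s in self.species])
        if not keep.any():
            raise ValueError("filter removed every stem")
        sub = CensusPlot.__new__(CensusPlot)
        sub.window = self.window
        for name in ("stem_ids", "species", "x", "y", "dbh"):
            setattr(sub, name, getattr(self, name)[keep])
        sub._kdtree = None
        return sub

    # -- geometry ------------------------------------------------------
    def edge_distance(self) -> np.ndarray:
        """Distance of each stem to the nearest window edge."""
        xmin, ymin, xmax, ymax = self.window
        return np.minimum.reduce([self.x - xmin, xmax - self.x,
                                  self.y - ymin, ymax - self.y])

    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.coords)
        return self._kdtree


class RadiusGrid:
    """Strictly increasing neighborhood radii in meters."""

    def __init__(self, radii: Sequence[float]):
        r = np.asarray(radii, dtype=float)
        if r.ndim != 1 or r.size == 0:
            raise ValueError("radii must be a non-empty 1-d sequence")
        if not (r > 0).all():
            raise ValueError("radii must be positive")
        if not (np.diff(r) > 0).all():
            raise ValueError("radii must be strictly increasing")
        self.radii = r

    def __iter__(self):
        return iter(self.radii)

    def __len__(self):
        return self.radii.size

    @property
    def max(self) -> float:
        return float(self.radii[-1])


#: Default ISAR grid: 1..50 m in 1 m increments.
ISAR_RADII = RadiusGrid(np.arange(1.0, 51.0))
#: Default IPAR grid: 1..10, 15, 20, 30, 40, 50 m.
IPAR_RADII = RadiusGrid(list(range(1, 11)) + [15, 20, 30, 40, 50])


class SpeciesAbsentError(KeyError):
    """Requested focal species does not occur in the plot at all."""


def eligible_focals(plot: CensusPlot, species: str, buffer: float) -> np.ndarray:
    """Indices of stems of ``species`` at least ``buffer`` m from every edge.

    Raises :class:`SpeciesAbsentError` if the species has no stems in the
    plot — distinguishable from a species that is present but whose stems
    all sit within the buffer (empty index array).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    is_sp = plot.species == species
    if not is_sp.any():
        raise SpeciesAbsentError(species)
    return np.flatnonzero(is_sp & (plot.edge_distance() >= buffer))


def _neighbor_species_min_dist(plot: CensusPlot, focal_xy: np.ndarray,
                               focal_species: str, r_max: float,
                               focal_index: int | None = None,
                               include_focal_species: bool = False):
    """Species of stems within ``r_max`` of a point and their minimal distances.

    Returns ``(species_labels, min_dists)`` where each species appears once
    with the distance of its nearest stem.  The focal stem itself (by index)
    is always excluded; conspecifics are excluded unless
    ``include_focal_species``.
    """
    idx = plot.kdtree().query_ball_point(focal_xy, r_max)
    idx = np.asarray(idx, dtype=int)
    if focal_index is not None:
        idx = idx[idx != focal_index]
    if idx.size == 0:
        return np.empty(0, dtype=object), np.empty(0)
    sp = plot.species[idx]
    if not include_focal_species:
        keep = sp != focal_species
        idx, sp = idx[keep], sp[keep]
        if idx.size == 0:
            return np.empty(0, dtype=object), np.empty(0)
    d = np.hypot(plot.x[idx] - focal_xy[0], plot.y[idx] - focal_xy[1])
    order = np.argsort(d, kind="stable")
    sp, d = sp[order], d[order]
    uniq, first = np.unique(sp, return_index=True)
    return uniq, d[first]


def neighborhood_species(plot: CensusPlot, focal: TreeRecord | int, r: float,
                         include_focal_species: bool = False) -> set[str]:
    """Species found within ``r`` m of a focal stem (closed disc).

    The focal stem is never its own neighbor; by default the focal
    *species* is excluded entirely, so richness counts heterospecifics
    only.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if isinstance(focal, TreeRecord):
        matches = np.flatnonzero(
            (plot.stem_ids == focal.stem_id) & (plot.x == focal.x)
            & (plot.y == focal.y))
        if matches.size == 0:
            raise ValueError(f"focal stem {focal.stem_id} not in plot")
        i = int(matches[0])
    else:
        i = int(focal)
    xy = np.array([plot.x[i], plot.y[i]])
    sp, d = _neighbor_species_min_dist(
        plot, xy, plot.species[i], r, focal_index=i,
        include_focal_species=include_focal_species)
    return set(sp[d <= r].tolist())


def _richness_curve_for_points(plot: CensusPlot, pts: np.ndarray,
                               species: str, radii: np.ndarray,
                               exclude_indices: np.ndarray | None = None,
                               include_focal_species: bool = False) -> np.ndarray:
    """Mean heterospecific richness curve over arbitrary focal points.

    ``exclude_indices`` maps each focal point to a stem index to ignore
    (the focal stem itself when points are real stems).  Used both for the
    observed curve and, with simulated points, inside the null model.
    """
    r_max = float(radii[-1])
    curves = np.zeros((len(pts), radii.size))
    for k, xy in enumerate(pts):
        fi = None if exclude_indices is None else int(exclude_indices[k])
        _, mind = _neighbor_species_min_dist(
            plot, xy, species, r_max, focal_index=fi,
            include_focal_species=include_focal_species)
        # richness at r = number of species whose nearest stem is <= r
        curves[k] = np.searchsorted(np.sort(mind), radii, side="right")
    return curves.mean(axis=0)


def isar_curve(plot: CensusPlot, species: str,
               radii: RadiusGrid | Sequence[float] = ISAR_RADII,
               buffer: float = 50.0,
               include_focal_species: bool = False):
    """Observed ISAR: mean neighborhood richness per radius.

    Returns ``(curve, n_focals)`` where ``curve`` is the arithmetic mean
    over eligible focal stems of the number of (by default heterospecific)
    species within each radius.

    Raises ``ValueError`` when the species has no eligible focal.
    """
    grid = radii if isinstance(radii, RadiusGrid) else RadiusGrid(radii)
    foc = eligible_focals(plot, species, buffer)
    if foc.size == 0:
        raise ValueError(
            f"species {species!r}: no focal at least {buffer} m from the edge")
    pts = plot.coords[foc]
    curve = _richness_curve_for_points(
        plot, pts, species, grid.radii, exclude_indices=foc,
        include_focal_species=include_focal_species)
    return curve, int(foc.size)
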