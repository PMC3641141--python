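"""ISAR inference: heterogeneous Poisson null and accumulator/repeller calls.

For each target species the null model keeps every other species' stems
fixed and relocates only the target's stems, drawing them from an
Epanechnikov-kernel intensity (bandwidth 50 m by default) fitted to the
target's own observed pattern.  Repeating this 999 times yields a null
distribution of mean-richness curves; the observed curve is compared
pointwise at each radius:

* observed above the upper ``alpha/2`` empirical quantile -> *accumulator*
* below the lower quantile -> *repeller*
* otherwise -> *neutral*

A species receives one designation per radius, so it may be an
accumulator at 5 m and neutral at 30 m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .intensity import epanechnikov_intensity, simulate_heterogeneous_poisson
from .plots import (CensusPlot, RadiusGrid, ISAR_RADII, TreeRecord,
                    eligible_focals, _richness_curve_for_points)

__all__ = ["NullEnsemble", "isar_null", "classify", "IsarClassifier",
           "ACCUMULATOR", "REPELLER", "NEUTRAL"]

logger = logging.getLogger(__name__)

ACCUMULATOR = "accumulator"
REPELLER = "repeller"
NEUTRAL = "neutral"


@dataclass
class NullEnsemble:
    """Simulated mean-richness curves for one species: shape (n_sim, n_radii)."""

    radii: np.ndarray
    curves: np.ndarray

    @property
    def n_sim(self) -> int:
        return self.curves.shape[0]

    def quantile(self, q: float) -> np.ndarray:
        return np.nanquantile(self.curves, q, axis=0)


def _median_dbh(plot: CensusPlot, species: str) -> float:
    return float(np.median(plot.dbh[plot.species == species]))


def isar_null(plot: CensusPlot, species: str,
              radii: RadiusGrid | np.ndarray = ISAR_RADII,
              n_sim: int = 999, buffer: float = 50.0,
              bandwidth: float = 50.0, cell: float = 1.0,
              include_focal_species: bool = False,
              rng: np.random.Generator | int | None = None) -> NullEnsemble:
    """Null ensemble of ISAR curves for one target species.

    Each iteration relocates the target species' stems via a heterogeneous
    Poisson draw from the intensity fitted to its observed pattern, keeps
    all other stems bit-identical, and recomputes the mean richness curve
    over the relocated stems that satisfy the edge buffer.  Iterations
    where no relocated stem is eligible are recorded as NaN rows (they are
    vanishingly rare for realistic plots) and ignored by quantiles.
    """
    grid = radii if isinstance(radii, RadiusGrid) else RadiusGrid(radii)
    rng = np.random.default_rng(rng)

    is_target = plot.species == species
    if not is_target.any():
        raise KeyError(species)
    n_target = int(is_target.sum())
    target_pts = plot.coords[is_target]
    surface = epanechnikov_intensity(target_pts, plot.window,
                                     bandwidth=bandwidth, cell=cell)

    others_mask = ~is_target
    xmin, ymin, xmax, ymax = plot.window
    sim_dbh = _median_dbh(plot, species)

    if include_focal_species:
        base_records = [TreeRecord(plot.stem_ids[i], plot.species[i],
                                   plot.x[i], plot.y[i], plot.dbh[i])
                        for i in np.flatnonzero(others_mask)]
        others_plot = None
    elif others_mask.any():
        others_plot = CensusPlot.__new__(CensusPlot)
        others_plot.window = plot.window
        for name in ("stem_ids", "species", "x", "y", "dbh"):
            setattr(others_plot, name, getattr(plot, name)[others_mask])
        others_plot._kdtree = None
    else:
        others_plot = None  # monospecific plot: richness identically 0

    curves = np.full((n_sim, len(grid)), np.nan)
    for s in range(n_sim):
        pts = simulate_heterogeneous_poisson(surface, n_target, rng)
        np.clip(pts[:, 0], xmin, xmax, out=pts[:, 0])
        np.clip(pts[:, 1], ymin, ymax, out=pts[:, 1])
        edge = np.minimum.reduce([pts[:, 0] - xmin, xmax - pts[:, 0],
                                  pts[:, 1] - ymin, ymax - pts[:, 1]])
        foc = pts[edge >= buffer]
        if foc.shape[0] == 0:
            continue
        if include_focal_species:
            sim_plot = CensusPlot(plot.window, base_records + [
                TreeRecord(f"__sim{k}", species, p[0], p[1], sim_dbh)
                for k, p in enumerate(pts)])
            sim_idx = np.flatnonzero(sim_plot.species == species)
            sim_elig = sim_idx[edge >= buffer]
            curves[s] = _richness_curve_for_points(
                sim_plot, foc, species, grid.radii,
                exclude_indices=sim_elig, include_focal_species=True)
        elif others_plot is None:
            curves[s] = 0.0
        else:
            curves[s] = _richness_curve_for_points(
                others_plot, foc, species, grid.radii)
    return NullEnsemble(radii=grid.radii.copy(), curves=curves)


def classify(observed: np.ndarray, ensemble: NullEnsemble,
             alpha: float = 0.05) -> np.ndarray:
    """Pointwise two-sided Monte-Carlo designation per radius.

    With 999 simulations and ``alpha = 0.05`` a radius is called
    accumulator when the observed value exceeds at least 975 of the 999
    null values (rank >= 976 of the 1000 pooled values) and repeller
    symmetrically.  Ties between observed and null values count against
    significance on both sides, i.e. break toward neutral.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape[0] != ensemble.curves.shape[1]:
        raise ValueError("observed curve and ensemble use different radius grids")
    valid = ~np.isnan(ensemble.curves)
    n_valid = valid.sum(axis=0)
    n_ge = np.nansum(ensemble.curves >= observed[None, :], axis=0)
    n_le = np.nansum(ensemble.curves <= observed[None, :], axis=0)
    p_up = (1.0 + n_ge) / (n_valid + 1.0)
    p_lo = (1.0 + n_le) / (n_valid + 1.0)
    status = np.full(observed.shape, NEUTRAL, dtype=object)
    status[p_up <= alpha / 2.0] = ACCUMULATOR
    status[p_lo <= alpha / 2.0] = REPELLER
    return status


class IsarClassifier(BaseEstimator):
    """Per-scale accumulator/repeller/neutral classification of species.

    scikit-learn style estimator: construct with hyper-parameters, call
    :meth:`fit` with a :class:`~canopyphy.plots.CensusPlot`, then read the
    fitted attributes.

    Parameters
    ----------
    radii : sequence of float, default 1..50 m
        Neighborhood radii.
    buffer : float, default 50.0
        Focal stems must be at least this far from every plot edge.
    n_sim : int, default 999
        Null-model iterations per species.
    alpha : float, default 0.05
        Two-sided pointwise significance level.
    bandwidth, cell : float
        Epanechnikov kernel bandwidth and lattice cell size (m).
    include_focal_species : bool, default False
        Count conspecifics toward neighborhood richness.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    results_ : pandas.DataFrame
        Tidy table: species, radius_m, n_focals, obs_mean_richness,
        null_mean, null_q025, null_q975, status.
    status_ : pandas.DataFrame
        species x radius pivot of designations.
    skipped_ : dict
        Species excluded from inference, mapped to the reason.
    """

    def __init__(self, radii=None, buffer: float = 50.0, n_sim: int = 999,
                 alpha: float = 0.05, bandwidth: float = 50.0,
                 cell: float = 1.0, include_focal_species: bool = False,
                 random_state=None):
        self.radii = radii
        self.buffer = buffer
        self.n_sim = n_sim
        self.alpha = alpha
        self.bandwidth = bandwidth
        self.cell = cell
        self.include_focal_species = include_focal_species
        self.random_state = random_state

    def _grid(self) -> RadiusGrid:
        if self.radii is None:
            return ISAR_RADII
        return self.radii if isinstance(self.radii, RadiusGrid) \
            else RadiusGrid(self.radii)

    def fit(self, plot: CensusPlot, species: list[str] | None = None):
        """Run observed curves, null ensembles and designations.

        ``species`` restricts the analysis; by default every species in
        the plot is attempted and those without eligible focals are
        reported in ``skipped_``.
        """
        if not isinstance(plot, CensusPlot):
            raise TypeError("fit expects a CensusPlot")
        grid = self._grid()
        todo = sorted(species) if species is not None else plot.species_ids
        seed_seq = np.random.SeedSequence(
            self.random_state if isinstance(self.random_state, (int, np.integer))
            else None) if not isinstance(self.random_state, np.random.Generator) \
            else None

        rows = []
        self.skipped_ = {}
        self.ensembles_ = {}
        children = (seed_seq.spawn(len(todo)) if seed_seq is not None
                    else [None] * len(todo))
        for sp, child in zip(todo, children):
            foc = eligible_focals(plot, sp, self.buffer)
            if foc.size == 0:
                self.skipped_[sp] = "no focal outside edge buffer"
                logger.info("skipping %s: no eligible focal", sp)
                continue
            pts = plot.coords[foc]
            obs = _richness_curve_for_points(
                plot, pts, sp, grid.radii, exclude_indices=foc,
                include_focal_species=self.include_focal_species)
            rng = (np.random.default_rng(child) if child is not None
                   else self.random_state)
            ens = isar_null(plot, sp, grid, n_sim=self.n_sim,
                            buffer=self.buffer, bandwidth=self.bandwidth,
                            cell=self.cell,
                            include_focal_species=self.include_focal_species,
                            rng=rng)
            status = classify(obs, ens, alpha=self.alpha)
            self.ensembles_[sp] = ens
            if np.isnan(ens.curves).all():
                logger.warning("%s: no null iteration kept an eligible "
                               "focal; designations forced neutral", sp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append(pd.DataFrame({
                    "species": sp, "radius_m": grid.radii,
                    "n_focals": foc.size, "obs_mean_richness": obs,
                    "null_mean": np.nanmean(ens.curves, axis=0),
                    "null_q025": ens.quantile(0.025),
                    "null_q975": ens.quantile(0.975),
                    "status": status,
                }))
        self.results_ = (pd.concat(rows, ignore_index=True) if rows
                         else pd.DataFrame(columns=[
                             "species", "radius_m", "n_focals",
                             "obs_mean_richness", "null_mean", "null_q025",
                             "null_q975", "status"]))
        if rows:
            self.status_ = self.results_.pivot(index="species",
                                               columns="radius_m",
                                               values="status")
        else:
            self.status_ = pd.DataFrame()
        return self
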