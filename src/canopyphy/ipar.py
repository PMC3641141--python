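"""Individual phylogenetic-area relationships (IPAR) and S.E.S. PD.

The IPAR replaces neighborhood species richness with Faith's phylogenetic
diversity (PD): for an average individual of a focal species it reports
the PD of the species found within nested circular neighborhoods (grid
1-10, 15, 20, 30, 40, 50 m by default).

Because PD scales with richness, the observed neighborhood PD is compared
with a *compositional* null rather than a spatial one: species names are
shuffled across the tips of the plot phylogeny (999 times by default) and
the neighborhood PD recomputed each time.  The standardized effect size

    S.E.S. PD = (PD_obs - mean PD_null) / sd PD_null

is positive when the average individual's neighborhood is more
phylogenetically diverse than expected for its richness and negative when
less.  Species significantly above / below the null are *phylogenetic
accumulators* / *repellers*, mirroring the richness-based designations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .isar import ACCUMULATOR, NEUTRAL, REPELLER
from .phylotree import Phylogeny
from .plots import (CensusPlot, IPAR_RADII, RadiusGrid,
                    _neighbor_species_min_dist, eligible_focals)

__all__ = ["SesPd", "ipar_observed", "ses_pd", "nri_nti", "IparAnalysis"]


@dataclass
class SesPd:
    """S.E.S. PD of one species at one radius."""

    radius: float
    observed_pd: float
    null_mean: float
    null_sd: float
    ses: float
    i: int           # focal individuals averaged
    j: int           # null values
    status: str
    flag: str = ""


def _membership_matrix(plot: CensusPlot, tree: Phylogeny, species: str,
                       radii: np.ndarray, buffer: float,
                       include_focal_species: bool):
    """Boolean (n_focals * n_radii, n_tips) neighborhood membership rows.

    Row ``f * n_radii + r`` marks which phylogeny tips occur within
    ``radii[r]`` of focal ``f``.  Species in the plot but absent from the
    tree raise ``KeyError``.
    """
    foc = eligible_focals(plot, species, buffer)
    if foc.size == 0:
        raise ValueError(
            f"species {species!r}: no focal outside the edge buffer")
    n_tips = tree.n_tips
    rows = np.zeros((foc.size * radii.size, n_tips), dtype=bool)
    r_max = float(radii[-1])
    for k, i in enumerate(foc):
        xy = np.array([plot.x[i], plot.y[i]])
        sp, mind = _neighbor_species_min_dist(
            plot, xy, species, r_max, focal_index=int(i),
            include_focal_species=include_focal_species)
        tip_idx = np.array([tree.tip_index[s] if s in tree.tip_index else -1
                            for s in sp], dtype=int)
        missing = sp[tip_idx < 0]
        if missing.size:
            raise KeyError(
                f"species not in phylogeny: {sorted(set(missing))}")
        for r_i, r in enumerate(radii):
            rows[k * radii.size + r_i, tip_idx[mind <= r]] = True
    return rows, int(foc.size)


def _pd_rows(tree: Phylogeny, rows: np.ndarray, perm: np.ndarray | None,
             rooted: bool) -> np.ndarray:
    """PD of each membership row, optionally under a tip-label permutation."""
    inc = tree.incidence if perm is None else tree.incidence[perm]
    counts = rows.astype(np.float64) @ inc.astype(np.float64)
    union = counts > 0.5
    out = union @ tree.edge_length
    if not rooted:
        sizes = rows.sum(axis=1)
        inter = counts >= np.maximum(sizes, 1)[:, None]
        out = out - inter @ tree.edge_length
        out[sizes == 0] = 0.0
    return out


def ipar_observed(plot: CensusPlot, tree: Phylogeny, species: str,
                  radii: RadiusGrid | np.ndarray = IPAR_RADII,
                  buffer: float = 50.0, rooted: bool = True,
                  include_focal_species: bool = False):
    """Observed mean neighborhood PD per radius.

    Empty neighborhoods contribute PD 0; singleton neighborhoods score
    the root-to-tip path under the rooted convention.  Returns
    ``(curve, n_focals)``.
    """
    grid = radii if isinstance(radii, RadiusGrid) else RadiusGrid(radii)
    rows, n_foc = _membership_matrix(plot, tree, species, grid.radii,
                                     buffer, include_focal_species)
    pd_vals = _pd_rows(tree, rows, None, rooted)
    return pd_vals.reshape(n_foc, grid.radii.size).mean(axis=0), n_foc


def _status_from_rank(obs: float, null: np.ndarray, alpha: float) -> str:
    n = null.size
    p_up = (1.0 + np.sum(null >= obs)) / (n + 1.0)
    p_lo = (1.0 + np.sum(null <= obs)) / (n + 1.0)
    if p_up <= alpha / 2.0:
        return ACCUMULATOR
    if p_lo <= alpha / 2.0:
        return REPELLER
    return NEUTRAL


def ses_pd(plot: CensusPlot, tree: Phylogeny, species: str,
           radii: RadiusGrid | np.ndarray = IPAR_RADII,
           n_shuffle: int = 999, buffer: float = 50.0,
           alpha: float = 0.05, rooted: bool = True,
           include_focal_species: bool = False, average_first: bool = True,
           rng: np.random.Generator | int | None = None) -> list[SesPd]:
    """S.E.S. PD of a species at every radius via tip-label shuffling.

    The null permutes species names across *all* tips of the plot
    phylogeny, not only those seen in some neighborhood.  By default
    per-individual PD values are averaged over focals first and the
    average is standardized (``average_first=False`` standardizes each
    focal's PD and averages the standardized scores instead).
    """
    if n_shuffle < 99:
        raise ValueError("n_shuffle must be >= 99")
    grid = radii if isinstance(radii, RadiusGrid) else RadiusGrid(radii)
    rng = np.random.default_rng(rng)
    rows, n_foc = _membership_matrix(plot, tree, species, grid.radii,
                                     buffer, include_focal_species)
    obs_focal = _pd_rows(tree, rows, None, rooted).reshape(n_foc, -1)
    null_focal = np.empty((n_shuffle, n_foc, grid.radii.size))
    for s in range(n_shuffle):
        perm = rng.permutation(tree.n_tips)
        null_focal[s] = _pd_rows(tree, rows, perm, rooted).reshape(n_foc, -1)

    out = []
    if average_first:
        obs = obs_focal.mean(axis=0)
        null = null_focal.mean(axis=1)          # (n_shuffle, n_radii)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        for r_i, r in enumerate(grid.radii):
            if sd[r_i] > 0:
                ses = (obs[r_i] - mu[r_i]) / sd[r_i]
                status = _status_from_rank(obs[r_i], null[:, r_i], alpha)
                flag = ""
            else:
                ses, status, flag = np.nan, NEUTRAL, "degenerate null (sd=0)"
            out.append(SesPd(float(r), float(obs[r_i]), float(mu[r_i]),
                             float(sd[r_i]), float(ses), n_foc, n_shuffle,
                             status, flag))
    else:
        mu = null_focal.mean(axis=0)            # (n_foc, n_radii)
        sd = null_focal.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (obs_focal - mu) / sd
        for r_i, r in enumerate(grid.radii):
            zi = z[:, r_i]
            ok = np.isfinite(zi)
            if not ok.any():
                out.append(SesPd(float(r), float(obs_focal[:, r_i].mean()),
                                 float(mu[:, r_i].mean()), 0.0, np.nan,
                                 n_foc, n_shuffle, NEUTRAL,
                                 "degenerate null (sd=0)"))
                continue
            ses = float(zi[ok].mean())
            obs_mean = obs_focal[:, r_i].mean()
            null_mean_curve = null_focal[:, :, r_i].mean(axis=1)
            status = _status_from_rank(obs_mean, null_mean_curve, alpha)
            out.append(SesPd(float(r), float(obs_mean),
                             float(null_mean_curve.mean()),
                             float(null_mean_curve.std(ddof=1)), ses,
                             n_foc, n_shuffle, status,
                             "" if ok.all() else "some focals degenerate"))
    return out


def nri_nti(tree: Phylogeny, species_set, n_shuffle: int = 999,
            rng: np.random.Generator | int | None = None):
    """Net Relatedness Index and Nearest Taxon Index of a species set.

    NRI = -(MPD_obs - mean MPD_null) / sd MPD_null, and NTI likewise with
    MNTD; the null shuffles species names across the phylogeny tips
    (equivalently: draws random same-sized tip subsets).  Positive values
    mean the set is phylogenetically clustered, negative overdispersed.
    Returns ``(nri, nti)``; NaN with a warning-level flag when the set
    spans all tips (null variance 0).
    """
    rng = np.random.default_rng(rng)
    idx = tree._resolve(species_set)
    if idx.size < 2:
        raise ValueError("need at least 2 species")
    if idx.size >= tree.n_tips:
        return float("nan"), float("nan")
    dmat = tree.patristic_matrix()
    k = idx.size

    def _mpd_mntd(sub):
        d = dmat[np.ix_(sub, sub)].copy()
        iu = np.triu_indices(k, 1)
        m1 = d[iu].mean()
        np.fill_diagonal(d, np.inf)
        return m1, d.min(axis=1).mean()

    obs_mpd, obs_mntd = _mpd_mntd(idx)
    null = np.empty((n_shuffle, 2))
    for s in range(n_shuffle):
        null[s] = _mpd_mntd(rng.permutation(tree.n_tips)[:k])
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    nri = -(obs_mpd - mu[0]) / sd[0] if sd[0] > 0 else float("nan")
    nti = -(obs_mntd - mu[1]) / sd[1] if sd[1] > 0 else float("nan")
    return float(nri), float(nti)


class IparAnalysis(BaseEstimator):
    """Phylogenetic accumulator/repeller/neutral classification per scale.

    ``fit(plot, tree)`` computes, for every species with eligible focals
    and a matching tip, the observed mean neighborhood PD and its S.E.S.
    against the tip-shuffle null.

    Attributes
    ----------
    results_ : pandas.DataFrame
        species, radius_m, n_focals, obs_pd, null_mean, null_sd, ses_pd,
        status, flag.
    status_ : pandas.DataFrame
        species x radius pivot.
    skipped_ : dict of excluded species -> reason.
    """

    def __init__(self, radii=None, buffer: float = 50.0,
                 n_shuffle: int = 999, alpha: float = 0.05,
                 rooted: bool = True, include_focal_species: bool = False,
                 average_first: bool = True, random_state=None):
        self.radii = radii
        self.buffer = buffer
        self.n_shuffle = n_shuffle
        self.alpha = alpha
        self.rooted = rooted
        self.include_focal_species = include_focal_species
        self.average_first = average_first
        self.random_state = random_state

    def fit(self, plot: CensusPlot, tree: Phylogeny,
            species: list[str] | None = None):
        grid = (IPAR_RADII if self.radii is None else
                self.radii if isinstance(self.radii, RadiusGrid)
                else RadiusGrid(self.radii))
        todo = sorted(species) if species is not None else plot.species_ids
        seed_seq = np.random.SeedSequence(
            self.random_state if isinstance(self.random_state, (int, np.integer))
            else None)
        rows = []
        self.skipped_ = {}
        for sp, child in zip(todo, seed_seq.spawn(len(todo))):
            if sp not in tree.tip_index:
                self.skipped_[sp] = "not a tip of the phylogeny"
                continue
            try:
                res = ses_pd(plot, tree, sp, grid, n_shuffle=self.n_shuffle,
                             buffer=self.buffer, alpha=self.alpha,
                             rooted=self.rooted,
                             include_focal_species=self.include_focal_species,
                             average_first=self.average_first,
                             rng=np.random.default_rng(child))
            except ValueError as exc:
                self.skipped_[sp] = str(exc)
                continue
            for r in res:
                rows.append({"species": sp, "radius_m": r.radius,
                             "n_focals": r.i, "obs_pd": r.observed_pd,
                             "null_mean": r.null_mean, "null_sd": r.null_sd,
                             "ses_pd": r.ses, "status": r.status,
                             "flag": r.flag})
        self.results_ = pd.DataFrame(rows, columns=[
            "species", "radius_m", "n_focals", "obs_pd", "null_mean",
            "null_sd", "ses_pd", "status", "flag"])
        self.status_ = (self.results_.pivot(index="species",
                                            columns="radius_m",
                                            values="status")
                        if rows else pd.DataFrame())
        return self
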