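"""Synthetic mapped forests, phylogenies and tip traits with known truth.

No census data ship with the package, so every stage is exercised on
generated inputs: multispecies point patterns in a rectangular window
(complete spatial randomness, Thomas cluster processes, and engineered
attraction/repulsion toward a target species) and Yule phylogenies with
binary traits evolved by shuffling or Brownian-threshold dynamics.

All samplers are conditioned on exact counts (stems per species, tips per
tree, state-1 tips per trait) so downstream tests are not confounded by
count variance, and all are reproducible from the spec seed.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .phylotree import Phylogeny, simulate_brownian
from .plots import CensusPlot, TreeRecord

__all__ = ["RandomPlacement", "ThomasPlacement", "AttractPlacement",
           "RepelPlacement", "ForestSpec", "TreeSimSpec",
           "generate_forest", "generate_tree", "attraction_scenario"]


@dataclass(frozen=True)
class RandomPlacement:
    """Complete spatial randomness (binomial process)."""


@dataclass(frozen=True)
class ThomasPlacement:
    """Thomas cluster process: Poisson parents, Gaussian offspring."""

    kappa: float = 5e-4   # parents per m^2
    sigma: float = 5.0    # offspring dispersal sd, m


@dataclass(frozen=True)
class AttractPlacement:
    """Excess intensity inside discs around a target species' stems."""

    target: str
    radius: float = 10.0
    multiplier: float = 8.0


@dataclass(frozen=True)
class RepelPlacement:
    """Deficit intensity inside discs around a target species' stems."""

    target: str
    radius: float = 10.0
    multiplier: float = 8.0


@dataclass
class ForestSpec:
    """Recipe for a synthetic mapped census.

    ``abundance`` is either ``"uniform"`` (every species receives
    ``n_per_species`` stems) or ``"logseries"`` (per-species counts drawn
    from a log-series with parameter ``logseries_p``, the classic
    rank-abundance shape of tropical tree plots, floored at 1).
    ``placements`` overrides the per-species placement model (default
    CSR); keys are species ids ``sp01..``.
    """

    window: tuple[float, float, float, float] = (0.0, 0.0, 200.0, 200.0)
    n_species: int = 20
    abundance: str = "uniform"
    n_per_species: int = 100
    logseries_p: float = 0.995
    abundance_overrides: dict = field(default_factory=dict)
    placements: dict = field(default_factory=dict)
    dbh_lognormal: tuple[float, float] = (0.5, 0.7)  # (mu, sigma) of log
    seed: int | None = None

    def species_ids(self) -> list[str]:
        width = max(2, len(str(self.n_species)))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]


def _uniform_points(rng, window, n):
    xmin, ymin, xmax, ymax = window
    return np.column_stack([rng.uniform(xmin, xmax, n),
                            rng.uniform(ymin, ymax, n)])


def _thomas_points(rng, window, n, kappa, sigma):
    xmin, ymin, xmax, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    n_parents = max(1, rng.poisson(kappa * area))
    parents = _uniform_points(rng, window, n_parents)
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        par = parents[rng.integers(0, n_parents, m)]
        cand = par + rng.normal(0.0, sigma, (m, 2))
        ok = ((cand[:, 0] >= xmin) & (cand[:, 0] <= xmax)
              & (cand[:, 1] >= ymin) & (cand[:, 1] <= ymax))
        k = int(ok.sum())
        pts[filled:filled + k] = cand[ok]
        filled += k
    return pts


def _weighted_points(rng, window, n, anchors, radius, w_in, w_out):
    """Rejection sampler for intensity w_in inside discs, w_out outside."""
    from scipy.spatial import cKDTree
    tree = cKDTree(anchors)
    w_max = max(w_in, w_out)
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = (n - filled) * 4 + 16
        cand = _uniform_points(rng, window, m)
        d, _ = tree.query(cand, k=1)
        w = np.where(d <= radius, w_in, w_out)
        acc = cand[rng.random(m) < w / w_max]
        k = min(acc.shape[0], n - filled)
        pts[filled:filled + k] = acc[:k]
        filled += k
    return pts


def generate_forest(spec: ForestSpec) -> CensusPlot:
    """Generate a mapped plot from a :class:`ForestSpec`.

    Species with attract/repel placements are laid down after their target
    species.  dbh values are ``1 + lognormal`` cm so every stem passes the
    1 cm census threshold.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.species_ids()
    for sp, pl in spec.placements.items():
        if sp not in ids:
            raise ValueError(f"placement for unknown species {sp!r}")
        if isinstance(pl, (AttractPlacement, RepelPlacement)):
            if pl.target not in ids:
                raise ValueError(f"{sp}: unknown target {pl.target!r}")
            xmin, ymin, xmax, ymax = spec.window
            if pl.radius >= min(xmax - xmin, ymax - ymin) / 2:
                raise ValueError(f"{sp}: effect radius too large for window")

    if spec.abundance == "uniform":
        counts = {sp: spec.n_per_species for sp in ids}
    elif spec.abundance == "logseries":
        from scipy.stats import logser
        draws = logser.rvs(spec.logseries_p, size=spec.n_species,
                           random_state=rng)
        counts = {sp: max(1, int(c)) for sp, c in zip(ids, draws)}
    else:
        raise ValueError(f"unknown abundance model {spec.abundance!r}")
    for sp, n in spec.abundance_overrides.items():
        if sp not in counts:
            raise ValueError(f"abundance override for unknown species {sp!r}")
        counts[sp] = int(n)
    if sum(counts.values()) == 0:
        raise ValueError("spec yields no stems")

    # dependents (attract/repel) go after their targets
    dependent = [sp for sp in ids
                 if isinstance(spec.placements.get(sp),
                               (AttractPlacement, RepelPlacement))]
    order = [sp for sp in ids if sp not in dependent] + dependent

    coords: dict[str, np.ndarray] = {}
    for sp in order:
        pl = spec.placements.get(sp, RandomPlacement())
        n = counts[sp]
        if isinstance(pl, RandomPlacement):
            coords[sp] = _uniform_points(rng, spec.window, n)
        elif isinstance(pl, ThomasPlacement):
            coords[sp] = _thomas_points(rng, spec.window, n, pl.kappa,
                                        pl.sigma)
        elif isinstance(pl, AttractPlacement):
            coords[sp] = _weighted_points(rng, spec.window, n,
                                          coords[pl.target], pl.radius,
                                          pl.multiplier, 1.0)
        elif isinstance(pl, RepelPlacement):
            coords[sp] = _weighted_points(rng, spec.window, n,
                                          coords[pl.target], pl.radius,
                                          1.0 / pl.multiplier, 1.0)
        else:
            raise TypeError(f"unknown placement {pl!r}")

    mu, sg = spec.dbh_lognormal
    stems = []
    for sp in ids:
        xy = coords[sp]
        dbh = 1.0 + rng.lognormal(mu, sg, len(xy))
        for k in range(len(xy)):
            stems.append(TreeRecord(f"{sp}_{k + 1}", sp,
                                    float(xy[k, 0]), float(xy[k, 1]),
                                    float(dbh[k])))
    return CensusPlot(spec.window, stems)


def attraction_scenario(seed: int | None = None,
                        effect_radius: float = 10.0,
                        multiplier: float = 20.0) -> ForestSpec:
    """Canonical strong-attraction benchmark plot.

    A 250 x 250 m window with one moderately common CSR focal species
    (``sp01``, 40 stems) and 14 heterospecific species (80 stems each)
    whose placement intensity is boosted ``multiplier``-fold inside
    ``effect_radius`` discs around the focal's stems.  By construction
    ``sp01`` is a ground-truth diversity accumulator at radii up to the
    effect radius.  The focal species is kept sparse so the attraction
    discs cover only a small fraction of the window; a denser focal
    dilutes its own engineered effect.
    """
    n_sp = 15
    ids = [f"sp{i:02d}" for i in range(1, n_sp + 1)]
    placements = {sp: AttractPlacement("sp01", effect_radius, multiplier)
                  for sp in ids[1:]}
    return ForestSpec(window=(0.0, 0.0, 250.0, 250.0), n_species=n_sp,
                      abundance="uniform", n_per_species=80,
                      abundance_overrides={"sp01": 40},
                      placements=placements, seed=seed)


@dataclass
class TreeSimSpec:
    """Recipe for a Yule phylogeny plus a binary tip trait.

    ``trait_model`` is ``"shuffle"`` (states assigned by uniform random
    permutation at exact prevalence) or ``"brownian_threshold"``
    (continuous Brownian trait thresholded at the rank giving exact
    prevalence).
    """

    n_tips: int = 64
    birth_rate: float = 1.0
    trait_model: str = "shuffle"
    prevalence: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def generate_tree(spec: TreeSimSpec) -> tuple[Phylogeny, dict]:
    """Simulate a Yule tree and a binary tip trait.

    Returns ``(phylogeny, trait)`` where ``trait`` maps each tip label to
    0/1 with exactly ``round(prevalence * n_tips)`` ones.
    """
    rng = np.random.default_rng(spec.seed)
    pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=spec.birth_rate, death_rate=0.0,
        num_extant_tips=spec.n_tips, rng=pyrng)
    for k, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{k + 1:03d}"
    tree = Phylogeny(dtree)

    k1 = int(round(spec.prevalence * spec.n_tips))
    k1 = min(max(k1, 1), spec.n_tips - 1)
    states = np.zeros(tree.n_tips, dtype=int)
    if spec.trait_model == "shuffle":
        states[rng.permutation(tree.n_tips)[:k1]] = 1
    elif spec.trait_model == "brownian_threshold":
        vals = simulate_brownian(tree, 1, rng)[0]
        states[np.argsort(vals)[-k1:]] = 1
    else:
        raise ValueError(f"unknown trait model {spec.trait_model!r}")
    trait = {lab: int(s) for lab, s in zip(tree.tip_labels, states)}
    return tree, trait
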