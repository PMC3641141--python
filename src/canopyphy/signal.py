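"""Phylogenetic signal of discrete traits: Sankoff parsimony and the D statistic.

Two complementary tests of whether a species attribute (here the per-scale
accumulator / repeller / neutral status) is non-randomly distributed on a
phylogeny:

* **Sankoff parsimony.**  The minimal total substitution cost of the trait
  on the tree under a cost matrix (unit costs by default).  Significance
  comes from re-arraying the observed states across the tips: a trait that
  needs fewer changes than its permutations shows phylogenetic signal.

* **Fritz-Purvis D.**  For a binary trait, the observed sum of
  sister-clade differences d is scaled between its expectations under two
  nulls — random shuffling of tip states and a threshold model on
  Brownian-motion trait evolution:

      D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

  so D = 1 for a phylogenetically random trait, D = 0 for Brownian-like
  conservatism, D < 0 for stronger clumping than Brownian and D > 1 for
  overdispersion.  Nodal trait values are estimated by averaging daughter
  values from the tips toward the root; a polytomy's daughters are folded
  in pairwise-sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .phylotree import Phylogeny, simulate_brownian

__all__ = ["sankoff_score", "sankoff_signal_test", "SankoffResult",
           "fritz_purvis_d", "DResult", "SankoffSignal", "DStatistic"]

_INF = np.inf


def _states_to_matrix(tree: Phylogeny, tip_states, states: list):
    """(R, n_tips) integer state matrix; -1 marks unscored tips."""
    if isinstance(tip_states, dict):
        lookup = {s: i for i, s in enumerate(states)}
        vec = np.full(tree.n_tips, -1, dtype=int)
        for lab, st in tip_states.items():
            if lab not in tree.tip_index:
                raise KeyError(f"tip {lab!r} not in tree")
            if st not in lookup:
                raise KeyError(f"state {st!r} not in cost matrix states")
            vec[tree.tip_index[lab]] = lookup[st]
        return vec[None, :]
    arr = np.atleast_2d(np.asarray(tip_states, dtype=int))
    if arr.shape[1] != tree.n_tips:
        raise ValueError("state matrix width must equal tip count")
    if arr.max() >= len(states):
        raise KeyError("state index outside cost matrix")
    return arr


def _sankoff_batch(tree: Phylogeny, state_mat: np.ndarray,
                   cost: np.ndarray) -> np.ndarray:
    """Minimal Sankoff cost for each row of ``state_mat``.

    Unscored tips (state -1) are unconstrained (zero cost in every state),
    which yields the same minimum as pruning them with the induced
    subtree.
    """
    R = state_mat.shape[0]
    S = cost.shape[0]
    n_nodes = tree.edge_length.size
    tip_of_node = np.full(n_nodes, -1, dtype=int)
    tip_of_node[tree.tip_nodes] = np.arange(tree.n_tips)
    node_cost: list[np.ndarray | None] = [None] * n_nodes
    for j in range(n_nodes):  # postorder by construction
        ch = tree.children[j]
        if ch.size == 0:
            c = np.zeros((R, S))
            st = state_mat[:, tip_of_node[j]]
            scored = st >= 0
            c[scored] = _INF
            c[scored, st[scored]] = 0.0
            node_cost[j] = c
        else:
            total = np.zeros((R, S))
            for ci in ch:
                child = node_cost[ci]
                # min over child state s' of child[s'] + cost[s, s']
                total += np.min(child[:, None, :] + cost[None, :, :], axis=2)
                node_cost[ci] = None
            node_cost[j] = total
    root = node_cost[n_nodes - 1]
    return root.min(axis=1)


def unit_cost_matrix(n_states: int) -> np.ndarray:
    return 1.0 - np.eye(n_states)


def sankoff_score(tree: Phylogeny, tip_states: dict,
                  cost_matrix: np.ndarray | None = None,
                  states: list | None = None) -> float:
    """Exact minimal substitution cost of a discrete trait on the tree.

    ``tip_states`` maps tip labels to states; tips left out are treated as
    unscored and do not constrain the reconstruction.  ``cost_matrix``
    must be square with a zero diagonal and non-negative entries; by
    default unit costs over the sorted set of observed states.
    """
    if states is None:
        states = sorted(set(tip_states.values()))
    if cost_matrix is None:
        cost_matrix = unit_cost_matrix(len(states))
    cost_matrix = np.asarray(cost_matrix, dtype=float)
    if (cost_matrix.shape[0] != cost_matrix.shape[1]
            or np.any(np.diag(cost_matrix) != 0) or np.any(cost_matrix < 0)):
        raise ValueError("cost matrix must be square, zero-diagonal, >= 0")
    if cost_matrix.shape[0] != len(states):
        raise ValueError("cost matrix size must match number of states")
    mat = _states_to_matrix(tree, tip_states, states)
    return float(_sankoff_batch(tree, mat, cost_matrix)[0])


@dataclass
class SankoffResult:
    score: float
    p: float
    n_perm: int
    flag: str = ""


def sankoff_signal_test(tree: Phylogeny, tip_states: dict,
                        n_perm: int = 999,
                        cost_matrix: np.ndarray | None = None,
                        rng: np.random.Generator | int | None = None
                        ) -> SankoffResult:
    """Permutation test of phylogenetic signal via the Sankoff score.

    The observed states are randomly re-arrayed across the scored tips
    ``n_perm`` times; ``p = (1 + #{score_perm <= score_obs}) / (n_perm + 1)``.
    Low p means the trait requires fewer changes than random arrangements,
    i.e. shows signal.  A one-state trait is degenerate: p is NaN and the
    result flagged.
    """
    if len(tip_states) < 3:
        raise ValueError("need at least 3 scored tips")
    rng = np.random.default_rng(rng)
    states = sorted(set(tip_states.values()))
    if cost_matrix is None:
        cost_matrix = unit_cost_matrix(len(states))
    cost_matrix = np.asarray(cost_matrix, dtype=float)
    vec = _states_to_matrix(tree, tip_states, states)[0]
    scored = np.flatnonzero(vec >= 0)
    obs = float(_sankoff_batch(tree, vec[None, :], cost_matrix)[0])
    if len(states) < 2:
        return SankoffResult(obs, float("nan"), n_perm,
                             "degenerate trait (single state)")
    perms = np.tile(vec, (n_perm, 1))
    for r in range(n_perm):
        perms[r, scored] = vec[scored][rng.permutation(scored.size)]
    null = _sankoff_batch(tree, perms, cost_matrix)
    p = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return SankoffResult(obs, float(p), n_perm)


def _d_sums(tree: Phylogeny, vals: np.ndarray) -> np.ndarray:
    """Sum of absolute sister-clade differences for each row of tip values.

    Nodal values are means of daughter values computed tips-to-root;
    polytomies are folded pairwise-sequentially in child order.
    """
    R = vals.shape[0]
    n_nodes = tree.edge_length.size
    tip_of_node = np.full(n_nodes, -1, dtype=int)
    tip_of_node[tree.tip_nodes] = np.arange(tree.n_tips)
    node_val = np.empty((n_nodes, R))
    d = np.zeros(R)
    for j in range(n_nodes):
        ch = tree.children[j]
        if ch.size == 0:
            node_val[j] = vals[:, tip_of_node[j]]
        else:
            running = node_val[ch[0]].copy()
            for k, ci in enumerate(ch[1:], start=2):
                d += np.abs(running - node_val[ci])
                running = running + (node_val[ci] - running) / k
            node_val[j] = running
    return d


@dataclass
class DResult:
    d: float
    p_random: float
    p_brownian: float
    d_obs: float
    mean_random: float
    mean_brownian: float
    n_perm: int
    flag: str = ""


def fritz_purvis_d(tree: Phylogeny, binary_states, n_perm: int = 1000,
                   rng: np.random.Generator | int | None = None) -> DResult:
    """Fritz-Purvis D of a binary trait with permutation significance.

    ``binary_states`` is a dict mapping every tip label to 0/1 or an array
    in tip order.  The random null permutes the observed states across
    tips (prevalence preserved); the Brownian null evolves a continuous
    trait on the tree and thresholds it at the rank giving exactly the
    observed prevalence.  ``p_random`` is the fraction of random-null d
    values <= the observed d (evidence against D = 1); ``p_brownian`` the
    fraction of Brownian-null d values >= observed (evidence against
    D = 0).
    """
    rng = np.random.default_rng(rng)
    if isinstance(binary_states, dict):
        missing = set(tree.tip_labels) - set(binary_states)
        if missing:
            raise KeyError(f"tips without a state: {sorted(missing)[:5]}")
        b = np.array([binary_states[t] for t in tree.tip_labels], dtype=float)
    else:
        b = np.asarray(binary_states, dtype=float)
        if b.size != tree.n_tips:
            raise ValueError("state vector length must equal tip count")
    uniq = np.unique(b)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("trait must be binary 0/1")
    if uniq.size < 2:
        return DResult(float("nan"), float("nan"), float("nan"),
                       float("nan"), float("nan"), float("nan"), n_perm,
                       "constant trait")
    k1 = int(b.sum())
    d_obs = float(_d_sums(tree, b[None, :])[0])

    perm_mat = np.empty((n_perm, b.size))
    for r in range(n_perm):
        perm_mat[r] = b[rng.permutation(b.size)]
    d_rand = _d_sums(tree, perm_mat)

    bm = simulate_brownian(tree, n_perm, rng)
    # threshold at the rank giving the observed prevalence exactly
    order = np.argsort(bm, axis=1)
    bm_states = np.zeros_like(bm)
    rows = np.arange(n_perm)[:, None]
    bm_states[rows, order[:, -k1:]] = 1.0
    d_brown = _d_sums(tree, bm_states)

    mr, mb = float(d_rand.mean()), float(d_brown.mean())
    if np.isclose(mr, mb):
        return DResult(float("nan"), float("nan"), float("nan"), d_obs,
                       mr, mb, n_perm, "null means coincide")
    d_stat = (d_obs - mb) / (mr - mb)
    p_rand = float(np.mean(d_rand <= d_obs))
    p_brown = float(np.mean(d_brown >= d_obs))
    return DResult(float(d_stat), p_rand, p_brown, d_obs, mr, mb, n_perm)


class SankoffSignal(BaseEstimator):
    """Estimator wrapper: Sankoff permutation test of a tip trait.

    ``fit(tree, tip_states)`` sets ``score_``, ``p_``, ``result_``.
    """

    def __init__(self, n_perm: int = 999, cost_matrix=None, random_state=None):
        self.n_perm = n_perm
        self.cost_matrix = cost_matrix
        self.random_state = random_state

    def fit(self, tree: Phylogeny, tip_states: dict):
        res = sankoff_signal_test(tree, tip_states, n_perm=self.n_perm,
                                  cost_matrix=self.cost_matrix,
                                  rng=np.random.default_rng(self.random_state))
        self.result_ = res
        self.score_ = res.score
        self.p_ = res.p
        return self


class DStatistic(BaseEstimator):
    """Estimator wrapper: Fritz-Purvis D of a binary tip trait.

    ``fit(tree, binary_states)`` sets ``d_``, ``p_random_``,
    ``p_brownian_``, ``result_``.
    """

    def __init__(self, n_perm: int = 1000, random_state=None):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, tree: Phylogeny, binary_states):
        res = fritz_purvis_d(tree, binary_states, n_perm=self.n_perm,
                             rng=np.random.default_rng(self.random_state))
        self.result_ = res
        self.d_ = res.d
        self.p_random_ = res.p_random
        self.p_brownian_ = res.p_brownian
        return self
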