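"""Rooted phylogeny container and branch-length diversity metrics.

Wraps a dendropy tree in flat arrays (postorder node list, parent
pointers, edge lengths, tip-to-root incidence) so that Faith's
phylogenetic diversity (PD), mean pairwise distance (MPD) and mean
nearest-taxon distance (MNTD) are cheap to evaluate repeatedly under
tip-label randomizations.

Conventions
-----------
* PD is *rooted* by default: the minimal subtree connecting a species set
  always includes the path to the root, so a singleton set scores its
  root-to-tip path length.  ``rooted=False`` gives the tips-only spanning
  subtree instead.
* Branch lengths must be non-negative; a missing root edge counts 0.
* Polytomies are allowed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "faith_pd", "mpd", "mntd"]


class Phylogeny:
    """Rooted tree with branch lengths over uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self._nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.edge_length = np.zeros(n)
        self.children: list[np.ndarray] = [None] * n
        tips = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
            ln = nd.edge.length
            if ln is None:
                ln = 0.0
            if ln < 0:
                raise ValueError("negative branch length")
            self.edge_length[i] = ln
            self.children[i] = np.array(
                [index[id(c)] for c in nd.child_nodes()], dtype=int)
            if nd.is_leaf():
                tips.append(i)
        self.tip_nodes = np.array(tips, dtype=int)
        self.tip_labels = [nodes[i].taxon.label for i in self.tip_nodes]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels are not unique")
        self.tip_index = {lab: k for k, lab in enumerate(self.tip_labels)}

        # incidence[k, j] True when node j lies on tip k's path to the root
        self.incidence = np.zeros((len(tips), n), dtype=bool)
        for k, i in enumerate(self.tip_nodes):
            j = i
            while j != -1:
                self.incidence[k, j] = True
                j = self.parent[j]
        self.depths = self.incidence @ self.edge_length  # root-to-tip distances
        self._patristic: np.ndarray | None = None

    # -- constructors --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    # -- basic views ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_length.sum())

    def _resolve(self, species_set: Iterable[str]) -> np.ndarray:
        idx = []
        for s in species_set:
            if s not in self.tip_index:
                raise KeyError(f"species {s!r} is not a tip of the phylogeny")
            idx.append(self.tip_index[s])
        return np.array(sorted(set(idx)), dtype=int)

    # -- metrics -------------------------------------------------------
    def pd_from_indices(self, idx: np.ndarray, rooted: bool = True) -> float:
        """Faith's PD of the tips at positional indices ``idx``."""
        if idx.size == 0:
            return 0.0
        rows = self.incidence[idx]
        union = rows.any(axis=0)
        total = float(self.edge_length[union].sum())
        if not rooted:
            total -= float(self.edge_length[rows.all(axis=0)].sum())
        return total

    def patristic_matrix(self) -> np.ndarray:
        """Dense tip x tip patristic (branch-length path) distance matrix."""
        if self._patristic is None:
            w = self.incidence * self.edge_length  # weighted root paths
            shared = w @ self.incidence.T
            d = self.depths[:, None] + self.depths[None, :] - 2.0 * shared
            np.fill_diagonal(d, 0.0)
            self._patristic = d
        return self._patristic

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-12))


def simulate_brownian(tree: Phylogeny, n_reps: int,
                      rng: np.random.Generator | int | None = None
                      ) -> np.ndarray:
    """Tip values of ``n_reps`` Brownian-motion traits evolved on the tree.

    Each edge receives an independent normal increment with variance equal
    to its length (rate 1); a tip's value is the sum of increments along
    its root path.  Returns shape ``(n_reps, n_tips)`` in tip-label order.
    """
    rng = np.random.default_rng(rng)
    inc = rng.standard_normal((n_reps, tree.edge_length.size))
    inc *= np.sqrt(tree.edge_length)[None, :]
    return inc @ tree.incidence.T.astype(float)


def faith_pd(tree: Phylogeny, species_set: Iterable[str],
             rooted: bool = True) -> float:
    """Sum of branch lengths of the minimal subtree spanning ``species_set``.

    With ``rooted=True`` (default) the subtree also connects to the root,
    so a singleton returns its root-to-tip path length.
    """
    idx = tree._resolve(species_set)
    if idx.size == 0:
        raise ValueError("species_set must be non-empty")
    return tree.pd_from_indices(idx, rooted=rooted)


def _pairwise_submatrix(tree: Phylogeny, species_set: Iterable[str]) -> np.ndarray:
    idx = tree._resolve(species_set)
    if idx.size < 2:
        raise ValueError("need at least 2 species")
    return tree.patristic_matrix()[np.ix_(idx, idx)]


def mpd(tree: Phylogeny, species_set: Iterable[str]) -> float:
    """Unweighted mean pairwise patristic distance within the set."""
    d = _pairwise_submatrix(tree, species_set)
    n = d.shape[0]
    return float(d[np.triu_indices(n, k=1)].mean())


def mntd(tree: Phylogeny, species_set: Iterable[str]) -> float:
    """Mean distance from each member to its nearest other member."""
    d = _pairwise_submatrix(tree, species_set).astype(float)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())
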