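import numpy as np
import pytest

import canopyphy as cp


@pytest.fixture(scope="session")
def small_plot():
    """Hand-built 100x100 m plot with three species at known positions."""
    stems = [
        cp.TreeRecord("a1", "A", 50.0, 50.0, 5.0),
        cp.TreeRecord("a2", "A", 50.0, 52.0, 3.0),
        cp.TreeRecord("b1", "B", 50.0, 53.0, 2.0),
        cp.TreeRecord("c1", "C", 60.0, 50.0, 8.0),
        cp.TreeRecord("a3", "A", 49.0, 50.0, 1.5),
    ]
    return cp.CensusPlot((0.0, 0.0, 100.0, 100.0), stems)


@pytest.fixture(scope="session")
def csr_plot():
    """Generated 10-species CSR plot, 150x150 m."""
    spec = cp.ForestSpec(window=(0, 0, 150, 150), n_species=10,
                         n_per_species=50, seed=42)
    return cp.generate_forest(spec)


@pytest.fixture(scope="session")
def eight_tip_tree():
    tree, _ = cp.generate_tree(cp.TreeSimSpec(n_tips=8, seed=7))
    return tree


@pytest.fixture(scope="session")
def balanced16():
    """Balanced ultrametric 16-tip tree, depth 5, all branch lengths 1."""
    def clade(labels, depth):
        if len(labels) == 1:
            return f"{labels[0]}:{depth}"
        half = len(labels) // 2
        return (f"({clade(labels[:half], depth - 1)},"
                f"{clade(labels[half:], depth - 1)}):1")
    labels = [f"t{i:02d}" for i in range(16)]
    tree = cp.Phylogeny.from_newick(clade(labels, 5) + ";")
    assert tree.is_ultrametric(1e-9)
    return tree


def brute_force_neighborhood(plot, i, r, include_focal_species=False):
    """All-pairs reference for neighborhood species sets."""
    out = set()
    for j in range(plot.n_stems):
        if j == i:
            continue
        if not include_focal_species and plot.species[j] == plot.species[i]:
            continue
        d = np.hypot(plot.x[j] - plot.x[i], plot.y[j] - plot.y[i])
        if d <= r:
            out.add(plot.species[j])
    return out


def brute_force_pd(tree: "cp.Phylogeny", labels, rooted=True):
    """Union-of-root-paths Faith PD computed through the dendropy tree."""
    leaves = {lf.taxon.label: lf for lf in tree.tree.leaf_node_iter()}
    paths = []
    for lab in labels:
        edges = []
        nd = leaves[lab]
        while nd is not None:
            edges.append(nd)
            nd = nd.parent_node
        paths.append(edges)
    union, seen = 0.0, set()
    for path in paths:
        for nd in path:
            if id(nd) not in seen:
                seen.add(id(nd))
                union += nd.edge.length or 0.0
    if not rooted:
        common = set(id(nd) for nd in paths[0])
        for path in paths[1:]:
            common &= set(id(nd) for nd in path)
        union -= sum((nd.edge.length or 0.0) for nd in paths[0]
                     if id(nd) in common)
    return union
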