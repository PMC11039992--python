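"""Yule pure-birth species-tree simulation."""

from __future__ import annotations

import numpy as np
import dendropy

from ..errors import InvalidArgumentError

__all__ = ["simulate_tree"]


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Simulate an ultrametric species tree under a Yule pure-birth process.

    Lineages split at unit rate; the finished tree is rescaled so that the
    root-to-tip depth is exactly 1 (the tree is ultrametric, so every tip
    sits at depth 1).  Leaves are labelled ``sp0001``, ``sp0002``, ... in
    simulation order.

    Parameters
    ----------
    n_species
        Number of extant leaves; must be at least 2.
    seed
        Seed for the generator; output is byte-reproducible per seed.

    Returns
    -------
    dendropy.Tree
        Rooted, ultrametric, unit-height tree with ``n_species`` leaves.
    """
    if n_species < 2:
        raise InvalidArgumentError(f"n_species must be >= 2, got {n_species}")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    # Active lineages are (node, birth_time); the root splits at t=0 into
    # two lineages, then each subsequent event splits a random lineage.
    t = 0.0
    root = tree.seed_node
    left = root.new_child()
    right = root.new_child()
    active: list[tuple[dendropy.Node, float]] = [(left, 0.0), (right, 0.0)]
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    # Close all open lineages at the present and rescale to unit height.
    t_end = t + rng.exponential(1.0 / n_species)
    root.edge.length = 0.0
    for node, birth in active:
        node.edge.length = t_end - birth
    if t_end > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= t_end

    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = taxon_namespace.new_taxon(f"sp{i:04d}")
        leaf.taxon = taxon
    return tree


def tree_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every leaf, keyed by taxon label."""
    depths: dict[str, float] = {}
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.root_distance
    return depths
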