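"""Dollo gene-loss simulation on a species tree.

Every orthologous group (OG) is present at the root.  Traversing the tree
from the root, an OG present at the top of a branch of length ``L`` is
lost on that branch with probability ``1 - exp(-lambda * L)``; once lost
it stays absent in every descendant (no regain).  OGs belonging to a
correlated-loss module mix a per-branch shared loss indicator (used with
probability ``rho``) with an independent one, so that ``rho = 1`` makes
module profiles identical and ``rho = 0`` makes them independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy

from ..coevolution import PresenceAbsenceMatrix
from ..errors import InvalidArgumentError

__all__ = ["LossModel", "simulate_gene_loss"]


@dataclass(frozen=True)
class LossModel:
    """Per-OG loss rate plus an optional correlated-loss module.

    Attributes
    ----------
    lam
        Loss rate in events per unit branch length; must be >= 0.
    module_members
        OG identifiers whose losses are correlated; may be empty when
        ``rho`` is 0.
    rho
        Probability that a module OG uses the branch-shared loss
        indicator instead of its own; in [0, 1].
    """

    lam: float
    module_members: tuple[str, ...] = field(default_factory=tuple)
    rho: float = 0.0

    def __post_init__(self):
        if self.lam < 0:
            raise InvalidArgumentError(f"lambda must be >= 0, got {self.lam}")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidArgumentError(f"rho must be in [0, 1], got {self.rho}")
        if self.rho > 0 and not self.module_members:
            raise InvalidArgumentError("module_members must be non-empty when rho > 0")
        if len(set(self.module_members)) != len(self.module_members):
            raise InvalidArgumentError("module_members contains duplicates")


def simulate_gene_loss(
    tree: dendropy.Tree,
    n_background: int,
    loss_model: LossModel,
    seed: int,
    return_trace: bool = False,
):
    """Simulate presence/absence profiles under Dollo loss.

    Parameters
    ----------
    tree
        Species tree with branch lengths; leaves provide the species ids.
    n_background
        Number of independent background OGs (ids ``og00001``...).
    loss_model
        Loss rate and module specification; module OG ids come from
        ``loss_model.module_members``.
    seed
        Generator seed; output is reproducible per seed.
    return_trace
        If True, also return the per-branch loss events as
        ``{branch_head_species_set: lost OG index array}`` for auditing
        the Dollo property.

    Returns
    -------
    PresenceAbsenceMatrix, or (PresenceAbsenceMatrix, trace) when
    ``return_trace`` is set.  Rows are OGs (background first, then module
    members), columns are species in leaf-iteration order.
    """
    if n_background < 0:
        raise InvalidArgumentError(f"n_background must be >= 0, got {n_background}")
    rng = np.random.default_rng(seed)

    module_ids = list(loss_model.module_members)
    og_ids = [f"og{i + 1:05d}" for i in range(n_background)] + module_ids
    n_og = len(og_ids)
    module_idx = np.arange(n_background, n_og)

    leaves = list(tree.leaf_node_iter())
    species_ids = [leaf.taxon.label for leaf in leaves]

    lam = loss_model.lam
    rho = loss_model.rho
    # present[node] is a boolean vector over OGs.
    present: dict[int, np.ndarray] = {id(tree.seed_node): np.ones(n_og, dtype=bool)}
    trace: list[tuple[frozenset[str], np.ndarray]] = []

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = present[id(node.parent_node)]
        length = node.edge.length or 0.0
        p_loss = -np.expm1(-lam * length)
        lost = rng.random(n_og) < p_loss
        if rho > 0 and len(module_idx):
            # One coin per branch: with probability rho the whole module
            # follows a single shared indicator on this branch, otherwise
            # every member keeps its independent draw.
            shared_lost = rng.random() < p_loss
            if rng.random() < rho:
                lost[module_idx] = shared_lost
        # Dollo: a loss only matters where the OG is still present.
        lost &= parent_state
        present[id(node)] = parent_state & ~lost
        if return_trace and lost.any():
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            trace.append((clade, np.flatnonzero(lost)))

    values = np.zeros((n_og, len(leaves)), dtype=np.int8)
    for j, leaf in enumerate(leaves):
        values[:, j] = present[id(leaf)]
    matrix = PresenceAbsenceMatrix(og_ids=og_ids, species_ids=species_ids, values=values)
    if return_trace:
        return matrix, trace
    return matrix
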