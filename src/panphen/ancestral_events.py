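"""Parsimony event counts and continuous ancestral reconstruction.

Two reconstructions live here:

* ``fitch_count`` / ``count_all`` — the minimum number of presence/absence
  state changes (gene gains plus losses, undirected) that explain a gene's
  tip pattern on the strain tree. Computed by unit-cost Sankoff dynamic
  programming, which handles polytomies natively and reduces to Fitch
  parsimony on binary trees; the count is independent of root placement
  because the cost matrix is symmetric.

* ``ancestral_phenotype_changes`` — squared-change parsimony for a
  continuous tip value: internal node values minimise
  ``sum_branches (dy)^2 / length``, which coincides with the ML ancestral
  states under Brownian motion on a fixed tree. The per-branch changes
  feed the tree-aware association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_io import PAMatrix
from .tree import StrainTree

__all__ = [
    "GeneEventCount",
    "BranchPhenotypeChange",
    "fitch_count",
    "count_all",
    "event_counts",
    "parsimony_node_states",
    "ancestral_phenotype_changes",
    "squared_change_reconstruction",
]

_BIG = np.int32(1 << 20)  # effectively infinite cost for a forbidden tip state
ZERO_LENGTH_EPS_FACTOR = 1e-8  # x tree depth, continuous reconstruction only


@dataclass
class GeneEventCount:
    """Minimum gain+loss count for one gene's tip pattern."""

    gene: str
    n_g: int
    invariant: bool


@dataclass
class BranchPhenotypeChange:
    """Signed phenotype change along one branch (child minus parent).

    ``branch`` is the child node id; summing ``delta`` along any
    root-to-tip path telescopes to tip value minus root value.
    """

    branch: int
    delta: float


# ----------------------------------------------------------------------
# discrete (gain/loss) parsimony


def _tip_state_array(tree: StrainTree, columns: np.ndarray) -> np.ndarray:
    """Scatter a (n_tips, G) tip-state matrix into a (n_nodes, G) array."""
    n, g = tree.n_nodes, columns.shape[1]
    states = np.full((n, g), -1, dtype=np.int8)
    states[tree.tip_nodes] = columns
    return states


def _sankoff_cost(tree: StrainTree, tip_states: np.ndarray) -> np.ndarray:
    """Unit-cost Sankoff bottom-up pass.

    ``tip_states``: (n_nodes, G) with 0/1 at tips, -1 elsewhere. Returns
    the (n_nodes, 2, G) minimum subtree cost table.
    """
    n, g = tip_states.shape
    cost = np.zeros((n, 2, g), dtype=np.int32)
    for v in tree.postorder():
        if tree.is_tip(v):
            s = tip_states[v]
            cost[v, 0] = np.where(s == 0, 0, _BIG)
            cost[v, 1] = np.where(s == 1, 0, _BIG)
        else:
            c0 = np.zeros(g, dtype=np.int32)
            c1 = np.zeros(g, dtype=np.int32)
            for ch in tree.children[v]:
                c0 += np.minimum(cost[ch, 0], cost[ch, 1] + 1)
                c1 += np.minimum(cost[ch, 1], cost[ch, 0] + 1)
            cost[v, 0] = c0
            cost[v, 1] = c1
    return cost


def fitch_count(tree: StrainTree, tip_states: Mapping[str, int]) -> int:
    """Minimum number of 0/1 state changes explaining ``tip_states``.

    Every tip must be assigned a state in {0, 1}.
    """
    missing = [lbl for lbl in tree.tip_labels if lbl not in tip_states]
    if missing:
        raise ValueError(f"missing tip states for {missing}")
    col = np.array([[tip_states[lbl]] for lbl in tree.tip_labels], dtype=np.int8)
    if not np.isin(col, (0, 1)).all():
        raise ValueError("tip states must be 0/1")
    cost = _sankoff_cost(tree, _tip_state_array(tree, col))
    return int(cost[0].min(axis=0)[0])


def event_counts(tree: StrainTree, columns: np.ndarray) -> np.ndarray:
    """Vectorised parsimony counts for many genes at once.

    ``columns``: (n_tips, G) 0/1 matrix ordered like ``tree.tip_labels``.
    """
    cost = _sankoff_cost(tree, _tip_state_array(tree, columns.astype(np.int8)))
    return cost[0].min(axis=0).astype(np.int64)


def count_all(tree: StrainTree, pa: PAMatrix) -> list[GeneEventCount]:
    """One :class:`GeneEventCount` per gene in ``pa``.

    Strain sets must match; invariant genes get ``n_g = 0`` and the
    invariant flag.
    """
    missing = [s for s in tree.tip_labels if s not in pa.values.columns]
    if missing:
        raise ValueError(f"matrix lacks strains present in the tree: {missing}")
    cols = pa.values[tree.tip_labels].to_numpy().T  # (n_tips, G)
    ng = event_counts(tree, cols)
    totals = cols.sum(axis=0)
    out = []
    for gene, n_g, tot in zip(pa.genes, ng, totals):
        inv = tot in (0, cols.shape[0])
        out.append(GeneEventCount(gene=gene, n_g=int(n_g), invariant=bool(inv)))
    return out


def parsimony_node_states(tree: StrainTree, columns: np.ndarray) -> np.ndarray:
    """One minimum-cost ancestral labelling per gene, (n_nodes, G).

    Deterministic tie-breaking: the root prefers state 0, every other node
    prefers its parent's state (no change). Tips keep their observed state.
    """
    tip_states = _tip_state_array(tree, columns.astype(np.int8))
    cost = _sankoff_cost(tree, tip_states)
    n, g = tip_states.shape
    states = np.zeros((n, g), dtype=np.int8)
    idx = np.arange(g)
    states[0] = (cost[0, 1] < cost[0, 0]).astype(np.int8)
    for v in range(1, n):
        p = states[tree.parent[v]]
        keep = cost[v][p, idx]
        flip = cost[v][1 - p, idx] + 1
        states[v] = np.where(flip < keep, 1 - p, p)
    return states


# ----------------------------------------------------------------------
# continuous (phenotype) reconstruction


def squared_change_reconstruction(
    tree: StrainTree, tip_values: np.ndarray
) -> np.ndarray:
    """Squared-change parsimony node values for a continuous character.

    ``tip_values`` is ordered like ``tree.tip_labels``. Minimises
    ``sum_edges (x_child - x_parent)^2 / length`` with tips fixed, by
    solving the weighted-Laplacian linear system for the internal nodes.
    Unspecified branch lengths count as 1; zero lengths are lifted to
    ``1e-8 x tree depth``.
    """
    if tree.n_tips < 2:
        raise ValueError("continuous reconstruction needs at least 2 tips")
    depth = tree.depth()
    eps = ZERO_LENGTH_EPS_FACTOR * (depth if depth > 0 else 1.0)
    lengths = tree.resolved_lengths(default=1.0, zero_eps=eps)
    values = np.zeros(tree.n_nodes)
    values[tree.tip_nodes] = tip_values
    internal = np.array(
        [v for v in range(tree.n_nodes) if not tree.is_tip(v)], dtype=np.int64
    )
    pos = {int(v): i for i, v in enumerate(internal)}
    m = len(internal)
    a = np.zeros((m, m))
    b = np.zeros(m)
    for v in range(1, tree.n_nodes):
        p = int(tree.parent[v])
        w = 1.0 / lengths[v]
        pi = pos[p]
        a[pi, pi] += w
        if tree.is_tip(v):
            b[pi] += w * values[v]
        else:
            vi = pos[int(v)]
            a[pi, vi] -= w
            a[vi, vi] += w
            a[vi, pi] -= w
    values[internal] = np.linalg.solve(a, b)
    return values


def ancestral_phenotype_changes(
    tree: StrainTree, strain_values: Mapping[str, float]
) -> list[BranchPhenotypeChange]:
    """Per-branch signed phenotype change under squared-change parsimony."""
    tips = tree.tip_values(strain_values)
    values = squared_change_reconstruction(tree, tips)
    return [
        BranchPhenotypeChange(branch=int(v), delta=float(values[v] - values[tree.parent[v]]))
        for v in tree.edges()
    ]
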