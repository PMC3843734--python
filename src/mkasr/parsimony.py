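"""Unordered-state parsimony with most-parsimonious-reconstruction sets.

Generalized (Sankoff) parsimony over an arbitrary cost matrix gives the
minimum total change cost and, for every node, the MPR set: the states that
node attains in at least one globally optimal reconstruction.  A node is
*unequivocal* when that set is a singleton — the criterion used when
counting parsimony reconstructions over a tree sample.  Unit costs
reproduce Fitch/Hartigan parsimony; branch lengths play no role anywhere.

Polytomies are handled natively by the dynamic program.  Missing and
polymorphic tips start with zero cost on each allowed state and an
effectively infinite cost elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .characters import MISSING, CodedCharacter
from .mk_likelihood import _check_taxa
from .tree_io import ArrayTree, PhyloTree

INF = np.inf


@dataclass
class ParsimonyResult:
    """Minimum tree length plus per-node MPR state sets."""

    length: float
    state_names: tuple[str, ...]
    mpr: list[frozenset[int]]      # indexed like the tree's ArrayTree
    _tree: PhyloTree

    def mpr_set(self, node: int) -> frozenset[int]:
        if not 0 <= node < len(self.mpr):
            raise IndexError(f"no node {node} in this tree")
        return self.mpr[node]

    def is_unequivocal(self, node: int) -> bool:
        return len(self.mpr_set(node)) == 1


def _tip_costs(at: ArrayTree, character: CodedCharacter, k: int) -> np.ndarray:
    cost = np.full((at.n_nodes, k), INF)
    for lbl, i in at.label_to_index.items():
        s = character.states.get(lbl, MISSING)
        allowed = range(k) if s is MISSING else s
        for si in allowed:
            cost[i, si] = 0.0
    return cost


def sankoff_reconstruct(
    tree: PhyloTree,
    character: CodedCharacter,
    cost: np.ndarray | None = None,
) -> ParsimonyResult:
    """Sankoff dynamic program with union-of-optima MPR backtracking.

    Down-pass: ``S[v][s]`` = minimal cost of v's subtree given v is in
    state s.  Up-pass: ``O[v][s]`` = minimal cost of everything outside v's
    subtree given v is in state s.  A state belongs to v's MPR set iff
    ``S[v][s] + O[v][s]`` attains the global minimum — i.e. some optimal
    full reconstruction assigns it.  No ACCTRAN/DELTRAN resolution is
    applied.
    """
    at = tree.arrays()
    _check_taxa(at, character)
    k = character.k
    if cost is None:
        cost = np.ones((k, k)) - np.eye(k)
    else:
        cost = np.asarray(cost, dtype=float)
        if cost.shape != (k, k):
            raise ValueError(f"cost matrix must be {k}x{k}")
        if np.any(np.diag(cost) != 0):
            raise ValueError("cost matrix diagonal must be zero")
        if np.any(cost < 0):
            raise ValueError("negative substitution cost")

    S = _tip_costs(at, character, k)
    # edge_min[c][s_p] = min over child states of (cost[s_p, s_c] + S[c][s_c])
    edge_min = np.zeros((at.n_nodes, k))
    for v in range(at.n_nodes):
        if not at.is_leaf[v]:
            S[v] = 0.0
            for c in at.children[v]:
                S[v] += edge_min[c]
        if at.parent[v] >= 0:
            edge_min[v] = (cost + S[v][None, :]).min(axis=1)
    root = at.root
    length = float(S[root].min())

    # up-pass: outside costs
    O = np.zeros((at.n_nodes, k))
    for v in range(at.n_nodes - 1, -1, -1):
        if at.is_leaf[v]:
            continue
        sib_sum = edge_min[at.children[v]].sum(axis=0)  # (k,) indexed by state of v
        for c in at.children[v]:
            other = O[v] + sib_sum - edge_min[c]        # cost outside c, by state of v
            O[c] = (other[:, None] + cost).min(axis=0)  # min over parent state

    total = S + O
    mpr = [
        frozenset(np.flatnonzero(np.isclose(total[v], length)).tolist())
        for v in range(at.n_nodes)
    ]
    return ParsimonyResult(length=length, state_names=character.state_names,
                           mpr=mpr, _tree=tree)


def fitch_length(tree: PhyloTree, character: CodedCharacter) -> int:
    """Minimum number of changes under unit costs (Hartigan down-pass).

    Handles polytomies and ambiguous tips; cross-checks the Sankoff length.
    """
    at = tree.arrays()
    _check_taxa(at, character)
    k = character.k
    length = 0
    sets: list[frozenset[int]] = [frozenset()] * at.n_nodes
    for v in range(at.n_nodes):
        if at.is_leaf[v]:
            sets[v] = character.allowed(at.leaf_labels[v])
        else:
            counts = np.zeros(k, dtype=int)
            for c in at.children[v]:
                for s in sets[c]:
                    counts[s] += 1
            top = counts.max()
            sets[v] = frozenset(np.flatnonzero(counts == top).tolist())
            length += len(at.children[v]) - int(top)
    return length


def is_unequivocal(result: ParsimonyResult, node: int) -> bool:
    """True iff the node's MPR set is a singleton (a single traced state)."""
    return result.is_unequivocal(node)
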