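"""Independent brute-force oracles used by the tests.

These enumerate over all internal-node state assignments, so they are
exponential in tree size and only run on tiny instances.  They share no
code with the pruning/Sankoff implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

from mkasr.mk_likelihood import build_rate_matrix


def enumeration_lnl(tree, character, model, fixed=None):
    """lnL by summing over every internal-node (and ambiguous-tip) assignment.

    L = sum over assignments of rootfreq[root state] * prod over edges of
    P(parent -> child, branch length), with P computed by scipy's expm.
    """
    at = tree.arrays()
    k = model.k
    Q = build_rate_matrix(model)
    P = [expm(Q * (0.0 if np.isnan(at.blen[v]) else at.blen[v]))
         for v in range(at.n_nodes)]
    internals = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
    tips = [v for v in range(at.n_nodes) if at.is_leaf[v]]
    tip_choices = [sorted(character.allowed(at.leaf_labels[v])) for v in tips]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        if fixed is not None and st.get(fixed[0], None) not in (None, fixed[1]):
            continue
        if fixed is not None and fixed[0] in st and st[fixed[0]] != fixed[1]:
            continue
        for tipstates in itertools.product(*tip_choices):
            full = dict(st)
            full.update(zip(tips, tipstates))
            if fixed is not None and full[fixed[0]] != fixed[1]:
                continue
            lik = model.root_freq[full[at.root]]
            for v in range(at.n_nodes - 1):
                lik *= P[v][full[at.parent[v]], full[v]]
            total += lik
    return math.log(total) if total > 0 else float("-inf")


def enumeration_parsimony(tree, character, cost=None):
    """Minimum change cost and exact MPR sets by exhaustive assignment.

    Returns ``(length, mpr)`` where ``mpr[v]`` is the set of states node v
    attains in at least one minimum-cost full assignment.
    """
    at = tree.arrays()
    k = character.k
    if cost is None:
        cost = np.ones((k, k)) - np.eye(k)
    internals = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
    tips = [v for v in range(at.n_nodes) if at.is_leaf[v]]
    tip_choices = [sorted(character.allowed(at.leaf_labels[v])) for v in tips]
    best = math.inf
    optima = []
    for assign in itertools.product(range(k), repeat=len(internals)):
        for tipstates in itertools.product(*tip_choices):
            full = dict(zip(internals, assign))
            full.update(zip(tips, tipstates))
            c = sum(
                cost[full[at.parent[v]], full[v]]
                for v in range(at.n_nodes - 1)
            )
            if c < best - 1e-12:
                best = c
                optima = [dict(full)]
            elif abs(c - best) <= 1e-12:
                optima.append(dict(full))
    mpr = [set() for _ in range(at.n_nodes)]
    for full in optima:
        for v, s in full.items():
            mpr[v].add(s)
    return best, [frozenset(m) for m in mpr]


def random_instance(rng, n_tips_max=6, k_max=3, ambiguous_p=0.2):
    """A random small tree + character + model-class-free state sets."""
    import mkasr

    n = int(rng.integers(2, n_tips_max + 1))
    k = int(rng.integers(2, k_max + 1))
    tree = mkasr.simulate_tree(n, seed=int(rng.integers(2**31 - 1)))
    states = {}
    for lbl in sorted(tree.tip_labels):
        if rng.random() < ambiguous_p:
            if rng.random() < 0.5:
                states[lbl] = None  # MISSING
            else:
                size = int(rng.integers(2, k + 1))
                states[lbl] = frozenset(
                    rng.choice(k, size=size, replace=False).tolist()
                )
        else:
            states[lbl] = frozenset([int(rng.integers(k))])
    char = mkasr.CodedCharacter("c", tuple(map(str, range(k))), states)
    return tree, char, k
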