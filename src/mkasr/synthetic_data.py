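"""Synthetic trees, pseudo-posterior tree samples, and Mk-evolved characters.

Everything the pipeline consumes can be generated here with a known ground
truth: birth-death trees, tree samples with topological noise (random NNI
moves plus lognormal branch-length jitter, emulating the variation in a
post-burn-in Bayesian sample, including the possibility that a focal clade
is absent from some trees), characters evolved forward under an Mk model,
and a preset scenario mirroring a published study design for parmelioid
lichens: ~9 major clades plus three nested higher-level groups (12 focal
nodes), four traits with alphabets of 5/2/2/3 states, and a pseudo-
posterior of trees over the same tips.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .characters import CharacterMatrix, CodedCharacter
from .mk_likelihood import MkModel, ModelClass, _transition_stack, build_rate_matrix
from .tree_io import NodeDefinition, PhyloTree, TreeSample


@dataclass
class SimulationTruth:
    """Ground truth of one simulated character: states at every node."""

    model: MkModel
    seed: int
    tip_states: dict            # tip label -> state index
    clade_states: dict          # frozenset(descendant tips) -> state index
    root_state: int


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                  seed: int = 0) -> PhyloTree:
    """Birth-death tree conditioned on ``n_tips`` extant tips, labels t1..tn."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth <= 0 or death < 0 or death >= birth:
        raise ValueError(f"need birth > 0 and 0 <= death < birth, got "
                         f"({birth}, {death})")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_tips, rng=rng,
    )
    dtree.seed_node.edge.length = None
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    return PhyloTree(dtree)


def _nni_candidates(dtree: dendropy.Tree):
    """Internal edges usable for an NNI: child internal, parent present."""
    out = []
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None and not nd.is_leaf():
            out.append(nd)
    return out


def _apply_nni(dtree: dendropy.Tree, rng: random.Random) -> None:
    cands = _nni_candidates(dtree)
    if not cands:
        return
    v = rng.choice(cands)
    u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    if not sibs or not v.child_nodes():
        return
    s = rng.choice(sibs)
    c = rng.choice(v.child_nodes())
    # swap the subtrees s and c across the internal edge (u, v)
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)


def make_pseudo_posterior(
    tree: PhyloTree,
    n_trees: int,
    nni_rate: float = 1.0,
    length_jitter: float = 0.1,
    seed: int = 0,
) -> TreeSample:
    """A seedable stand-in for a post-burn-in Bayesian tree sample.

    Each sample tree is a copy of the source with Poisson(``nni_rate``)
    random NNI rearrangements and multiplicative lognormal branch-length
    noise of sigma ``length_jitter``.  With both set to 0 the sample is
    ``n_trees`` identical copies.  The NNI moves create the node-absence
    phenomenon the summaries must account for.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if nni_rate < 0 or length_jitter < 0:
        raise ValueError("nni_rate and length_jitter must be >= 0")
    rng = random.Random(seed)
    trees = []
    for _ in range(n_trees):
        dt = tree.dtree.clone(depth=1)
        n_moves = _poisson(nni_rate, rng)
        for _ in range(n_moves):
            _apply_nni(dt, rng)
        if length_jitter > 0:
            for edge in dt.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= math.exp(rng.gauss(0.0, length_jitter))
        trees.append(PhyloTree(dt))
    return TreeSample(trees, provenance=f"pseudo-posterior(seed={seed})")


def _poisson(lam: float, rng: random.Random) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; lam is small (a few moves per tree) in practice
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


# ---------------------------------------------------------------------------
# characters


def simulate_character(
    tree: PhyloTree,
    model: MkModel,
    seed: int = 0,
    name: str = "trait",
    state_names: tuple[str, ...] | None = None,
    root_state: int | None = None,
) -> tuple[CodedCharacter, SimulationTruth]:
    """Evolve one character forward along the tree under the model.

    The root state is drawn from the model's root frequencies (or fixed via
    ``root_state``); each child's state is drawn from the transition-matrix
    row of its parent's state over the connecting branch.
    """
    at = tree.arrays()
    k = model.k
    if state_names is None:
        state_names = tuple(str(i) for i in range(k))
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(model)
    bl = at.blen.copy()
    bl[at.root] = 0.0
    if np.isnan(bl).any():
        raise ValueError("cannot simulate on a tree with absent branch lengths")
    P = _transition_stack(Q, bl)
    states = np.empty(at.n_nodes, dtype=int)
    if root_state is None:
        root_state = int(rng.choice(k, p=model.root_freq))
    states[at.root] = root_state
    # preorder = reversed postorder
    for v in range(at.n_nodes - 2, -1, -1):
        p = states[at.parent[v]]
        states[v] = int(rng.choice(k, p=P[v][p]))
    tip_states = {at.leaf_labels[i]: int(states[i])
                  for i in range(at.n_nodes) if at.is_leaf[i]}
    clade_states = {at.tipset(v): int(states[v])
                    for v in range(at.n_nodes) if not at.is_leaf[v]}
    char = CodedCharacter(
        name, state_names,
        {lbl: frozenset([s]) for lbl, s in tip_states.items()},
    )
    truth = SimulationTruth(model=model, seed=seed, tip_states=tip_states,
                            clade_states=clade_states, root_state=root_state)
    return char, truth


# ---------------------------------------------------------------------------
# the parmelioid-style scenario


#: Table-1-style trait alphabets of the emulated study
TRAIT_ALPHABETS = {
    "growth_form": ("crustose", "foliose", "fruticose", "subcrustose",
                    "umbilicate"),
    "epicortex": ("non-pored", "pored"),
    "pseudocyphellae": ("present", "absent"),
    "cortical_chemistry": ("atranorin", "melanin", "usnic_acid"),
}

#: the nine major clades (node ids "1".."9")
CLADE_NAMES = (
    "Parmotrema", "Xanthoparmelia", "Cetrelia", "Parmelina", "Hypotrachyna",
    "Parmelinopsis", "Nipponoparmelia", "Parmelia", "Melanohalea",
)

# designated ancestral state (index into the trait's alphabet) for each of
# the 12 focal nodes: the 9 clades plus the nested groups 10 = clades {1,2},
# 11 = {1,2,3}, 12 = all.  Patterned after the study system: mostly foliose,
# clade-specific epicortex/pseudocyphellae, chemistry split by clade.
DESIGNATED_STATES = {
    "growth_form":        {"1": 1, "2": 1, "3": 1, "4": 1, "5": 1, "6": 1,
                           "7": 1, "8": 1, "9": 1, "10": 1, "11": 1, "12": 1},
    "epicortex":          {"1": 0, "2": 1, "3": 0, "4": 1, "5": 1, "6": 1,
                           "7": 0, "8": 0, "9": 0, "10": 0, "11": 0, "12": 0},
    "pseudocyphellae":    {"1": 0, "2": 1, "3": 0, "4": 1, "5": 1, "6": 1,
                           "7": 0, "8": 0, "9": 0, "10": 0, "11": 0, "12": 0},
    "cortical_chemistry": {"1": 2, "2": 2, "3": 0, "4": 0, "5": 0, "6": 0,
                           "7": 0, "8": 0, "9": 1, "10": 2, "11": 2, "12": 2},
}


@dataclass
class ParmelioidScenario:
    """Everything the pipeline needs for the emulated study, plus truth."""

    tree: PhyloTree
    tree_sample: TreeSample
    matrix: CharacterMatrix
    node_definitions: list[NodeDefinition]
    truth: dict                  # trait -> {node_id -> true state index}
    tip_truth: dict              # trait -> {tip label -> state index}
    seed: int


def scenario_parmelioid(
    n_tips: int = 120,
    n_trees: int = 1000,
    seed: int = 0,
    full_size: bool = False,
    within_clade_rate: float = 0.02,
    nni_rate: float = 1.0,
    length_jitter: float = 0.1,
) -> ParmelioidScenario:
    """The emulated study design: 9 clades, 12 focal nodes, 4 traits.

    Tips are split across nine clades joined by a fixed backbone that
    nests clades 1+2 (node "10") inside 1+2+3 (node "11") inside the whole
    group (node "12", the root).  Each clade's subtree is a birth-death
    tree rescaled to a common height; clade stems are long relative to the
    within-clade depth.  Each trait evolves within each clade from the
    clade's designated ancestral state under a slow equal-rates Mk model,
    so clades are strongly (but not perfectly) enriched for their state —
    the clade-biased regime the reconstructions are meant to recover.

    ``full_size=True`` raises the tip count to the 323 OTUs of the
    emulated study.  The pseudo-posterior has ``n_trees`` trees.
    """
    if full_size:
        n_tips = 323
    if n_tips < 40:
        raise ValueError("need n_tips >= 40 to populate 9 clades")
    rng = random.Random(seed)
    n_clades = len(CLADE_NAMES)
    base, extra = divmod(n_tips, n_clades)
    sizes = [base + (1 if i < extra else 0) for i in range(n_clades)]

    clade_height = 0.5
    stem_length = 1.0
    backbone_step = 0.5

    subtrees = []
    for ci, (cname, size) in enumerate(zip(CLADE_NAMES, sizes)):
        sub = simulate_tree(size, birth=1.0, death=0.0,
                            seed=seed * 1009 + ci + 1).dtree
        _scale_to_height(sub, clade_height)
        for i, leaf in enumerate(sub.leaf_node_iter(), start=1):
            leaf.taxon.label = f"{cname}_{i}"
        subtrees.append(sub)

    # backbone: (((c1,c2),c3),c4..c9 ladder) with the root = whole group
    tns = dendropy.TaxonNamespace()
    newick_parts = []

    def sub_newick(i):
        s = subtrees[i].as_string(schema="newick",
                                  suppress_rooting=True).strip()
        return s.rstrip(";")

    node10 = f"({sub_newick(0)}:{stem_length},{sub_newick(1)}:{stem_length})"
    node11 = f"({node10}:{backbone_step},{sub_newick(2)}:{stem_length})"
    core = node11
    for i in range(3, n_clades - 1):
        core = f"({core}:{backbone_step},{sub_newick(i)}:{stem_length})"
    newick = f"({core}:{backbone_step},{sub_newick(n_clades - 1)}:{stem_length});"
    tree = PhyloTree(dendropy.Tree.get(data=newick, schema="newick",
                                       preserve_underscores=True,
                                       suppress_internal_node_taxa=True))

    # node definitions: clades 1-9, then the nested groups
    clade_tips = {
        str(ci + 1): frozenset(
            f"{CLADE_NAMES[ci]}_{i}" for i in range(1, sizes[ci] + 1)
        )
        for ci in range(n_clades)
    }
    defs = [
        NodeDefinition(str(ci + 1), clade_tips[str(ci + 1)],
                       f"{CLADE_NAMES[ci]} clade")
        for ci in range(n_clades)
    ]
    defs.append(NodeDefinition("10", clade_tips["1"] | clade_tips["2"],
                               "Parmotrema+Xanthoparmelia"))
    defs.append(NodeDefinition("11",
                               clade_tips["1"] | clade_tips["2"] | clade_tips["3"],
                               "Cetrelia+Parmotrema+Xanthoparmelia"))
    defs.append(NodeDefinition("12", frozenset().union(*clade_tips.values()),
                               "whole group"))

    # traits: evolve within each clade from its designated state
    data = {}
    tip_truth: dict = {trait: {} for trait in TRAIT_ALPHABETS}
    truth: dict = {}
    for tidx, (trait, alpha) in enumerate(TRAIT_ALPHABETS.items()):
        k = len(alpha)
        model = MkModel(k, ModelClass.RESTRICTED, np.array([within_clade_rate]))
        for ci, cname in enumerate(CLADE_NAMES):
            sub_tree = PhyloTree(subtrees[ci].clone(depth=1))
            root_state = DESIGNATED_STATES[trait][str(ci + 1)]
            char, tr = simulate_character(
                sub_tree, model, seed=seed * 7919 + tidx * 101 + ci,
                name=trait, state_names=alpha, root_state=root_state,
            )
            for lbl, s in tr.tip_states.items():
                data[(lbl, trait)] = frozenset([s])
                tip_truth[trait][lbl] = s
        truth[trait] = dict(DESIGNATED_STATES[trait])

    taxa = sorted(data_taxa := {lbl for lbl, _ in data})
    matrix = CharacterMatrix(taxa, TRAIT_ALPHABETS, data)

    sample = make_pseudo_posterior(tree, n_trees, nni_rate=nni_rate,
                                   length_jitter=length_jitter,
                                   seed=seed + 424243)
    return ParmelioidScenario(
        tree=tree, tree_sample=sample, matrix=matrix, node_definitions=defs,
        truth=truth, tip_truth=tip_truth, seed=seed,
    )


def _scale_to_height(dtree: dendropy.Tree, height: float) -> None:
    """Rescale all branch lengths so the max root-to-tip depth is ``height``."""
    depths = dtree.calc_node_root_distances(return_leaf_distances_only=True)
    cur = max(depths)
    if cur <= 0:
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = height / max(1, len(dtree.leaf_nodes()))
        return
    f = height / cur
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
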