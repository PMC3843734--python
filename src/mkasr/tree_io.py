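"""Rooted phylogenies, tree samples, and named-node resolution.

Trees are held as :class:`PhyloTree` objects wrapping a dendropy tree, with
an indexed array view (:class:`ArrayTree`) used by the numerical routines.
Focal nodes are specified by their defining taxon set and matched across
trees by strict monophyly: the node "exists" in a tree only if the MRCA of
the defining taxa contains exactly those taxa.  This is what allows a named
clade to be *absent* from some trees of a Bayesian sample, which the
summaries must account for.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml


class TreeParseError(ValueError):
    """Raised when a Newick/NEXUS input cannot be parsed."""


class NodeAbsent:
    """Sentinel: the defining taxon set is not monophyletic in this tree."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


#: Singleton returned by :meth:`PhyloTree.resolve_node` for non-monophyletic sets.
ABSENT = NodeAbsent()


@dataclass
class ArrayTree:
    """Postorder-indexed view of a rooted tree for fast numeric traversal.

    Node ``i``'s children all have indices ``< i`` (postorder), the root is
    the last index.  ``blen[i]`` is the length of the edge above node ``i``
    (``nan`` when absent; the root edge is ignored by all algorithms).
    """

    n_nodes: int
    n_tips: int
    parent: np.ndarray           # int, -1 at root
    children: list[list[int]]
    blen: np.ndarray             # float, nan = absent
    is_leaf: np.ndarray          # bool
    leaf_labels: list[str | None]   # label at leaf indices, None at internals
    label_to_index: dict[str, int]
    nodes: list                  # dendropy node objects aligned with indices

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def index_of(self, dnode) -> int:
        """Array index of a dendropy node belonging to this tree."""
        try:
            return self._node_index[id(dnode)]
        except AttributeError:
            self._node_index = {id(n): i for i, n in enumerate(self.nodes)}
            return self._node_index[id(dnode)]

    def tipset(self, i: int) -> frozenset[str]:
        """Descendant tip labels of node ``i`` (cached)."""
        try:
            return self._tipsets[i]
        except AttributeError:
            sets: list[frozenset[str]] = [frozenset()] * self.n_nodes
            for j in range(self.n_nodes):
                if self.is_leaf[j]:
                    sets[j] = frozenset([self.leaf_labels[j]])
                else:
                    s: set[str] = set()
                    for c in self.children[j]:
                        s |= sets[c]
                    sets[j] = frozenset(s)
            self._tipsets = sets
            return sets[i]


class PhyloTree:
    """A rooted tree with labeled tips and optional branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self.dtree = dtree
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        dup = {x for x in labels if labels.count(x) > 1}
        if dup:
            raise TreeParseError(f"duplicate tip labels: {sorted(dup)}")
        if not labels:
            raise TreeParseError("tree has no labeled tips")
        self._arrays: ArrayTree | None = None

    # -- basic interrogation -------------------------------------------------

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self.dtree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def arrays(self) -> ArrayTree:
        """Build (and cache) the postorder-indexed view."""
        if self._arrays is not None:
            return self._arrays
        nodes = list(self.dtree.postorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.full(n, np.nan)
        is_leaf = np.zeros(n, dtype=bool)
        children: list[list[int]] = [[] for _ in range(n)]
        leaf_labels: list[str | None] = [None] * n
        label_to_index: dict[str, int] = {}
        n_tips = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                children[parent[i]].append(i)
            if nd.edge.length is not None:
                blen[i] = float(nd.edge.length)
                if blen[i] < 0:
                    raise TreeParseError(
                        f"negative branch length {blen[i]} above "
                        f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                    )
            if nd.is_leaf():
                is_leaf[i] = True
                leaf_labels[i] = nd.taxon.label
                label_to_index[nd.taxon.label] = i
                n_tips += 1
        self._arrays = ArrayTree(
            n_nodes=n, n_tips=n_tips, parent=parent, children=children,
            blen=blen, is_leaf=is_leaf, leaf_labels=leaf_labels,
            label_to_index=label_to_index, nodes=nodes,
        )
        return self._arrays

    # -- node resolution -----------------------------------------------------

    def resolve_node(self, nd: "NodeDefinition"):
        """MRCA of ``nd.taxon_set`` iff that clade is exactly monophyletic.

        Returns the array index of the matching node, or :data:`ABSENT`
        when the MRCA contains extra taxa.  A taxon missing from the tree
        altogether is an error, distinct from ABSENT.
        """
        at = self.arrays()
        missing = nd.taxon_set - self.tip_labels
        if missing:
            raise KeyError(
                f"node {nd.node_id!r}: taxa not in tree: {sorted(missing)}"
            )
        want = frozenset(nd.taxon_set)
        # MRCA = shallowest node whose tip set is a superset of `want`;
        # walking up from one member tip finds it directly.
        start = at.label_to_index[next(iter(want))]
        v = start
        while not at.tipset(v) >= want:
            v = int(at.parent[v])
        return v if at.tipset(v) == want else ABSENT

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree({self.n_tips} tips)"


@dataclass
class NodeDefinition:
    """A named focal node, defined as the clade of a taxon set."""

    node_id: str
    taxon_set: frozenset[str]
    description: str = ""

    def __post_init__(self):
        self.node_id = str(self.node_id)
        self.taxon_set = frozenset(self.taxon_set)
        if len(self.taxon_set) < 2:
            raise ValueError(
                f"node {self.node_id!r}: need >= 2 taxa, got {len(self.taxon_set)}"
            )


@dataclass
class TreeSample:
    """An ordered sample of trees over one shared taxon set."""

    trees: list[PhyloTree]
    provenance: str = ""
    taxa: frozenset[str] = field(init=False)

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        self.taxa = self.trees[0].tip_labels
        for i, t in enumerate(self.trees[1:], start=1):
            if t.tip_labels != self.taxa:
                diff = sorted(t.tip_labels ^ self.taxa)
                raise ValueError(
                    f"tree {i} taxon set differs from tree 0; "
                    f"symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# parsing


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a rooted :class:`PhyloTree`.

    Missing branch lengths stay absent (``nan`` in the array view), they are
    never coerced to zero.  Unrooted input with a basal trifurcation is
    accepted, its basal node serving as the root.
    """
    if not text or not text.strip():
        raise TreeParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    return PhyloTree(dtree)


def _sniff_schema(path: str | Path) -> str:
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


def parse_tree_sample(path: str | Path, normalize_underscores: bool = False) -> TreeSample:
    """Read a multi-Newick file or a NEXUS TREES block into a TreeSample.

    NEXUS translate tables are applied so every tip carries its taxon label.
    All trees must share one taxon set; a mismatch is reported with the
    symmetric difference of the offending sets.
    """
    schema = _sniff_schema(path)
    try:
        tlist = dendropy.TreeList.get(
            path=str(path), schema=schema,
            preserve_underscores=not normalize_underscores,
            suppress_internal_node_taxa=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeParseError(f"cannot parse {path}: {exc}") from exc
    if len(tlist) == 0:
        raise TreeParseError(f"no trees found in {path}")
    return TreeSample([PhyloTree(t) for t in tlist], provenance=str(path))


def write_tree_sample(sample: TreeSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sample:
            fh.write(t.to_newick() + "\n")


def subsample_trees(sample: TreeSample, n: int, seed: int) -> TreeSample:
    """Uniform subsample without replacement, keeping original file order."""
    if not 1 <= n <= len(sample):
        raise ValueError(f"cannot take {n} trees from a sample of {len(sample)}")
    rng = random.Random(seed)
    keep = sorted(rng.sample(range(len(sample)), n))
    return TreeSample(
        [sample.trees[i] for i in keep],
        provenance=f"{sample.provenance} (subsample n={n}, seed={seed})",
    )


# ---------------------------------------------------------------------------
# node-definition config (YAML/JSON mapping node_id -> taxa or {taxa, description})


def load_node_definitions(path: str | Path) -> list[NodeDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping of node_id -> taxon list")
    defs = []
    for node_id, val in raw.items():
        if isinstance(val, Mapping):
            taxa = val["taxa"]
            desc = str(val.get("description", ""))
        else:
            taxa, desc = val, ""
        defs.append(NodeDefinition(str(node_id), frozenset(taxa), desc))
    return defs


def save_node_definitions(defs: Sequence[NodeDefinition], path: str | Path) -> None:
    out = {
        d.node_id: {"taxa": sorted(d.taxon_set), "description": d.description}
        for d in defs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
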