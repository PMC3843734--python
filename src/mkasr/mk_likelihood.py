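"""Mk-model likelihood machinery for discrete characters on rooted trees.

The Mk model is a continuous-time Markov chain over k states with
instantaneous rate matrix Q; two model classes are supported:

* RESTRICTED (equal rates, "ER"): one free rate shared by all transitions;
* UNRESTRICTED (all rates different, "ARD"): all k(k-1) off-diagonal rates
  free.

The likelihood of a character given a tree is computed by Felsenstein's
pruning algorithm with per-node rescaling.  Ancestral states at a focal
node are scored by *node fixing*: the node's conditional likelihood vector
is collapsed to a single state after its subtree pass, the rates are
(optionally) re-optimized under that constraint, and states are compared by
their log-likelihood difference.  A difference of 2 natural-log units is
the conventional significance bar, both for state calls at a node
(inclusive, >= 2) and for preferring the unrestricted over the restricted
model (strict, > 2).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .characters import MISSING, CodedCharacter
from .tree_io import ABSENT, ArrayTree, NodeDefinition, PhyloTree

RATE_LO = 1e-8
RATE_HI = 1e3

NEG_INF = float("-inf")


class ModelClass(enum.Enum):
    RESTRICTED = "restricted"      # equal rates (ER): 1 free rate
    UNRESTRICTED = "unrestricted"  # all rates different (ARD): k(k-1) free

    def n_rates(self, k: int) -> int:
        return 1 if self is ModelClass.RESTRICTED else k * (k - 1)


@dataclass
class MkModel:
    """A concrete Mk model: state count, class, rates, root frequencies.

    ``rates`` holds the single shared rate for RESTRICTED models or the
    k(k-1) off-diagonal rates in row-major order (q01, q02, ..., q10, ...)
    for UNRESTRICTED ones, in units of expected transitions per unit branch
    length.  Root frequencies default to uniform 1/k.
    """

    k: int
    model_class: ModelClass
    rates: np.ndarray
    root_freq: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("Mk model needs k >= 2 states")
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        want = self.model_class.n_rates(self.k)
        if self.rates.size != want:
            raise ValueError(
                f"{self.model_class.value} model with k={self.k} needs "
                f"{want} rates, got {self.rates.size}"
            )
        if np.any(self.rates < 0):
            raise ValueError(f"negative rate in {self.rates}")
        if self.root_freq is None:
            self.root_freq = np.full(self.k, 1.0 / self.k)
        else:
            self.root_freq = np.asarray(self.root_freq, dtype=float)
            if self.root_freq.shape != (self.k,) or not math.isclose(
                self.root_freq.sum(), 1.0, rel_tol=0, abs_tol=1e-9
            ):
                raise ValueError("root frequencies must be a length-k simplex")


def build_rate_matrix(model: MkModel) -> np.ndarray:
    """The k x k instantaneous rate matrix Q (rows sum to zero)."""
    k = model.k
    Q = np.zeros((k, k))
    if model.model_class is ModelClass.RESTRICTED:
        q = float(model.rates[0])
        Q[:] = q
    else:
        it = iter(model.rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1 within 1e-12, entries in [0, 1]."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    P = _transition_stack(Q, np.array([float(t)]))[0]
    return P


def _transition_stack(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t in ``ts`` at once.

    Spectral decomposition when the eigenvector matrix is well conditioned
    (one eig + small matmuls, vectorized over branches); otherwise a
    scipy.linalg.expm fallback per distinct t.
    """
    k = Q.shape[0]
    ts = np.asarray(ts, dtype=float)
    use_eig = False
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            use_eig = True
    except np.linalg.LinAlgError:
        pass
    if use_eig:
        E = np.exp(np.multiply.outer(ts, w))          # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
        P = np.ascontiguousarray(P.real)
    else:
        uniq, inv = np.unique(ts, return_inverse=True)
        stack = np.stack([expm(Q * t) for t in uniq])
        P = stack[inv]
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0.0] = np.eye(k)  # zero-length branches are exact, no leakage
    return P


# ---------------------------------------------------------------------------
# pruning


def _tip_partials(at: ArrayTree, character: CodedCharacter, k: int) -> np.ndarray:
    """Indicator partials at the tips: multi-hot over the allowed state set."""
    part = np.zeros((at.n_nodes, k))
    for lbl, i in at.label_to_index.items():
        s = character.states.get(lbl, MISSING)
        if s is MISSING:
            part[i, :] = 1.0
        else:
            for si in s:
                if not 0 <= si < k:
                    raise ValueError(
                        f"taxon {lbl!r}: state {si} outside alphabet size {k}"
                    )
                part[i, si] = 1.0
            if not part[i].any():
                raise ValueError(f"taxon {lbl!r}: empty state set")
    return part


def _check_taxa(at: ArrayTree, character: CodedCharacter) -> None:
    tips = frozenset(at.label_to_index)
    if character.taxa != tips:
        diff = sorted(character.taxa ^ tips)
        raise ValueError(f"character/tree taxon mismatch: {diff}")


def _branch_lengths(at: ArrayTree) -> np.ndarray:
    bl = at.blen.copy()
    bl[at.root] = 0.0  # root edge plays no role
    if np.isnan(bl).any():
        bad = [i for i in range(at.n_nodes) if np.isnan(bl[i])]
        raise ValueError(
            f"{len(bad)} branch length(s) absent; likelihood needs lengths"
        )
    return bl


def _prune(
    at: ArrayTree,
    tip_part: np.ndarray,
    P: np.ndarray,
    root_freq: np.ndarray,
    fixed: tuple[int, int] | None = None,
) -> float:
    """Post-order pruning with per-node rescaling; returns lnL (or -inf).

    Leaf messages (P along the tip edge times the tip indicator) are
    batched in one einsum; the Python loop runs over internal nodes only.
    """
    fixed_node = fixed[0] if fixed is not None else -1
    try:
        leaf_idx, internal_idx = at._prune_order
    except AttributeError:
        leaf_idx = np.flatnonzero(at.is_leaf)
        internal_idx = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
        at._prune_order = (leaf_idx, internal_idx)

    tp = tip_part
    if fixed_node >= 0 and at.is_leaf[fixed_node]:
        tp = tip_part.copy()
        keep = tp[fixed_node, fixed[1]]
        if keep <= 0.0:
            return NEG_INF
        tp[fixed_node, :] = 0.0
        tp[fixed_node, fixed[1]] = keep

    msg = np.empty_like(tip_part)
    msg[leaf_idx] = np.einsum("nij,nj->ni", P[leaf_idx], tp[leaf_idx])
    log_scale = 0.0
    root = at.root
    acc = None
    for v in internal_idx:
        cs = at.children[v]
        acc = msg[cs[0]].copy()
        for c in cs[1:]:
            acc *= msg[c]
        if v == fixed_node:
            keep = acc[fixed[1]]
            acc[:] = 0.0
            acc[fixed[1]] = keep
        m = acc.max()
        if m <= 0.0:
            return NEG_INF
        acc /= m
        log_scale += math.log(m)
        if v != root:
            msg[v] = P[v] @ acc
    if acc is None:  # single-tip tree: the root is the leaf
        acc = tp[root]
    root_lik = float(root_freq @ acc)
    if root_lik <= 0.0:
        return NEG_INF
    return math.log(root_lik) + log_scale


def prune_likelihood(
    tree: PhyloTree,
    character: CodedCharacter,
    model: MkModel,
    fixed: tuple | None = None,
) -> float:
    """Log-likelihood of the character on the tree under a concrete model.

    ``fixed=(node, state)`` conditions on the ancestral state at a node
    ("fossil" fixing): the node's partial vector is collapsed to that state
    after its subtree pass.  ``node`` may be an array index or a
    :class:`NodeDefinition`.  Impossible data yield ``-inf``, never an
    exception, so fixed-state scans can include zero-likelihood states.
    """
    at = tree.arrays()
    _check_taxa(at, character)
    k = model.k
    Q = build_rate_matrix(model)
    P = _transition_stack(Q, _branch_lengths(at))
    tip_part = _tip_partials(at, character, k)
    fx = None
    if fixed is not None:
        node, state = fixed
        if isinstance(node, NodeDefinition):
            node = tree.resolve_node(node)
            if node is ABSENT:
                raise ValueError(f"fixed node not present in tree")
        if not 0 <= state < k:
            raise ValueError(f"fixed state {state} outside alphabet size {k}")
        fx = (int(node), int(state))
    return _prune(at, tip_part, P, model.root_freq, fx)


# ---------------------------------------------------------------------------
# rate fitting


@dataclass
class FitResult:
    """Maximum-likelihood rate fit for one character on one tree."""

    lnl: float
    model: MkModel
    converged: bool
    restarts_used: int

    @property
    def rates(self) -> np.ndarray:
        return self.model.rates


def _nll_factory(at, tip_part, root_freq, k, model_class, fixed):
    bl = _branch_lengths(at)

    def nll(log_rates: np.ndarray) -> float:
        rates = np.exp(np.atleast_1d(log_rates))
        model = MkModel(k, model_class, rates, root_freq)
        Q = build_rate_matrix(model)
        P = _transition_stack(Q, bl)
        lnl = _prune(at, tip_part, P, root_freq, fixed)
        return 1e12 if lnl == NEG_INF else -lnl
    return nll


def fit_mk(
    tree: PhyloTree,
    character: CodedCharacter,
    model_class: ModelClass = ModelClass.UNRESTRICTED,
    restarts: int = 5,
    seed: int = 0,
    root_freq: np.ndarray | None = None,
    fixed: tuple | None = None,
    init_rates: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> FitResult:
    """Maximize lnL over the model's rates by bounded optimization.

    Rates are optimized on a log scale within [1e-8, 1e3].  The first start
    is ``init_rates`` (or a moderate default); the remaining ``restarts - 1``
    starts are drawn log-uniformly under ``seed`` — near-flat likelihoods at
    small rates make multi-start worthwhile.  Deterministic under ``seed``.
    """
    at = tree.arrays()
    _check_taxa(at, character)
    k = character.k
    if root_freq is None:
        root_freq = np.full(k, 1.0 / k)
    tip_part = _tip_partials(at, character, k)
    fx = None
    if fixed is not None:
        node, state = fixed
        if isinstance(node, NodeDefinition):
            node = tree.resolve_node(node)
            if node is ABSENT:
                raise ValueError("fixed node not present in tree")
        fx = (int(node), int(state))
    nll = _nll_factory(at, tip_part, root_freq, k, model_class, fx)
    n_par = model_class.n_rates(k)
    lo, hi = math.log(RATE_LO), math.log(RATE_HI)
    rng = np.random.default_rng(seed)

    best_lnl, best_rates, converged, used = NEG_INF, None, False, 0
    if model_class is ModelClass.RESTRICTED:
        # one parameter: coarse log-grid then bounded scalar polish
        grid = np.log(np.geomspace(RATE_LO * 10, RATE_HI / 10, 13))
        x0 = min(grid, key=lambda x: nll(np.array([x])))
        res = minimize_scalar(
            lambda x: nll(np.array([x])), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-9},
        )
        used = 1
        cand = [(res.fun, np.array([res.x]), bool(res.success)),
                (nll(np.array([x0])), np.array([x0]), True)]
        for f, x, ok in cand:
            if -f > best_lnl:
                best_lnl, best_rates, converged = -f, np.exp(x), ok
    else:
        starts = []
        if init_rates is not None:
            starts.append(np.log(np.clip(init_rates, RATE_LO, RATE_HI)))
        else:
            starts.append(np.full(n_par, math.log(0.5)))
        while len(starts) < max(1, restarts):
            starts.append(rng.uniform(math.log(1e-3), math.log(10.0), n_par))
        for x0 in starts:
            used += 1
            res = minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[(lo, hi)] * n_par,
                options={"ftol": tol, "maxiter": maxiter},
            )
            if -res.fun > best_lnl:
                best_lnl = -res.fun
                best_rates = np.exp(res.x)
                converged = bool(res.success)
    if best_rates is None or best_lnl <= -1e11:
        raise RuntimeError(
            f"rate optimization failed for {character.name!r} "
            f"({model_class.value}, {used} restarts)"
        )
    model = MkModel(k, model_class, best_rates, root_freq)
    return FitResult(lnl=best_lnl, model=model, converged=converged,
                     restarts_used=used)


# ---------------------------------------------------------------------------
# model choice


@dataclass
class ModelChoice:
    """Restricted-vs-unrestricted comparison for one character."""

    delta_lnl: float          # lnL(unrestricted) - lnL(restricted), >= 0
    significant: bool         # delta > threshold (strict)
    chosen_class: ModelClass
    threshold: float


def compare_models(
    fit_unrestricted: FitResult,
    fit_restricted: FitResult,
    threshold: float = 2.0,
    policy: str = "always-unrestricted",
) -> ModelChoice:
    """Compare nested Mk fits by their log-likelihood difference.

    The difference is significant when strictly greater than ``threshold``
    (default 2 log units; a difference of exactly 2 is not significant).
    ``policy`` sets the class actually used downstream:
    ``always-unrestricted`` keeps the unrestricted model regardless (the
    pragmatic choice when batching many characters), ``by-test`` keeps the
    restricted model unless the test is significant.
    """
    delta = fit_unrestricted.lnl - fit_restricted.lnl
    if delta < -1e-6:
        raise RuntimeError(
            f"nesting violated: lnL(unrestricted)={fit_unrestricted.lnl:.6f} < "
            f"lnL(restricted)={fit_restricted.lnl:.6f}; optimization failed"
        )
    significant = delta > threshold
    if policy == "always-unrestricted":
        chosen = ModelClass.UNRESTRICTED
    elif policy == "by-test":
        chosen = ModelClass.UNRESTRICTED if significant else ModelClass.RESTRICTED
    else:
        raise ValueError(f"unknown model policy {policy!r}")
    return ModelChoice(delta_lnl=delta, significant=significant,
                       chosen_class=chosen, threshold=threshold)


# ---------------------------------------------------------------------------
# node reconstruction


@dataclass
class NodeReconstructionML:
    """Fixed-state ML scan at one node: per-state lnL and differences.

    ``delta_lnl[s] = lnL(best state) - lnL(state s)`` (0 at the best state);
    the call is significant when every competing state is at least
    ``threshold`` log units worse than the best.
    """

    node_id: str
    state_names: tuple[str, ...]
    lnls: np.ndarray
    delta_lnl: np.ndarray = field(init=False)
    best_state: int = field(init=False)
    significant: bool = field(init=False)
    threshold: float = 2.0

    def __post_init__(self):
        self.lnls = np.asarray(self.lnls, dtype=float)
        self.best_state = int(np.argmax(self.lnls))
        best = self.lnls[self.best_state]
        self.delta_lnl = best - self.lnls
        others = np.delete(self.delta_lnl, self.best_state)
        self.significant = bool(others.size and np.all(others >= self.threshold))

    @property
    def best_state_name(self) -> str:
        return self.state_names[self.best_state]


def ml_node_reconstruction(
    tree: PhyloTree,
    character: CodedCharacter,
    model_class: ModelClass,
    node: NodeDefinition,
    threshold: float = 2.0,
    reoptimize: bool = True,
    restarts: int = 5,
    seed: int = 0,
    root_freq: np.ndarray | None = None,
    base_fit: FitResult | None = None,
) -> NodeReconstructionML:
    """Score each possible ancestral state at a focal node by node fixing.

    For each state s the node is fixed to s and the likelihood maximized —
    with the rates re-optimized under the constraint (default, warm-started
    at the unconstrained MLE) or held frozen at the unconstrained MLE
    (``reoptimize=False``; in that mode the per-state likelihoods sum
    exactly to the unconstrained likelihood).
    """
    v = tree.resolve_node(node)
    if v is ABSENT:
        raise ValueError(
            f"node {node.node_id!r} not present in this tree; use the "
            "tree-sample summaries for nodes that vary across trees"
        )
    if base_fit is None:
        base_fit = fit_mk(tree, character, model_class, restarts=restarts,
                          seed=seed, root_freq=root_freq)
    k = character.k
    lnls = np.empty(k)
    for s in range(k):
        if reoptimize:
            try:
                # warm-started from the unconstrained MLE; the constrained
                # optimum is nearby, so a looser tolerance suffices
                fr = fit_mk(
                    tree, character, model_class, restarts=1, seed=seed,
                    root_freq=root_freq, fixed=(v, s),
                    init_rates=base_fit.model.rates, tol=1e-7, maxiter=120,
                )
                lnls[s] = max(fr.lnl, prune_likelihood(
                    tree, character, base_fit.model, fixed=(v, s)))
            except RuntimeError:
                lnls[s] = NEG_INF
        else:
            lnls[s] = prune_likelihood(tree, character, base_fit.model,
                                       fixed=(v, s))
    return NodeReconstructionML(
        node_id=node.node_id, state_names=character.state_names,
        lnls=lnls, threshold=threshold,
    )


def marginal_probabilities(
    tree: PhyloTree,
    character: CodedCharacter,
    model: MkModel,
    node,
) -> np.ndarray:
    """Marginal ancestral state probabilities at a node, rates held fixed.

    ``P(state s) = L(fixed at s) / sum_s' L(fixed at s')``; by the law of
    total probability the denominator equals the unconstrained likelihood.
    """
    if isinstance(node, NodeDefinition):
        v = tree.resolve_node(node)
        if v is ABSENT:
            raise ValueError(f"node {node.node_id!r} not present in tree")
    else:
        v = int(node)
    lnls = np.array([
        prune_likelihood(tree, character, model, fixed=(v, s))
        for s in range(model.k)
    ])
    if np.all(np.isneginf(lnls)):
        raise ValueError("all fixed-state likelihoods are zero: inconsistent data")
    return np.exp(lnls - logsumexp(lnls))
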