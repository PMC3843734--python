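"""Reconstruction summaries over single trees and Bayesian tree samples.

Three methods are summarized per focal node and character:

* ``ML`` — single-tree maximum likelihood with node fixing (per-state
  log-likelihood differences);
* ``ML_BMCMC`` — per-tree ML over a sample of trees, counting the fraction
  of trees in which each state is significantly reconstructed;
* ``MP`` — parsimony over the same sample, counting only *unequivocal*
  reconstructions (singleton MPR set).

All tree-sample fractions use the total number of trees as denominator, so
mass "missing to reach 1.00" is exactly the share of trees in which the
node is not present (not monophyletic).  The bookkeeping identity

    sum(per-state support) + equivocal + (1 - fraction_present) = 1

holds for every summary by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .characters import CodedCharacter
from .mk_likelihood import (
    NEG_INF,
    ModelClass,
    NodeReconstructionML,
    fit_mk,
    ml_node_reconstruction,
    prune_likelihood,
)
from .parsimony import sankoff_reconstruct
from .tree_io import ABSENT, NodeDefinition, PhyloTree, TreeSample

log = logging.getLogger(__name__)

METHODS = ("ML", "ML_BMCMC", "MP")


@dataclass
class NodeSummary:
    """Per-node reconstruction summary for one character and one method."""

    node_id: str
    trait: str
    coding: str                    # "multistate" or "binary:<state>"
    method: str                    # ML | ML_BMCMC | MP
    state_names: tuple[str, ...]
    fraction_present: float
    support: dict = field(default_factory=dict)   # state name -> fraction of trees
    equivocal: float = 0.0         # fraction of trees present but undecided
    headline_state: str | None = None
    significant: bool = False
    delta_lnl: dict | None = None  # ML only: state name -> ΔlnL
    mean_marginals: dict | None = None  # ML_BMCMC: mean P over present trees

    @property
    def absent(self) -> float:
        return 1.0 - self.fraction_present

    def check_identity(self, tol: float = 1e-9) -> float:
        """Residual of support + equivocal + absent - 1 (should be ~0)."""
        total = sum(self.support.values()) + self.equivocal + self.absent
        resid = abs(total - 1.0)
        if resid > tol:
            raise AssertionError(
                f"bookkeeping identity violated at node {self.node_id}: "
                f"residual {resid:.3e}"
            )
        return resid


def _headline_from_support(
    summary_support: Mapping[str, float], fraction_present: float
) -> tuple[str | None, bool]:
    """Headline = most-supported state; significant when it carries a
    majority of all trees."""
    if not summary_support or all(v == 0 for v in summary_support.values()):
        return None, False
    best = max(summary_support, key=summary_support.get)
    return best, summary_support[best] > 0.5


# ---------------------------------------------------------------------------
# parsimony over a tree sample


def mp_over_trees(
    sample: TreeSample,
    nodes: Sequence[NodeDefinition],
    character: CodedCharacter,
) -> dict[str, NodeSummary]:
    """Unequivocal-parsimony state counts over a tree sample.

    Per tree: resolve each focal node; where present, run unit-cost Sankoff
    and count state s only when the node's MPR set is exactly {s}.  Nodes
    with larger MPR sets count as equivocal.
    """
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    n = len(sample)
    k = character.k
    present = {d.node_id: 0 for d in nodes}
    counts = {d.node_id: np.zeros(k) for d in nodes}
    equiv = {d.node_id: 0 for d in nodes}
    for tree in sample:
        res = None
        for d in nodes:
            v = tree.resolve_node(d)
            if v is ABSENT:
                continue
            if res is None:
                res = sankoff_reconstruct(tree, character)
            present[d.node_id] += 1
            mpr = res.mpr_set(v)
            if len(mpr) == 1:
                counts[d.node_id][next(iter(mpr))] += 1
            else:
                equiv[d.node_id] += 1
    out = {}
    for d in nodes:
        support = {
            character.state_names[s]: counts[d.node_id][s] / n for s in range(k)
        }
        fp = present[d.node_id] / n
        headline, sig = _headline_from_support(support, fp)
        out[d.node_id] = NodeSummary(
            node_id=d.node_id, trait=character.name, coding="",
            method="MP", state_names=character.state_names,
            fraction_present=fp, support=support,
            equivocal=equiv[d.node_id] / n,
            headline_state=headline, significant=sig,
        )
    return out


# ---------------------------------------------------------------------------
# ML over a tree sample


def ml_over_trees(
    sample: TreeSample,
    nodes: Sequence[NodeDefinition],
    character: CodedCharacter,
    model_class: ModelClass = ModelClass.UNRESTRICTED,
    decision_threshold: float = 2.0,
    restarts: int = 1,
    seed: int = 0,
    max_failure_fraction: float = 0.1,
) -> dict[str, NodeSummary]:
    """Per-tree ML reconstruction counts over a tree sample.

    For each tree the model is fitted once, then each present focal node is
    scanned by fixed-state likelihoods at the fitted rates.  State s is
    counted for a tree when every competing state is at least
    ``decision_threshold`` log units worse; otherwise the tree counts as
    ambiguous.  Optimization failures are logged and counted as ambiguous;
    more than ``max_failure_fraction`` of trees failing is an error.

    Successive trees of a sample differ only by small rearrangements and
    branch noise, so each per-tree fit is warm-started from the previous
    tree's maximum-likelihood rates.
    """
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    n = len(sample)
    k = character.k
    present = {d.node_id: 0 for d in nodes}
    counts = {d.node_id: np.zeros(k) for d in nodes}
    equiv = {d.node_id: 0 for d in nodes}
    marg_sum = {d.node_id: np.zeros(k) for d in nodes}
    failures = 0
    warm_rates = None
    for ti, tree in enumerate(sample):
        resolved = [(d, tree.resolve_node(d)) for d in nodes]
        live = [(d, v) for d, v in resolved if v is not ABSENT]
        for d, _ in live:
            present[d.node_id] += 1
        if not live:
            continue
        try:
            fit = fit_mk(tree, character, model_class, restarts=restarts,
                         seed=seed + ti, init_rates=warm_rates,
                         tol=1e-6, maxiter=120)
            warm_rates = fit.model.rates
        except RuntimeError as exc:
            failures += 1
            log.warning("tree %d: fit failed (%s); counted ambiguous", ti, exc)
            for d, _ in live:
                equiv[d.node_id] += 1
            continue
        for d, v in live:
            lnls = np.array([
                prune_likelihood(tree, character, fit.model, fixed=(v, s))
                for s in range(k)
            ])
            if np.all(np.isneginf(lnls)):
                equiv[d.node_id] += 1
                continue
            finite = lnls[np.isfinite(lnls)]
            p = np.exp(lnls - max(finite))
            marg_sum[d.node_id] += p / p.sum()
            best = int(np.argmax(lnls))
            others = np.delete(lnls, best)
            decided = others.size == 0 or np.all(
                lnls[best] - others >= decision_threshold)
            if ti < 20:  # per-tree decisions, capped to keep 1000-tree logs sane
                log.debug("tree %d node %s: best=%s decided=%s", ti,
                          d.node_id, character.state_names[best], decided)
            if decided:
                counts[d.node_id][best] += 1
            else:
                equiv[d.node_id] += 1
    if failures > max_failure_fraction * n:
        raise RuntimeError(
            f"{failures}/{n} per-tree optimizations failed "
            f"(> {max_failure_fraction:.0%})"
        )
    out = {}
    for d in nodes:
        support = {
            character.state_names[s]: counts[d.node_id][s] / n for s in range(k)
        }
        fp = present[d.node_id] / n
        headline, sig = _headline_from_support(support, fp)
        marg = None
        if present[d.node_id] > 0:
            m = marg_sum[d.node_id] / present[d.node_id]
            marg = {character.state_names[s]: float(m[s]) for s in range(k)}
        out[d.node_id] = NodeSummary(
            node_id=d.node_id, trait=character.name, coding="",
            method="ML_BMCMC", state_names=character.state_names,
            fraction_present=fp, support=support,
            equivocal=equiv[d.node_id] / n,
            headline_state=headline, significant=sig, mean_marginals=marg,
        )
    return out


# ---------------------------------------------------------------------------
# single-tree ML


def ml_single_tree(
    tree: PhyloTree,
    nodes: Sequence[NodeDefinition],
    character: CodedCharacter,
    model_class: ModelClass = ModelClass.UNRESTRICTED,
    threshold: float = 2.0,
    reoptimize: bool = True,
    restarts: int = 5,
    seed: int = 0,
) -> dict[str, NodeSummary]:
    """Node-fixing ML on one reference tree; summaries carry ΔlnL values.

    Nodes that do not resolve on this tree are reported with
    ``fraction_present = 0`` rather than raised, so one unresolvable node
    does not abort a batch.
    """
    base_fit = fit_mk(tree, character, model_class, restarts=restarts, seed=seed)
    out = {}
    for d in nodes:
        v = tree.resolve_node(d)
        if v is ABSENT:
            out[d.node_id] = NodeSummary(
                node_id=d.node_id, trait=character.name, coding="",
                method="ML", state_names=character.state_names,
                fraction_present=0.0, equivocal=0.0,
            )
            continue
        rec = ml_node_reconstruction(
            tree, character, model_class, d, threshold=threshold,
            reoptimize=reoptimize, restarts=restarts, seed=seed,
            base_fit=base_fit,
        )
        out[d.node_id] = NodeSummary(
            node_id=d.node_id, trait=character.name, coding="",
            method="ML", state_names=character.state_names,
            fraction_present=1.0,
            support={rec.best_state_name: 1.0} if rec.significant else {},
            equivocal=0.0 if rec.significant else 1.0,
            headline_state=rec.best_state_name, significant=rec.significant,
            delta_lnl={
                character.state_names[s]: float(rec.delta_lnl[s])
                for s in range(character.k)
            },
        )
    return out


# ---------------------------------------------------------------------------
# binary-coding roll-up and the method x coding grid


def binary_trait_summary(
    per_state: Mapping[str, dict[str, NodeSummary]],
    trait: str,
    state_names: Sequence[str],
) -> dict[str, NodeSummary]:
    """Roll k presence/absence analyses into one trait-level summary.

    ``per_state`` maps source-state name -> node summaries of that derived
    character.  The headline state for the trait is the derived character
    with the strongest supported "present"; disagreements among derived
    characters (two states both called present) are kept visible in the
    support dict rather than silently resolved.
    """
    node_ids = next(iter(per_state.values())).keys()
    out = {}
    for nid in node_ids:
        support, deltas = {}, {}
        fp, sig_states = 0.0, []
        method = None
        for sname in state_names:
            s = per_state[sname][nid]
            method = s.method
            fp = max(fp, s.fraction_present)
            if s.method == "ML":
                present_delta = s.delta_lnl.get("present") if s.delta_lnl else None
                deltas[sname] = present_delta
                strength = 0.0
                if s.headline_state == "present":
                    strength = 1.0 if s.significant else 0.5
                support[sname] = strength
                if s.headline_state == "present" and s.significant:
                    sig_states.append(sname)
            else:
                support[sname] = s.support.get("present", 0.0)
                if s.headline_state == "present" and s.significant:
                    sig_states.append(sname)
        headline = max(support, key=support.get) if support else None
        if headline is not None and support[headline] == 0.0:
            headline = None
        out[nid] = NodeSummary(
            node_id=nid, trait=trait, coding="binary", method=method or "",
            state_names=tuple(state_names),
            fraction_present=fp, support=support,
            headline_state=headline,
            significant=headline in sig_states if headline else False,
            delta_lnl=deltas or None,
        )
    return out


AGREEMENT_LEVELS = ("all-agree", "agree-without-support", "conflict")


def compare_grid(summaries: Iterable[NodeSummary]) -> pd.DataFrame:
    """The methods x codings concordance grid.

    One row per node x trait with the headline state (and its significance)
    for each of the six method x coding cells, plus an agreement class:
    ``all-agree`` (every available cell names the same state, all
    significant), ``agree-without-support`` (same state, support lacking in
    some cells), ``conflict`` (cells name different states).  Missing cells
    are flagged, not fatal.
    """
    cells: dict[tuple, NodeSummary] = {}
    for s in summaries:
        coding = s.coding or "multistate"
        cells[(s.node_id, s.trait, s.method, coding)] = s
    rows = []
    keys = sorted({(nid, trait) for nid, trait, _, _ in cells})
    for nid, trait in keys:
        row: dict = {"node_id": nid, "trait": trait}
        states, sigs, gaps = [], [], 0
        for method in METHODS:
            for coding in ("binary", "multistate"):
                cell = cells.get((nid, trait, method, coding))
                col = f"{method}:{coding}"
                if cell is None or cell.fraction_present == 0:
                    row[col] = "--"
                    gaps += 1
                    continue
                st = cell.headline_state or "?"
                row[col] = f"{st}{'*' if cell.significant else ''}"
                if cell.headline_state is not None:
                    states.append(cell.headline_state)
                    sigs.append(cell.significant)
        if not states:
            agreement = "no-call"
        elif len(set(states)) > 1:
            agreement = "conflict"
        elif all(sigs):
            agreement = "all-agree"
        else:
            agreement = "agree-without-support"
        row["agreement"] = agreement
        row["gaps"] = gaps
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_table(summaries: Iterable[NodeSummary]) -> pd.DataFrame:
    """Long-format table: one row per node x trait x coding x method."""
    rows = []
    for s in summaries:
        rows.append({
            "node_id": s.node_id,
            "trait": s.trait,
            "coding": s.coding or "multistate",
            "method": s.method,
            "fraction_present": s.fraction_present,
            "headline_state": s.headline_state,
            "significant": s.significant,
            "equivocal": s.equivocal,
            "support": ";".join(
                f"{k}={v:.4g}" for k, v in sorted(s.support.items())
            ),
            "delta_lnl": ";".join(
                f"{k}={v:.4g}" for k, v in sorted((s.delta_lnl or {}).items())
                if v is not None
            ),
        })
    return pd.DataFrame(rows)
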