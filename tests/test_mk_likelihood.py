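"""Mk likelihood machinery: rate matrices, P(t), pruning, fitting,
model choice, and node-fixing reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mkasr
from mkasr.mk_likelihood import (
    NEG_INF,
    MkModel,
    ModelClass,
    build_rate_matrix,
    compare_models,
    transition_probabilities,
)
from oracles import enumeration_lnl, random_instance

ER = ModelClass.RESTRICTED
ARD = ModelClass.UNRESTRICTED


def char_from(tree, assignment, k=2):
    return mkasr.CodedCharacter(
        "c", tuple(map(str, range(k))),
        {l: (frozenset([s]) if s is not None else None)
         for l, s in assignment.items()},
    )


class TestRateMatrix:
    def test_restricted_k2(self):
        Q = build_rate_matrix(MkModel(2, ER, [1.0]))
        assert np.allclose(Q, [[-1, 1], [1, -1]])

    def test_unrestricted_k2(self):
        Q = build_rate_matrix(MkModel(2, ARD, [1.0, 2.0]))
        assert np.allclose(Q, [[-1, 1], [2, -2]])
        assert np.allclose(Q.sum(axis=1), 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MkModel(2, ER, [-0.5])

    def test_wrong_rate_count_rejected(self):
        with pytest.raises(ValueError):
            MkModel(3, ARD, [1.0, 2.0])


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(MkModel(3, ER, [0.7]))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(3))

    def test_long_time_uniform_stationary(self):
        Q = build_rate_matrix(MkModel(2, ER, [1.0]))
        P = transition_probabilities(Q, 500.0)
        assert np.allclose(P, 0.5, atol=1e-9)

    def test_two_state_closed_form(self):
        # P(stay) = 1/2 + 1/2 exp(-2qt) for the symmetric 2-state chain
        q, t = 1.0, 0.5
        Q = build_rate_matrix(MkModel(2, ER, [q]))
        P = transition_probabilities(Q, t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2 * q * t),
                                        abs=1e-12)
        assert P[0, 0] == pytest.approx(0.68394, abs=1e-5)

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(MkModel(2, ER, [1.0]))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            rates = rng.uniform(0, 3, k * (k - 1))
            Q = build_rate_matrix(MkModel(k, ARD, rates))
            P = transition_probabilities(Q, float(rng.uniform(0, 5)))
            assert np.all(P >= 0) and np.all(P <= 1)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-12)

    @given(t1=st.floats(0, 3), t2=st.floats(0, 3), k=st.integers(2, 5),
           seed=st.integers(0, 2**20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_chapman_kolmogorov(self, t1, t2, k, seed):
        rng = np.random.default_rng(seed)
        Q = build_rate_matrix(MkModel(k, ARD, rng.uniform(0, 2, k * (k - 1))))
        lhs = transition_probabilities(Q, t1) @ transition_probabilities(Q, t2)
        rhs = transition_probabilities(Q, t1 + t2)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestPruneLikelihood:
    def test_single_tip(self):
        t = mkasr.parse_newick("A:1.0;")
        ch = char_from(t, {"A": 0})
        lnl = mkasr.prune_likelihood(t, ch, MkModel(2, ER, [1.0]))
        assert lnl == pytest.approx(math.log(0.5))

    def test_impossible_data_gives_neg_inf(self):
        t = mkasr.parse_newick("(A:0,B:0);")
        ch = char_from(t, {"A": 0, "B": 1})
        assert mkasr.prune_likelihood(t, ch, MkModel(2, ER, [1.0])) == NEG_INF

    def test_matches_enumeration_oracle(self):
        """Pruning equals brute-force enumeration over all internal-node
        assignments on random small instances (incl. node fixing)."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            tree, ch, k = random_instance(rng)
            mc = ARD if rng.random() < 0.5 else ER
            model = MkModel(k, mc, rng.uniform(0.05, 2.0, mc.n_rates(k)))
            a = mkasr.prune_likelihood(tree, ch, model)
            b = enumeration_lnl(tree, ch, model)
            if math.isinf(a) or math.isinf(b):
                assert a == b
            else:
                assert a == pytest.approx(b, rel=1e-10)
            at = tree.arrays()
            internals = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
            v, s = int(rng.choice(internals)), int(rng.integers(k))
            af = mkasr.prune_likelihood(tree, ch, model, fixed=(v, s))
            bf = enumeration_lnl(tree, ch, model, fixed=(v, s))
            if math.isinf(af) or math.isinf(bf):
                assert af == bf
            else:
                assert af == pytest.approx(bf, rel=1e-10)

    def test_invariant_under_state_relabeling_er(self):
        t = mkasr.parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        model = MkModel(2, ER, [0.7])
        a = mkasr.prune_likelihood(
            t, char_from(t, {"A": 0, "B": 0, "C": 1, "D": 1}), model)
        b = mkasr.prune_likelihood(
            t, char_from(t, {"A": 1, "B": 1, "C": 0, "D": 0}), model)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invariant_under_child_reordering(self):
        model = MkModel(3, ARD, np.arange(1, 7) * 0.2)
        a = mkasr.parse_newick("((A:1,B:2):0.5,(C:1,D:1.5):0.7);")
        b = mkasr.parse_newick("((D:1.5,C:1):0.7,(B:2,A:1):0.5);")
        assign = {"A": 0, "B": 1, "C": 2, "D": 0}
        la = mkasr.prune_likelihood(a, char_from(a, assign, k=3), model)
        lb = mkasr.prune_likelihood(b, char_from(b, assign, k=3), model)
        assert la == pytest.approx(lb, rel=1e-12)

    def test_taxon_mismatch_rejected(self):
        t = mkasr.parse_newick("(A:1,B:1);")
        ch = char_from(t, {"A": 0, "Z": 1})
        with pytest.raises(ValueError, match="mismatch"):
            mkasr.prune_likelihood(t, ch, MkModel(2, ER, [1.0]))


class TestFitMk:
    def test_invariant_character_drives_rate_to_floor(self):
        t = mkasr.simulate_tree(8, seed=1)
        ch = char_from(t, {l: 0 for l in t.tip_labels})
        fit = mkasr.fit_mk(t, ch, ER, seed=0)
        assert fit.rates[0] < 1e-4
        assert fit.lnl == pytest.approx(math.log(0.5), abs=1e-4)

    def test_nesting_unrestricted_at_least_restricted(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 5:
            tree, ch, k = random_instance(rng, n_tips_max=8, ambiguous_p=0.0)
            probe = mkasr.prune_likelihood(tree, ch, MkModel(k, ER, [0.5]))
            if math.isinf(probe):
                continue  # conflicting states across a zero-length cherry
            fu = mkasr.fit_mk(tree, ch, ARD, seed=1)
            fr = mkasr.fit_mk(tree, ch, ER, seed=1)
            assert fu.lnl >= fr.lnl - 1e-6
            checked += 1

    def test_er_rate_recovery_median_within_20pct(self):
        """100 characters simulated at q=0.5 on a 200-tip tree: the median
        per-character MLE is close to truth."""
        tree = mkasr.simulate_tree(200, seed=5)
        model = MkModel(2, ER, [0.5])
        fits = []
        for i in range(100):
            ch, _ = mkasr.simulate_character(tree, model, seed=1000 + i)
            fits.append(mkasr.fit_mk(tree, ch, ER, seed=i).rates[0])
        med = float(np.median(fits))
        assert abs(med - 0.5) / 0.5 < 0.2

    def test_deterministic_under_seed(self):
        tree = mkasr.simulate_tree(10, seed=2)
        ch, _ = mkasr.simulate_character(tree, MkModel(2, ER, [0.5]), seed=4)
        a = mkasr.fit_mk(tree, ch, ARD, seed=9)
        b = mkasr.fit_mk(tree, ch, ARD, seed=9)
        assert a.lnl == b.lnl
        assert np.array_equal(a.rates, b.rates)


class TestCompareModels:
    def _fake_fit(self, lnl):
        return mkasr.FitResult(lnl=lnl, model=MkModel(2, ER, [1.0]),
                               converged=True, restarts_used=1)

    def test_large_difference_significant(self):
        c = compare_models(self._fake_fit(-10.0), self._fake_fit(-20.5))
        assert c.delta_lnl == pytest.approx(10.5)
        assert c.significant
        assert c.chosen_class is ARD

    def test_small_difference_not_significant(self):
        c = compare_models(self._fake_fit(-10.0), self._fake_fit(-11.5))
        assert not c.significant

    def test_boundary_exactly_two_not_significant(self):
        c = compare_models(self._fake_fit(-10.0), self._fake_fit(-12.0))
        assert c.delta_lnl == pytest.approx(2.0)
        assert not c.significant

    def test_policy_by_test_keeps_restricted(self):
        c = compare_models(self._fake_fit(-10.0), self._fake_fit(-11.0),
                           policy="by-test")
        assert c.chosen_class is ER

    def test_nesting_violation_raises(self):
        with pytest.raises(RuntimeError, match="nesting"):
            compare_models(self._fake_fit(-12.0), self._fake_fit(-10.0))


class TestNodeReconstruction:
    def test_symmetric_data_is_equivocal(self, balanced_four_tip):
        t = balanced_four_tip
        ch = char_from(t, {"A": 0, "B": 0, "C": 1, "D": 1})
        nd = mkasr.NodeDefinition("root", {"A", "B", "C", "D"})
        rec = mkasr.ml_node_reconstruction(t, ch, ER, nd, seed=0)
        assert rec.delta_lnl.max() == pytest.approx(0.0, abs=1e-6)
        assert not rec.significant

    def test_clade_fixed_state_is_significant(self):
        """A 10-tip clade fixed for state 1 on a long stem: its MRCA is
        reconstructed as state 1 with ΔlnL >= 2."""
        left = mkasr.simulate_tree(10, seed=3)
        sub = left.to_newick().rstrip(";")
        right = mkasr.simulate_tree(10, seed=4).to_newick().rstrip(";")
        right = right.replace("t", "u")  # disjoint labels
        tree = mkasr.parse_newick(f"({sub}:2.0,{right}:2.0);")
        assignment = {l: (1 if l.startswith("t") else 0)
                      for l in tree.tip_labels}
        ch = char_from(tree, assignment)
        nd = mkasr.NodeDefinition("clade", {l for l in tree.tip_labels
                                            if l.startswith("t")})
        rec = mkasr.ml_node_reconstruction(tree, ch, ER, nd, seed=0)
        assert rec.best_state_name == "1"
        assert rec.significant

    def test_absent_node_raises(self):
        t = mkasr.parse_newick("((A:1,C:1):1,B:1);")
        ch = char_from(t, {"A": 0, "B": 0, "C": 1})
        nd = mkasr.NodeDefinition("n", {"A", "B"})
        with pytest.raises(ValueError, match="not present"):
            mkasr.ml_node_reconstruction(t, ch, ER, nd)

    def test_marginal_decomposition_identity(self):
        """With rates frozen at the MLE, sum_s L(fixed at s) equals the
        unconstrained likelihood (law of total probability)."""
        rng = np.random.default_rng(11)
        from scipy.special import logsumexp
        checked = 0
        while checked < 10:
            tree, ch, k = random_instance(rng, n_tips_max=8, ambiguous_p=0.1)
            if math.isinf(mkasr.prune_likelihood(tree, ch, MkModel(k, ER, [0.5]))):
                continue
            checked += 1
            fit = mkasr.fit_mk(tree, ch, ER, seed=1)
            at = tree.arrays()
            internals = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
            v = int(rng.choice(internals))
            lnls = [mkasr.prune_likelihood(tree, ch, fit.model, fixed=(v, s))
                    for s in range(k)]
            assert logsumexp(lnls) == pytest.approx(fit.lnl, rel=1e-9, abs=1e-9)

    def test_marginals_sum_to_one_and_match_oracle(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 5:
            tree, ch, k = random_instance(rng, n_tips_max=5, ambiguous_p=0.0)
            model = MkModel(k, ER, [0.6])
            if math.isinf(mkasr.prune_likelihood(tree, ch, model)):
                continue
            checked += 1
            at = tree.arrays()
            internals = [v for v in range(at.n_nodes) if not at.is_leaf[v]]
            v = int(rng.choice(internals))
            p = mkasr.marginal_probabilities(tree, ch, model, v)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            lnum = np.array([enumeration_lnl(tree, ch, model, fixed=(v, s))
                             for s in range(k)])
            expected = np.exp(lnum - enumeration_lnl(tree, ch, model))
            assert np.allclose(p, expected, atol=1e-8)

    def test_threshold_zero_names_marginal_argmax(self):
        rng = np.random.default_rng(17)
        tree, ch, k = random_instance(rng, n_tips_max=6, ambiguous_p=0.0)
        fit = mkasr.fit_mk(tree, ch, ER, seed=2)
        at = tree.arrays()
        internals = [v for v in range(at.n_nodes)
                     if not at.is_leaf[v] and v != at.root]
        v = internals[0] if internals else at.root
        nd = mkasr.NodeDefinition("n", at.tipset(v))
        rec = mkasr.ml_node_reconstruction(tree, ch, ER, nd, threshold=0.0,
                                           reoptimize=False, seed=2)
        marg = mkasr.marginal_probabilities(tree, ch, fit.model, v)
        assert rec.best_state == int(np.argmax(marg))
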