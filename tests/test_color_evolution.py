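"""Mk likelihood, model set, ancestral states, stochastic mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from campion.color_evolution import (build_model_set, compare_models, fit_mk,
                                     history_to_simmap_newick, marginal_asr,
                                     mk_loglik, stochastic_map, FittedMk)
from campion.phylo import PhyloTree
from conftest import random_tree

MODELS = {m.name: m for m in build_model_set()}
STATES = ("white", "pink", "red")


def enumeration_loglik(tree, tips, Q, prior):
    """Brute-force sum over all internal-state assignments (tiny trees)."""
    code = {s: i for i, s in enumerate(STATES)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    P = {v: expm(Q * tree.edge_length[v]) for v in range(tree.n_nodes)
         if v != tree.root}
    tip_code = [code[tips[l]] for l in tree.tip_labels]
    total = 0.0
    for assign in itertools.product(range(3), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for i in range(tree.n_tips):
            state[i] = tip_code[i]
        lik = prior[state[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                lik *= P[v][state[tree.parent[v]], state[v]]
        total += lik
    return np.log(total)


def enumeration_marginals(tree, tips, Q, prior):
    code = {s: i for i, s in enumerate(STATES)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    P = {v: expm(Q * tree.edge_length[v]) for v in range(tree.n_nodes)
         if v != tree.root}
    tip_code = [code[tips[l]] for l in tree.tip_labels]
    marg = {v: np.zeros(3) for v in internal}
    for assign in itertools.product(range(3), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for i in range(tree.n_tips):
            state[i] = tip_code[i]
        lik = prior[state[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                lik *= P[v][state[tree.parent[v]], state[v]]
        for v in internal:
            marg[v][state[v]] += lik
    return {v: m / m.sum() for v, m in marg.items()}


class TestModelSet:
    def test_seven_distinct_models_with_expected_free_counts(self):
        assert len(MODELS) == 7
        expected = {"ER": 1, "SYM": 3, "ARD": 6, "stepwise_reversible": 4,
                    "stepwise_pink_red_irrev": 3, "stepwise_red_white_irrev": 3,
                    "stepwise_red_pink_red_white_irrev": 2}
        for name, k in expected.items():
            assert MODELS[name].n_free == k
        constraint_sets = {m.index for m in MODELS.values()}
        assert len(constraint_sets) == 7

    def test_er_shares_one_rate_index(self):
        idx = np.asarray(MODELS["ER"].index)
        off = idx[~np.eye(3, dtype=bool)]
        assert set(off) == {1}

    def test_stepwise_forbids_direct_white_red(self):
        iw, ir = STATES.index("white"), STATES.index("red")
        for name, m in MODELS.items():
            if name.startswith("stepwise"):
                idx = np.asarray(m.index)
                assert idx[iw, ir] == 0 and idx[ir, iw] == 0

    def test_q_rows_sum_to_zero_and_forbidden_rates_exact_zero(self):
        for m in MODELS.values():
            Q = m.Q(np.linspace(0.1, 0.6, m.n_free))
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)
            idx = np.asarray(m.index)
            off = ~np.eye(3, dtype=bool)
            assert np.all(Q[off & (idx == 0)] == 0.0)

    def test_transition_matrix_rows_sum_to_one(self):
        from campion.color_evolution import _transition_matrix
        rng = np.random.default_rng(0)
        for m in MODELS.values():
            Q = m.Q(rng.uniform(0.01, 2.0, m.n_free))
            for t in (0.0, 0.013, 1.0, 47.0):
                P = _transition_matrix(Q, t)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
                assert np.all(P >= 0)


class TestLikelihood:
    def test_rate_to_zero_monomorphic_limit(self, three_tip_tree):
        tips = {"A": "pink", "B": "pink", "C": "pink"}
        lnl = mk_loglik(three_tip_tree, tips, MODELS["ER"], [1e-10])
        assert lnl == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_pruning_equals_enumeration_3tip(self, three_tip_tree):
        tips = {"A": "pink", "B": "white", "C": "red"}
        Q = MODELS["ER"].Q([0.1])
        ref = enumeration_loglik(three_tip_tree, tips, Q, np.full(3, 1 / 3))
        assert mk_loglik(three_tip_tree, tips, MODELS["ER"], [0.1]) == \
            pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("newick", [
        "((A:0.5,B:1.2):0.8,C:2.0);",
        "((A:0.5,B:1.2):0.8,(C:0.3,D:0.9):1.1);",
        "(((A:0.2,B:0.4):0.3,C:0.9):0.5,D:1.4);",
        "(A:1,B:1,C:1,D:1);",
    ])
    @pytest.mark.parametrize("model", ["ER", "SYM", "ARD", "stepwise_reversible"])
    def test_pruning_equals_enumeration_all_small_trees(self, newick, model):
        tree = PhyloTree.from_newick(newick)
        rng = np.random.default_rng(hash((newick, model)) % 2**31)
        m = MODELS[model]
        rates = rng.uniform(0.05, 1.5, m.n_free)
        Q = m.Q(rates)
        for states in [("pink",) * tree.n_tips,
                       tuple(rng.choice(STATES, tree.n_tips))]:
            tips = dict(zip(tree.tip_labels, states))
            ref = enumeration_loglik(tree, tips, Q, np.full(3, 1 / 3))
            assert mk_loglik(tree, tips, m, rates) == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_tip_input_ordering(self, five_tip_tree):
        tips = {"A": "red", "B": "pink", "C": "white", "D": "pink", "E": "red"}
        shuffled = dict(reversed(list(tips.items())))
        a = mk_loglik(five_tip_tree, tips, MODELS["SYM"], [0.1, 0.2, 0.3])
        b = mk_loglik(five_tip_tree, shuffled, MODELS["SYM"], [0.1, 0.2, 0.3])
        assert a == b


class TestFitting:
    def test_nested_models_likelihood_ordering(self, study):
        tree = study["tree"]
        tips = study["table"].colors.loc[tree.tip_labels]
        er = fit_mk(tree, tips, MODELS["ER"])
        ard = fit_mk(tree, tips, MODELS["ARD"])
        assert ard.log_likelihood >= er.log_likelihood - 1e-6

    def test_aic_formula_and_retained_flag(self, study):
        tree = study["tree"]
        tips = study["table"].colors.loc[tree.tip_labels]
        table = compare_models(tree, tips)
        for _, row in table.iterrows():
            fit = table.attrs["fits"][row.model]
            assert row.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)
        assert table.retained.iloc[0]
        assert (table.loc[table.retained, "delta_aic"] < 2).all()

    def test_aic_invariant_to_state_relabeling_for_er_and_sym(self, study):
        tree = study["tree"]
        tips = study["table"].colors.loc[tree.tip_labels]
        relabel = {"white": "red", "pink": "white", "red": "pink"}
        swapped = tips.map(relabel)
        for name in ("ER", "SYM"):
            a = fit_mk(tree, tips, MODELS[name])
            b = fit_mk(tree, swapped, MODELS[name])
            assert a.aic == pytest.approx(b.aic, abs=1e-4)


class TestMarginalAsr:
    def test_matches_enumeration_oracle(self):
        tree = PhyloTree.from_newick("((A:0.6,B:1.1):0.7,(C:0.4,D:1.3):0.9);")
        tips = {"A": "white", "B": "pink", "C": "red", "D": "pink"}
        m = MODELS["SYM"]
        rates = np.array([0.2, 0.35, 0.15])
        fit = FittedMk(model=m, rates=rates, log_likelihood=0.0, aic=0.0)
        res = marginal_asr(tree, tips, fit)
        ref = enumeration_marginals(tree, tips, m.Q(rates), np.full(3, 1 / 3))
        for v, probs in ref.items():
            assert np.allclose(res.node_probs.loc[v].to_numpy(), probs, atol=1e-10)

    def test_probabilities_sum_to_one(self, study):
        tree = study["tree"]
        tips = study["table"].colors.loc[tree.tip_labels]
        fit = fit_mk(tree, tips, MODELS["ER"])
        res = marginal_asr(tree, tips, fit)
        assert np.allclose(res.node_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_monomorphic_low_rate_pins_every_node(self, five_tip_tree):
        tips = dict.fromkeys("ABCDE", "red")
        fit = FittedMk(model=MODELS["ER"], rates=np.array([1e-6]),
                       log_likelihood=0.0, aic=0.0)
        res = marginal_asr(five_tip_tree, tips, fit)
        assert (res.node_probs["red"] > 0.99).all()


class TestStochasticMap:
    def test_zero_rate_monomorphic_no_transitions(self, five_tip_tree):
        tips = dict.fromkeys("ABCDE", "pink")
        fit = FittedMk(model=MODELS["ER"], rates=np.array([1e-9]),
                       log_likelihood=0.0, aic=0.0)
        sm = stochastic_map(five_tip_tree, tips, fit, n_sims=50, seed=0)
        assert (sm.transition_counts.to_numpy() == 0).all()

    def test_seed_determinism(self, five_tip_tree):
        tips = {"A": "red", "B": "pink", "C": "white", "D": "pink", "E": "red"}
        fit = fit_mk(five_tip_tree, tips, MODELS["ER"])
        a = stochastic_map(five_tip_tree, tips, fit, n_sims=40, seed=9,
                           keep_histories=True)
        b = stochastic_map(five_tip_tree, tips, fit, n_sims=40, seed=9,
                           keep_histories=True)
        pd.testing.assert_frame_equal(a.transition_counts, b.transition_counts)
        assert a.histories == b.histories

    def test_stepwise_histories_never_jump_white_red(self, study):
        tree = study["tree"]
        tips = study["table"].colors.loc[tree.tip_labels]
        fit = fit_mk(tree, tips, MODELS["stepwise_reversible"])
        sm = stochastic_map(tree, tips, fit, n_sims=200, seed=3)
        assert (sm.transition_counts["white->red"] == 0).all()
        assert (sm.transition_counts["red->white"] == 0).all()

    def test_histories_consistent_with_tips_and_exportable(self, five_tip_tree):
        tips = {"A": "red", "B": "pink", "C": "white", "D": "pink", "E": "red"}
        fit = fit_mk(five_tip_tree, tips, MODELS["ER"])
        sm = stochastic_map(five_tip_tree, tips, fit, n_sims=20, seed=1,
                            keep_histories=True)
        lab = five_tip_tree.tip_labels
        for hist in sm.histories:
            for i, l in enumerate(lab):
                last_state = hist[i][-1][0]
                assert STATES[last_state] == tips[l]
            for v, segs in hist.items():
                total = sum(d for _, d in segs)
                assert total == pytest.approx(five_tip_tree.edge_length[v])
        nwk = history_to_simmap_newick(five_tip_tree, sm.histories[0], STATES)
        assert nwk.count("{") == five_tip_tree.n_nodes - 1
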