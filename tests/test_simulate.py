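"""Forward sampling, mutilation, suite generation, fixture scenarios."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from causalvote import (
    CategoricalDomain,
    Dag,
    DiscreteBayesNet,
    InterventionPlan,
    discretize,
    pooling_trap_fixture,
    forward_sample,
    generate_suite,
    mutilate,
)
from causalvote.simulate import (
    asia_like_net,
    bn_from_json,
    bn_to_json,
    chain_net,
    collider_net,
    pooling_trap_net,
    named_net,
)


def _crosstab(data, a, b):
    table = data.table
    return pd.crosstab(table[a], table[b]).to_numpy()


class TestDiscreteBayesNet:
    def test_cpt_rows_must_sum_to_one(self):
        dom = CategoricalDomain({"X": ("0", "1")})
        with pytest.raises(ValueError, match="sums"):
            DiscreteBayesNet(Dag(["X"]), dom, {"X": np.array([[0.5, 0.6]])})

    def test_cpt_shape_checked(self):
        bn = chain_net()
        with pytest.raises(ValueError, match="shape"):
            DiscreteBayesNet(bn.dag, bn.domain, {**bn.cpts, "Y": np.array([[0.5, 0.5]])})

    def test_json_round_trip(self):
        bn = asia_like_net()
        back = bn_from_json(bn_to_json(bn))
        assert back.dag == bn.dag
        assert back.domain == bn.domain
        for node in bn.dag.nodes:
            assert np.allclose(back.cpts[node], bn.cpts[node])

    def test_named_net_lookup(self):
        assert named_net("collider").dag.edges == collider_net().dag.edges
        with pytest.raises(ValueError, match="unknown network"):
            named_net("nope")


class TestForwardSample:
    def test_degenerate_cpt_gives_constant_column(self):
        dom = CategoricalDomain({"X": ("0", "1")})
        bn = DiscreteBayesNet(Dag(["X"]), dom, {"X": np.array([[0.0, 1.0]])})
        data = forward_sample(bn, 50, seed=0)
        assert (data.codes[:, 0] == 1).all()

    def test_fair_coin_frequency(self):
        dom = CategoricalDomain({"X": ("0", "1")})
        bn = DiscreteBayesNet(Dag(["X"]), dom, {"X": np.array([[0.5, 0.5]])})
        data = forward_sample(bn, 10_000, seed=1)
        freq = data.codes[:, 0].mean()
        assert abs(freq - 0.5) < 0.02  # 4 sigma

    def test_chain_agreement_rate(self):
        bn = chain_net(p_follow=0.9)
        data = forward_sample(bn, 10_000, seed=2)
        agree = (data.codes[:, 0] == data.codes[:, 1]).mean()
        assert abs(agree - 0.9) < 0.02

    def test_deterministic_given_seed(self):
        bn = collider_net()
        a = forward_sample(bn, 100, seed=3)
        b = forward_sample(bn, 100, seed=3)
        assert np.array_equal(a.codes, b.codes)

    def test_mask_all_false_by_default(self):
        data = forward_sample(chain_net(), 10, seed=0)
        assert not data.mask.any()


class TestMutilate:
    def test_clamped_node_constant_children_still_respond(self):
        bn = chain_net(p_follow=0.9)
        cut = mutilate(bn, InterventionPlan("X", "1"))
        data = forward_sample(cut, 5000, seed=4)
        x, y = data.codes[:, 0], data.codes[:, 1]
        assert (x == 1).all()
        # Y conditions on the constant X: P(Y=1 | X=1) = 0.9
        assert abs(y.mean() - 0.9) < 0.02

    def test_fat_hand_child_constant_regardless_of_parent(self):
        bn = chain_net()
        cut = mutilate(bn, InterventionPlan("X", "0", fat_hand={"Y": "1"}))
        data = forward_sample(cut, 1000, seed=5)
        assert (data.codes[:, 1] == 1).all()

    def test_original_untouched_and_incoming_arcs_cut(self):
        bn = chain_net()
        cut = mutilate(bn, InterventionPlan("Y", "0"))
        assert ("X", "Y") not in cut.dag.edges
        assert ("Y", "Z") in cut.dag.edges
        assert ("X", "Y") in bn.dag.edges

    def test_double_clamp_rejected(self):
        plan = InterventionPlan("X", "0", fat_hand={"X": "1"})
        with pytest.raises(ValueError, match="twice"):
            mutilate(chain_net(), plan)

    def test_fat_hand_must_be_child(self):
        with pytest.raises(ValueError, match="child"):
            mutilate(chain_net(), InterventionPlan("X", "0", fat_hand={"Z": "1"}))

    def test_nondescendant_marginals_preserved(self):
        bn = collider_net()  # X -> Z <- Y
        cut = mutilate(bn, InterventionPlan("X", "1"))
        a = forward_sample(bn, 10_000, seed=6)
        b = forward_sample(cut, 10_000, seed=7)
        # Y is not a descendant of X: its marginal must be unchanged
        counts = np.array(
            [np.bincount(a.codes[:, 1], minlength=2), np.bincount(b.codes[:, 1], minlength=2)]
        )
        _, p, _, _ = chi2_contingency(counts)
        assert p > 0.001


class TestGenerateSuite:
    def test_shape_and_leaf_avoidance(self):
        suite, truth, plans = generate_suite(
            asia_like_net(), k_obs=2, k_int=7, n_per_exp=50, fat_hand_rate=1.0, seed=0
        )
        assert suite.k == 9
        leaves = set(truth.leaves())
        assert leaves == {"xray", "dysp"}
        for exp, plan in zip(suite, plans):
            assert exp.n_samples == 50
            if plan is None:
                assert exp.declared_targets == frozenset()
            else:
                assert exp.declared_targets == {plan.primary_target}
                assert plan.primary_target not in leaves

    def test_hidden_fat_hand_never_leaks(self):
        suite, truth, plans = generate_suite(
            asia_like_net(), k_obs=1, k_int=6, n_per_exp=30, fat_hand_rate=1.0, seed=1
        )
        dom = suite.domain
        for exp, plan in zip(suite, plans):
            if plan is None or not plan.fat_hand:
                continue
            for child in plan.fat_hand:
                assert child not in exp.declared_targets
                assert not exp.mask[:, dom.index(child)].any()
                # yet the hidden clamp really happened
                assert len(set(exp.codes[:, dom.index(child)])) == 1

    def test_k_int_zero_purely_observational(self):
        suite, _, plans = generate_suite(
            chain_net(), k_obs=3, k_int=0, n_per_exp=20, seed=2
        )
        assert all(p is None for p in plans)
        assert not any(e.mask.any() for e in suite)

    def test_fat_hand_rate_zero_perfect_interventions(self):
        _, _, plans = generate_suite(
            asia_like_net(), k_obs=0, k_int=5, n_per_exp=20, fat_hand_rate=0.0, seed=3
        )
        assert all(p is not None and not p.fat_hand for p in plans)

    def test_bitwise_reproducible(self):
        a, _, _ = generate_suite(chain_net(), k_obs=1, k_int=2, n_per_exp=25, seed=4)
        b, _, _ = generate_suite(chain_net(), k_obs=1, k_int=2, n_per_exp=25, seed=4)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.codes, eb.codes)
            assert np.array_equal(ea.mask, eb.mask)
            assert ea.declared_targets == eb.declared_targets


class TestPoolingTrapFixture:
    def test_observational_independence(self):
        suite, _ = pooling_trap_fixture(0)
        obs = suite[0]
        _, p, _, _ = chi2_contingency(_crosstab(obs, "Vi", "Vj"))
        assert p > 0.01

    def test_experiment_a_perfect_dependence(self):
        suite, _ = pooling_trap_fixture(0)
        exp_a = suite[1]
        assert exp_a.experiment_id == "intA"
        assert np.array_equal(exp_a.codes[:, 0], exp_a.codes[:, 1])
        assert exp_a.declared_targets == {"Vi"}

    def test_pooled_dependence_detectable(self):
        suite, _ = pooling_trap_fixture(0)
        pooled = suite.concatenate()
        _, p, _, _ = chi2_contingency(_crosstab(pooled, "Vi", "Vj"))
        assert p < 0.01

    def test_truth_is_the_collider(self):
        _, truth = pooling_trap_fixture(1)
        assert truth.edges == {("Vi", "Vk"), ("Vj", "Vk")}

    def test_experiment_b_clamps_vk(self):
        suite, _ = pooling_trap_fixture(2)
        exp_b = suite[2]
        assert exp_b.declared_targets == {"Vk"}
        assert len(set(exp_b.codes[:, 2])) == 1


class TestDiscretize:
    def test_binary_column_unchanged_up_to_labels(self):
        rng = np.random.default_rng(0)
        col = rng.integers(2, size=100).astype(float)
        data, _ = discretize(pd.DataFrame({"X": col}), bins=2)
        assert np.array_equal(data.codes[:, 0], col.astype(int))

    def test_normal_column_split_at_median(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=101)
        data, edges = discretize(pd.DataFrame({"X": col}), bins=2)
        counts = np.bincount(data.codes[:, 0])
        assert abs(counts[0] - counts[1]) <= 1
        assert edges["X"][1] == pytest.approx(np.median(col))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=80)
        a, _ = discretize(pd.DataFrame({"X": col}), bins=4)
        b, _ = discretize(pd.DataFrame({"X": np.exp(col)}), bins=4)
        assert np.array_equal(a.codes, b.codes)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize(pd.DataFrame({"X": [1.0] * 10}), bins=2)
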