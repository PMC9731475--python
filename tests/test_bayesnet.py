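import numpy as np
import pandas as pd
import pytest

from strikerisk._rng import substream
from strikerisk.bayesnet import (
    BayesNet,
    CPTSet,
    LikelihoodLabelSpec,
    NetworkStructure,
    NodeSpec,
    build_network,
    crossvalidate,
    derive_likelihood_label,
    discretise_node,
    infer,
    influence_strength,
    learn_cpts,
    roc_auc,
)
from strikerisk.report import default_structure


def two_node_net() -> BayesNet:
    return build_network(
        NetworkStructure(
            nodes=[NodeSpec("A", ("a0", "a1")), NodeSpec("B", ("b0", "b1"))],
            edges=[("A", "B")],
        )
    )


def worked_cpts(net: BayesNet) -> CPTSet:
    # P(A=1)=0.3, P(B=1|A=1)=0.9, P(B=1|A=0)=0.2
    return CPTSet(net, {"A": np.array([0.7, 0.3]), "B": np.array([[0.8, 0.2], [0.1, 0.9]])})


class TestLikelihoodLabel:
    def test_zero_observations_score_zero(self, zone_map):
        row = {f"observed_{z}": 0 for z in zone_map.zone_ids()}
        assert derive_likelihood_label(row, zone_map) == 0.0

    def test_single_zone_unit_weights(self, zone_map):
        row = {"observed_Z1": 10}  # weight 1, proximity 1
        assert derive_likelihood_label(row, zone_map) == pytest.approx(10.0)

    def test_moving_birds_closer_increases_score(self, zone_map):
        far = {"observed_Z3": 10}  # proximity 2
        near = {"observed_Z1": 10}  # proximity 1
        assert derive_likelihood_label(near, zone_map) > derive_likelihood_label(far, zone_map)

    def test_single_zone_mode(self, zone_map):
        spec = LikelihoodLabelSpec(mode="single", zone="Z3")
        row = {"observed_Z1": 100, "observed_Z3": 4}
        # only Z3 counts: weight 0.5 * 4 / proximity 2
        assert derive_likelihood_label(row, zone_map, spec) == pytest.approx(1.0)


class TestDiscretise:
    def test_tertiles_match_sorting_oracle(self):
        values = np.arange(1, 10)  # 1..9
        states = discretise_node(values, NodeSpec("x"))
        assert np.bincount(states).tolist() == [3, 3, 3]
        # oracle: sorted thirds
        order = np.argsort(values)
        assert all(states[order[:3]] == 0) and all(states[order[-3:]] == 2)

    def test_fixed_cutpoints_and_tie_to_lower(self):
        spec = NodeSpec("x", discretisation="fixed", cutpoints=(10.0, 20.0))
        assert discretise_node([15.0], spec)[0] == 1
        assert discretise_node([10.0], spec)[0] == 0  # boundary goes down
        assert discretise_node([25.0], spec)[0] == 2

    def test_constant_values_single_state_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            states = discretise_node([5.0] * 8, NodeSpec("x"))
        assert set(states) == {0}


class TestStructure:
    def test_cycle_rejected_with_listing(self):
        nodes = [NodeSpec(n, ("s0", "s1")) for n in "ABC"]
        with pytest.raises(ValueError, match="cycle"):
            build_network(NetworkStructure(nodes, [("A", "B"), ("B", "C"), ("C", "A")]))

    def test_dangling_edge_rejected(self):
        with pytest.raises(ValueError, match="dangling"):
            build_network(NetworkStructure([NodeSpec("A", ("s0", "s1"))], [("A", "B")]))

    def test_empty_node_list_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            build_network(NetworkStructure([], []))

    def test_default_migrant_config_links_season_to_behaviour(self):
        structure = default_structure("Cattle Egret")
        net = build_network(structure)
        assert ("Season", "Seasonal Behaviour") in structure.edges
        assert net.order.index("Season") < net.order.index("Seasonal Behaviour")

    def test_all_default_structures_are_valid_dags(self):
        for sp in ("Cattle Egret", "Nankeen Kestrel", "Straw-necked Ibis"):
            net = build_network(default_structure(sp))
            assert "Likelihood" in net.order


class TestLearning:
    def test_complete_data_matches_counting_oracle(self):
        net = two_node_net()
        # hand-tallied: A: 6 zeros, 4 ones; B|A=0: 3/6 ones; B|A=1: 1/4 ones
        cases = pd.DataFrame(
            {"A": [0] * 6 + [1] * 4, "B": [1, 1, 1, 0, 0, 0, 1, 0, 0, 0]}
        )
        cpts = learn_cpts(net, cases, alpha=0.0)
        np.testing.assert_allclose(cpts.tables["A"], [0.6, 0.4])
        np.testing.assert_allclose(cpts.tables["B"], [[0.5, 0.5], [0.75, 0.25]])

    def test_zero_cases_alpha_one_gives_uniform(self):
        net = two_node_net()
        cpts = learn_cpts(net, pd.DataFrame(columns=["A", "B"]), alpha=1.0)
        np.testing.assert_allclose(cpts.tables["A"], [0.5, 0.5])
        np.testing.assert_allclose(cpts.tables["B"], [[0.5, 0.5], [0.5, 0.5]])

    def test_zero_cases_alpha_zero_rejected(self):
        net = two_node_net()
        with pytest.raises(ValueError):
            learn_cpts(net, pd.DataFrame(columns=["A", "B"]), alpha=0.0)

    def test_cpt_rows_sum_to_one_for_any_data(self):
        rng = substream(4, "rows")
        net = build_network(
            NetworkStructure(
                [NodeSpec("A"), NodeSpec("B"), NodeSpec("C")],
                [("A", "C"), ("B", "C")],
            )
        )
        cases = pd.DataFrame(rng.integers(0, 3, size=(40, 3)), columns=["A", "B", "C"])
        cpts = learn_cpts(net, cases, alpha=0.5)
        for t in cpts.tables.values():
            np.testing.assert_allclose(t.reshape(-1, t.shape[-1]).sum(axis=1), 1.0, atol=1e-9)

    def test_em_loglik_nondecreasing_with_masked_data(self):
        rng = substream(9, "em")
        net = two_node_net()
        a = rng.random(60) < 0.3
        b = np.where(a, rng.random(60) < 0.9, rng.random(60) < 0.2)
        cases = pd.DataFrame({"A": a.astype(float), "B": b.astype(float)})
        mask = rng.random(cases.shape) < 0.3
        cases = cases.mask(mask)
        cpts = learn_cpts(net, cases, alpha=0.0, max_em_iters=25)
        trace = cpts.em_loglik
        assert len(trace) >= 2
        assert all(t2 >= t1 - 1e-9 for t1, t2 in zip(trace, trace[1:]))

    def test_cpt_recovery_from_simulated_data(self):
        """Sampling a known 3-node network and re-learning recovers the CPTs."""
        rng = substream(21, "recover")
        net = build_network(
            NetworkStructure(
                [NodeSpec("A", ("0", "1")), NodeSpec("B", ("0", "1", "2")), NodeSpec("C", ("0", "1"))],
                [("A", "B"), ("B", "C")],
            )
        )
        truth = CPTSet(
            net,
            {
                "A": np.array([0.6, 0.4]),
                "B": np.array([[0.5, 0.3, 0.2], [0.1, 0.2, 0.7]]),
                "C": np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]),
            },
        )
        n = 5000
        a = (rng.random(n) < 0.4).astype(int)
        b = np.array([rng.choice(3, p=truth.tables["B"][ai]) for ai in a])
        c = np.array([rng.choice(2, p=truth.tables["C"][bi]) for bi in b])
        learned = learn_cpts(net, pd.DataFrame({"A": a, "B": b, "C": c}), alpha=1.0)
        errs = np.concatenate(
            [np.abs(learned.tables[k] - truth.tables[k]).ravel() for k in ("A", "B", "C")]
        )
        assert np.median(errs) < 0.03


class TestInference:
    def test_prior_marginal_sums_to_one(self):
        net = two_node_net()
        post = infer(net, worked_cpts(net), {}, "B")
        assert post.sum() == pytest.approx(1.0)
        # chain-product oracle: P(B=1) = 0.7*0.2 + 0.3*0.9
        assert post[1] == pytest.approx(0.41, abs=1e-12)

    def test_bayes_rule_hand_posterior(self):
        net = two_node_net()
        post = infer(net, worked_cpts(net), {"B": 1}, "A")
        assert post[1] == pytest.approx(0.27 / 0.41, abs=1e-9)

    def test_evidence_on_query_is_point_mass(self):
        net = two_node_net()
        post = infer(net, worked_cpts(net), {"A": "a0"}, "A")
        np.testing.assert_allclose(post, [1.0, 0.0])

    def test_contradictory_evidence_raises_not_nan(self):
        net = two_node_net()
        cpts = CPTSet(net, {"A": np.array([1.0, 0.0]), "B": np.array([[1.0, 0.0], [0.0, 1.0]])})
        with pytest.raises(ValueError, match="zero probability"):
            infer(net, cpts, {"A": 1}, "B")

    def test_joint_matches_chain_product_oracle(self):
        net = two_node_net()
        joint = worked_cpts(net).joint()
        expected = np.array([[0.7 * 0.8, 0.7 * 0.2], [0.3 * 0.1, 0.3 * 0.9]])
        np.testing.assert_allclose(joint, expected, atol=1e-12)


class TestCrossvalidate:
    def _cases(self, n=60, seed=1, deterministic=True):
        rng = substream(seed, "cv")
        parent = rng.integers(0, 3, n)
        if deterministic:
            label = parent.copy()
        else:
            label = rng.integers(0, 3, n)
        return pd.DataFrame({"Season": parent, "Likelihood": label})

    def _net(self):
        return build_network(
            NetworkStructure(
                [NodeSpec("Season"), NodeSpec("Likelihood")], [("Season", "Likelihood")]
            )
        )

    def test_deterministic_copy_gets_perfect_accuracy(self):
        res = crossvalidate(self._net(), self._cases(), K=2, seed=0, alpha=0.1)
        assert res["mean_accuracy"] == pytest.approx(1.0)

    def test_independent_labels_score_majority_rate(self):
        rng = substream(3, "indep")
        n = 1200
        cases = pd.DataFrame(
            {"Season": rng.integers(0, 3, n), "Likelihood": rng.integers(0, 3, n)}
        )
        res = crossvalidate(self._net(), cases, K=2, seed=0)
        marginal = cases["Likelihood"].value_counts(normalize=True).max()
        assert abs(res["mean_accuracy"] - marginal) < 0.06

    def test_invariant_to_case_order(self):
        cases = self._cases(n=80, seed=5, deterministic=False)
        res1 = crossvalidate(self._net(), cases, K=2, seed=7)
        shuffled = cases.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = crossvalidate(self._net(), shuffled, K=2, seed=7)
        assert res1["mean_accuracy"] == pytest.approx(res2["mean_accuracy"])

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(self._net(), self._cases(), K=1)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == pytest.approx(1.0)

    def test_interleaved_scores_three_of_four_pairs(self):
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.6], [True, False, True, False])
        assert auc == pytest.approx(0.75)

    def test_inverted_scores_auc_zero(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [True, True, False, False])
        assert auc == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [True, True])

    def test_auc_equals_pairwise_concordance_oracle(self):
        rng = substream(13, "auc")
        for _ in range(10):
            scores = rng.random(25)
            labels = rng.random(25) < 0.4
            if labels.all() or (~labels).all():
                continue
            _, auc = roc_auc(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestInfluence:
    def test_identical_rows_zero_influence(self):
        net = two_node_net()
        cpts = CPTSet(net, {"A": np.array([0.5, 0.5]), "B": np.array([[0.3, 0.7], [0.3, 0.7]])})
        assert influence_strength(net, cpts, ("A", "B")) == 0.0

    def test_deterministic_child_full_influence(self):
        net = two_node_net()
        cpts = CPTSet(net, {"A": np.array([0.5, 0.5]), "B": np.array([[1.0, 0.0], [0.0, 1.0]])})
        assert influence_strength(net, cpts, ("A", "B")) == pytest.approx(1.0)

    def test_hand_computed_tv_distance(self):
        net = two_node_net()
        cpts = CPTSet(net, {"A": np.array([0.5, 0.5]), "B": np.array([[0.9, 0.1], [0.6, 0.4]])})
        assert influence_strength(net, cpts, ("A", "B")) == pytest.approx(0.3, abs=1e-12)

    def test_maximised_over_other_parent_states(self):
        net = build_network(
            NetworkStructure(
                [NodeSpec("A", ("0", "1")), NodeSpec("B", ("0", "1")), NodeSpec("C", ("0", "1"))],
                [("A", "C"), ("B", "C")],
            )
        )
        tbl = np.array(
            [
                [[0.5, 0.5], [0.5, 0.5]],  # A=0: B has no effect
                [[0.9, 0.1], [0.1, 0.9]],  # A=1: B flips C
            ]
        )
        cpts = CPTSet(net, {"A": np.array([0.5, 0.5]), "B": np.array([0.5, 0.5]), "C": tbl})
        assert influence_strength(net, cpts, ("B", "C")) == pytest.approx(0.8)
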