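import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kallima import ctmc, synthdata
from kallima.treeio import POLYMORPHIC, CharacterMatrix, parse_newick
from conftest import matrix_from_tips, random_tipdata

rates8 = st.lists(
    st.floats(min_value=0.0, max_value=10.0, allow_nan=False), min_size=8, max_size=8
)


class TestGenerators:
    def test_all_zero_rates(self):
        Q = ctmc.build_dependent_Q(*[0.0] * 8)
        assert np.all(Q.Q == 0)

    def test_all_one_rates(self):
        Q = ctmc.build_dependent_Q(*[1.0] * 8).Q
        assert np.allclose(Q.sum(axis=1), 0)
        for i, j in ((0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)):
            assert Q[i, j] == 1.0

    @given(rates8)
    @settings(max_examples=50, deadline=None)
    def test_row_sums_and_forbidden_entries(self, rates):
        Q = ctmc.build_dependent_Q(*rates).Q
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-12 * max(1.0, np.max(np.abs(Q)))
        for i, j in ((0, 3), (3, 0), (1, 2), (2, 1)):
            assert Q[i, j] == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="q21"):
            ctmc.build_dependent_Q(1, 1, -0.5, 1, 1, 1, 1, 1)

    def test_independent_equalities(self):
        Q = ctmc.build_independent_Q(0.7, 0.2, 1.3, 0.4).Q
        assert Q[0, 1] == Q[2, 3]  # q12 = q34
        assert Q[0, 2] == Q[1, 3]  # q13 = q24
        assert Q[1, 0] == Q[3, 2]  # q21 = q43
        assert Q[2, 0] == Q[3, 1]  # q31 = q42
        assert len({Q[0, 1], Q[0, 2], Q[1, 0], Q[2, 0]}) == 4

    def test_independent_equals_tied_dependent(self):
        g1, l1, g2, l2 = 0.7, 0.2, 1.3, 0.4
        A = ctmc.build_independent_Q(g1, l1, g2, l2).Q
        B = ctmc.build_dependent_Q(
            q12=g2, q13=g1, q21=l2, q24=g1, q31=l1, q34=g2, q42=l1, q43=l2
        ).Q
        assert np.array_equal(A, B)

    def test_equal_rates_symmetric(self):
        Q = ctmc.build_independent_Q(0.5, 0.5, 0.5, 0.5).Q
        assert np.allclose(Q, Q.T)


class TestTransitionProbabilities:
    def test_t_zero_identity(self):
        Q = ctmc.build_dependent_Q(*np.arange(1, 9) / 4.0)
        assert np.allclose(ctmc.transition_probabilities(Q, 0.0), np.eye(4))

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            ctmc.transition_probabilities(ctmc.build_binary_Q(1, 1), -0.1)

    @pytest.mark.parametrize("a,b,t", [(0.8, 0.3, 0.5), (2.0, 0.1, 1.7), (0.0, 1.0, 2.0)])
    def test_two_state_closed_form(self, a, b, t):
        # P(0->0)(t) = (b + a e^{-(a+b)t}) / (a+b)
        P = ctmc.transition_probabilities(ctmc.build_binary_Q(a, b), t)
        s = a + b
        assert P[0, 0] == pytest.approx((b + a * np.exp(-s * t)) / s, abs=1e-10)
        assert P[1, 1] == pytest.approx((a + b * np.exp(-s * t)) / s, abs=1e-10)

    def test_symmetric_long_time_stationary(self):
        P = ctmc.transition_probabilities(ctmc.build_binary_Q(1.0, 1.0), 50.0)
        assert np.allclose(P, 0.5, atol=1e-10)

    def test_matches_expm(self, rng):
        import scipy.linalg

        for _ in range(20):
            Q = ctmc.build_dependent_Q(*rng.uniform(0, 3, 8)).Q
            t = float(rng.uniform(0, 2))
            assert np.allclose(
                ctmc.transition_probabilities(Q, t), scipy.linalg.expm(Q * t), atol=1e-10
            )

    def test_chapman_kolmogorov(self, rng):
        for _ in range(10):
            Q = ctmc.build_dependent_Q(*rng.uniform(0, 2, 8)).Q
            t1, t2 = rng.uniform(0.1, 1.0, 2)
            lhs = ctmc.transition_probabilities(Q, t1 + t2)
            rhs = ctmc.transition_probabilities(Q, t1) @ ctmc.transition_probabilities(Q, t2)
            assert np.allclose(lhs, rhs, atol=1e-9)


class TestTipData:
    def test_pair_tipdata_examples(self):
        codes = np.array(
            [[0, 1], [POLYMORPHIC, 0], [POLYMORPHIC, POLYMORPHIC]], dtype=np.int8
        )
        m = CharacterMatrix(["A", "B", "C"], ["c1", "c2"], codes)
        tips = ctmc.pair_tipdata(m, "c1", "c2")
        assert np.array_equal(tips["A"], [0, 1, 0, 0])
        assert np.array_equal(tips["B"], [1, 0, 1, 0])
        assert np.array_equal(tips["C"], [1, 1, 1, 1])

    def test_unknown_character(self):
        m = CharacterMatrix(["A"], ["c1"], np.array([[0]], dtype=np.int8))
        with pytest.raises(KeyError):
            ctmc.pair_tipdata(m, "c1", "nope")


class TestPruneLoglik:
    def test_single_leaf_uniform_root(self):
        tree = parse_newick("(A:0.0);")
        tips = ctmc.TipData({"A": [0, 1]}, 2)
        got = ctmc.prune_loglik(tree, tips, ctmc.build_binary_Q(1.0, 0.5))
        assert got == pytest.approx(np.log(0.5), abs=1e-12)

    def test_zero_rates_give_log_root_prob(self, five_leaf_tree):
        tips = ctmc.TipData({n: [0, 1] for n in five_leaf_tree.taxon_set}, 2)
        root = np.array([0.3, 0.7])
        got = ctmc.prune_loglik(five_leaf_tree, tips, ctmc.build_binary_Q(0, 0), root=root)
        assert got == pytest.approx(np.log(0.7), abs=1e-12)

    @pytest.mark.parametrize("n_states", [2, 4])
    def test_matches_brute_force_on_random_instances(self, n_states, rng):
        # 50 random 4-6 leaf instances per state count
        for i in range(50):
            n = int(rng.integers(4, 7))
            tree = synthdata.simulate_yule_tree(n, 1.0, rng=rng)
            tips = random_tipdata(tree, n_states, rng)
            if n_states == 2:
                Q = ctmc.build_binary_Q(*rng.uniform(0.05, 2.0, 2)).Q
            else:
                Q = ctmc.build_dependent_Q(*rng.uniform(0.05, 2.0, 8)).Q
            a = ctmc.prune_loglik(tree, tips, Q)
            b = ctmc.brute_force_loglik(tree, tips, Q)
            assert a == pytest.approx(b, abs=1e-9)

    def test_zero_length_internal_edge_no_effect(self):
        t1 = parse_newick("((A:1,B:1):0.5,C:2);")
        t2 = parse_newick("(((A:1,B:1):0.0):0.5,C:2);")
        tips = ctmc.TipData({"A": [0, 1], "B": [1, 0], "C": [0, 1]}, 2)
        Q = ctmc.build_binary_Q(0.8, 0.4)
        assert ctmc.brute_force_loglik(t1, tips, Q) == pytest.approx(
            ctmc.brute_force_loglik(t2, tips, Q), abs=1e-12
        )

    def test_relabeling_invariance(self, five_leaf_tree, rng):
        Q = ctmc.build_binary_Q(0.6, 0.9).Q
        tips = random_tipdata(five_leaf_tree, 2, rng)
        base = ctmc.prune_loglik(five_leaf_tree, tips, Q)
        relabeled = five_leaf_tree.copy()
        mapping = {name: f"X_{name}" for name in five_leaf_tree.taxon_set}
        relabeled.labels = {n: mapping[l] for n, l in relabeled.labels.items()}
        tips2 = ctmc.TipData({mapping[k]: v for k, v in tips.partials.items()}, 2)
        assert ctmc.prune_loglik(relabeled, tips2, Q) == pytest.approx(base, abs=1e-12)

    def test_independence_factorization(self, rng):
        # joint 4-state independent likelihood = sum of the two 2-state ones
        tree = synthdata.simulate_yule_tree(47, 1.0, seed=99)
        taxa = sorted(tree.taxon_set)
        g1, l1, g2, l2 = 0.7, 0.3, 1.1, 0.5
        t1 = synthdata.simulate_character(tree, ctmc.build_binary_Q(g1, l1).Q, 0, seed=1)
        t2 = synthdata.simulate_character(tree, ctmc.build_binary_Q(g2, l2).Q, 0, seed=2)
        m = matrix_from_tips(tree, [t1, t2], ["c1", "c2"])
        joint = ctmc.prune_loglik(
            tree, ctmc.pair_tipdata(m, "c1", "c2"), ctmc.build_independent_Q(g1, l1, g2, l2)
        )
        s1 = ctmc.prune_loglik(tree, ctmc.binary_tipdata(m, "c1"), ctmc.build_binary_Q(g1, l1))
        s2 = ctmc.prune_loglik(tree, ctmc.binary_tipdata(m, "c2"), ctmc.build_binary_Q(g2, l2))
        assert joint == pytest.approx(s1 + s2, abs=1e-9)


class TestNodeStateProbs:
    def test_leaf_with_unambiguous_state_is_indicator(self, five_leaf_tree):
        tips = ctmc.TipData(
            {n: ([1, 0] if n != "A" else [0, 1]) for n in five_leaf_tree.taxon_set}, 2
        )
        Q = ctmc.build_binary_Q(0.5, 0.5).Q
        leaf_a = five_leaf_tree.label_to_node["A"]
        probs = ctmc.node_state_probs(five_leaf_tree, tips, Q, node=leaf_a)
        assert probs == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_symmetric_data_symmetric_probs(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = ctmc.TipData({"A": [1, 0], "B": [0, 1], "C": [1, 0], "D": [0, 1]}, 2)
        probs = ctmc.node_state_probs(tree, tips, ctmc.build_binary_Q(1, 1).Q, node=tree.root)
        assert probs == pytest.approx([0.5, 0.5], abs=1e-10)

    def test_rows_sum_to_one(self, five_leaf_tree, rng):
        tips = random_tipdata(five_leaf_tree, 4, rng)
        Q = ctmc.build_dependent_Q(*rng.uniform(0.1, 2, 8)).Q
        M = ctmc.node_state_probs(five_leaf_tree, tips, Q)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-10)

    def test_matches_clamped_brute_force(self, rng):
        # marginal at an internal node == Bayes rule over clamped likelihoods
        tree = parse_newick("((A:0.4,B:0.9):0.6,(C:0.3,D:1.1):0.2);")
        tips = ctmc.TipData({"A": [0, 1], "B": [1, 0], "C": [0, 1], "D": [0, 1]}, 2)
        Q = ctmc.build_binary_Q(0.9, 0.4).Q
        internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
        for node in internal:
            joint = np.array(
                [
                    np.exp(ctmc.brute_force_loglik(tree, tips, Q, clamp={node: s}))
                    for s in (0, 1)
                ]
            )
            expected = joint / joint.sum()
            got = ctmc.node_state_probs(tree, tips, Q, node=node)
            assert got == pytest.approx(expected, abs=1e-12)
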