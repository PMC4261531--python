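import numpy as np
import pytest

from kallima import ctmc
from kallima.synthdata import (
    PLANTED_CHAIN,
    SimulationScenario,
    first_gain_times,
    make_fixture_study,
    perturb_tree_sample,
    simulate_character,
    simulate_contingent_chain,
    simulate_pair,
    simulate_yule_tree,
)


class TestYule:
    def test_two_taxa_is_cherry(self):
        t = simulate_yule_tree(2, 1.0, seed=0)
        assert t.n_leaves == 2
        assert len(t.children[t.root]) == 2

    def test_seed_reproducibility(self):
        a = simulate_yule_tree(10, 1.0, seed=5)
        b = simulate_yule_tree(10, 1.0, seed=5)
        assert np.array_equal(a.blen, b.blen) and np.array_equal(a.parent, b.parent)

    def test_ultrametric(self):
        t = simulate_yule_tree(20, 2.0, seed=1)
        depths = t.depths()[t.leaf_nodes]
        assert np.allclose(depths, depths[0], atol=1e-10)

    def test_expected_depth_matches_theory(self):
        # E[depth] = sum_{k=2..n} 1/(k * lambda)
        n, lam = 8, 1.5
        rng = np.random.default_rng(42)
        got = np.mean([
            simulate_yule_tree(n, lam, rng=rng).depths().max() for _ in range(500)
        ])
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        assert got == pytest.approx(expected, rel=0.1)  # Monte-Carlo tolerance

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, 0.0, seed=0)


class TestPerturb:
    def test_zero_jitter_identical_lengths(self):
        t = simulate_yule_tree(10, 1.0, seed=0)
        sample = perturb_tree_sample(t, 5, 0.0, seed=1)
        for s in sample:
            assert np.allclose(s.blen, t.blen)

    def test_taxon_set_preserved_with_nni(self):
        t = simulate_yule_tree(12, 1.0, seed=2)
        sample = perturb_tree_sample(t, 20, 0.3, seed=3, nni_fraction=0.5)
        for s in sample:
            assert s.taxon_set == t.taxon_set

    def test_mean_branch_length_preserved(self):
        t = simulate_yule_tree(30, 1.0, seed=4)
        sample = perturb_tree_sample(t, 100, 0.2, seed=5)
        means = [s.blen[s.parent >= 0].mean() for s in sample]
        assert np.mean(means) == pytest.approx(t.blen[t.parent >= 0].mean(), rel=0.05)


class TestSimulateCharacter:
    def test_zero_rates_keep_root_state(self):
        t = simulate_yule_tree(10, 1.0, seed=0)
        tips = simulate_character(t, np.zeros((2, 2)), root_state=1, seed=1)
        assert all(v == 1 for v in tips.values())

    def test_seed_reproducibility(self):
        t = simulate_yule_tree(10, 1.0, seed=0)
        Q = ctmc.build_binary_Q(0.5, 0.5).Q
        assert simulate_character(t, Q, 0, seed=9) == simulate_character(t, Q, 0, seed=9)

    def test_stationary_fraction_on_long_branch_star(self):
        # star tree with long branches: tips approach the stationary law
        from kallima.treeio import Tree

        n = 400
        parent = np.concatenate([[-1], np.zeros(n, dtype=int)])
        blen = np.concatenate([[0.0], np.full(n, 50.0)])
        labels = {i + 1: f"t{i}" for i in range(n)}
        star = Tree(parent, blen, labels)
        q01, q10 = 0.7, 0.3
        tips = simulate_character(star, ctmc.build_binary_Q(q01, q10).Q, 0, seed=3)
        frac = np.mean(list(tips.values()))
        assert frac == pytest.approx(q01 / (q01 + q10), abs=0.06)


class TestSimulatePair:
    def test_double_change_generator_rejected(self):
        t = simulate_yule_tree(5, 1.0, seed=0)
        Q = np.array([[-1.0, 0, 0, 1.0], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]])
        with pytest.raises(ValueError, match="double"):
            simulate_pair(t, Q, (0, 0), seed=1)

    def test_zero_rates_keep_root(self):
        t = simulate_yule_tree(6, 1.0, seed=0)
        tips = simulate_pair(t, np.zeros((4, 4)), (1, 0), seed=1)
        assert all(v == (1, 0) for v in tips.values())

    def test_independent_generator_near_zero_tip_correlation(self):
        rng = np.random.default_rng(11)
        Q = ctmc.build_independent_Q(0.8, 0.8, 0.8, 0.8).Q
        cors = []
        for _ in range(100):
            t = simulate_yule_tree(40, 1.0, rng=rng)
            tips = simulate_pair(t, Q, (0, 0), rng=rng)
            arr = np.array(list(tips.values()), dtype=float)
            if arr[:, 0].std() > 0 and arr[:, 1].std() > 0:
                cors.append(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        assert abs(np.mean(cors)) < 0.08

    def test_structural_zero_event_log_consistency(self):
        # with q12 = 0 and root (0,0), no lineage may show a char2 gain before
        # its own char1 gain; verified against the recorded event history
        Q = ctmc.build_dependent_Q(
            q12=0.0, q13=0.8, q21=0.5, q24=0.8, q31=0.2, q34=2.0, q42=0.2, q43=0.3
        ).Q
        t = simulate_yule_tree(60, 1.0, seed=21)
        tips, states, events = simulate_pair(t, Q, (0, 0), seed=22, return_events=True)
        # replay every branch: state (0,0) must never jump directly to (0,1)
        for node, evs in events.items():
            prev = int(states[t.parent[node]]) if t.parent[node] >= 0 else 0
            for _, new in evs:
                assert not (prev == 0 and new == 1)  # (0,0) -> (0,1) forbidden
                prev = new


class TestContingentChain:
    def test_gain_order_respected_in_every_lineage(self):
        t = simulate_yule_tree(50, 1.0, seed=30)
        _, histories = simulate_contingent_chain(t, PLANTED_CHAIN, seed=31)
        gains = first_gain_times(t, histories)
        for taxon, times in gains.items():
            for earlier, later in zip(times, times[1:]):
                if np.isfinite(later):
                    assert earlier < later  # a successor never gains first


class TestFixtureStudy:
    def test_default_dimensions_47_by_11(self):
        trees, matrix, truth = make_fixture_study(
            "null", seed=1,
            scenario=SimulationScenario(n_taxa=47, n_chars=11, n_trees=3, seed=1),
        )
        assert matrix.n_taxa == 47 and matrix.n_characters == 11
        assert len(trees) == 3
        assert trees.taxon_set == set(matrix.taxa)

    def test_null_preset_plants_nothing(self):
        _, _, truth = make_fixture_study(
            "null", seed=2,
            scenario=SimulationScenario(n_taxa=10, n_chars=3, n_trees=2, seed=2),
        )
        assert truth["dependent_pairs"] == [] and truth["order_chain"] == []

    def test_planted_pairs_recorded(self):
        _, _, truth = make_fixture_study(
            "planted-pairs", seed=3,
            scenario=SimulationScenario(n_taxa=12, n_chars=5, n_trees=2, seed=3),
        )
        assert truth["dependent_pairs"] == [("Ch1", "Ch2"), ("Ch3", "Ch4")]

    def test_planted_order_audit(self):
        _, _, truth = make_fixture_study(
            "planted-order", seed=4,
            scenario=SimulationScenario(n_taxa=20, n_chars=4, n_trees=2, seed=4),
        )
        assert truth["order_chain"] == ["Ch1", "Ch2", "Ch3"]
        for times in truth["first_gain_times"].values():
            finite = [t for t in times if t is not None]
            assert finite == sorted(finite)

    def test_determinism(self):
        sc = SimulationScenario(n_taxa=10, n_chars=3, n_trees=2, seed=5)
        _, m1, _ = make_fixture_study("planted-pairs", seed=5, scenario=sc)
        _, m2, _ = make_fixture_study("planted-pairs", seed=5, scenario=sc)
        assert m1 == m2

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_fixture_study("nope", seed=0)


def test_generating_model_beats_misspecified_one():
    # simulated data should prefer its own generator over a wrong one
    rng = np.random.default_rng(99)
    wins = 0
    n = 60
    for _ in range(n):
        t = simulate_yule_tree(100, 1.0, rng=rng)
        Q_true = ctmc.build_binary_Q(1.0, 0.2).Q
        Q_wrong = ctmc.build_binary_Q(0.2, 1.0).Q
        tips = simulate_character(t, Q_true, 0, rng=rng)
        taxa = sorted(t.taxon_set)
        from kallima.treeio import CharacterMatrix

        m = CharacterMatrix(taxa, ["c"], np.array([[tips[x]] for x in taxa], dtype=np.int8))
        td = ctmc.binary_tipdata(m, "c")
        wins += ctmc.prune_loglik(t, td, Q_true) > ctmc.prune_loglik(t, td, Q_wrong)
    assert wins >= 0.95 * n
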