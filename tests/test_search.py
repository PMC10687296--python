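"""Taguchi robust-design loop: candidate generation, refinement, convergence."""

import numpy as np
import pytest

from annl36.design import OrthogonalArray
from annl36.encode import CodingConfig
from annl36.network import build_network
from annl36.search import (
    LevelTable,
    SearchConfig,
    candidates_from_array,
    evaluate_candidates,
    refine_levels,
    run_search,
)


def uniform_levels() -> LevelTable:
    """Level table with the symmetric grid for every factor (bias included)."""
    return LevelTable.initial(bias_center=0.0)


class TestLevelTable:
    def test_initial_shape(self):
        t = LevelTable.initial()
        assert len(t.levels) == 23
        assert all(len(v) == 2 for v in t.levels[:11])
        assert all(len(v) == 3 for v in t.levels[11:])

    def test_bias_centered_at_coded_target_midpoint(self):
        t = LevelTable.initial(bias_center=0.5)
        assert list(t.levels[22]) == [-0.5, 0.5, 1.5]

    def test_rejects_descending_levels(self):
        t = LevelTable.initial()
        bad = [v.copy() for v in t.levels]
        bad[3] = np.array([1.0, -1.0])
        with pytest.raises(ValueError):
            LevelTable(levels=bad, spacing=t.spacing)


class TestCandidates:
    def test_row_ann1_all_first_levels(self, l36):
        cands = candidates_from_array(l36, uniform_levels())
        assert np.all(cands[0] == -1.0)

    def test_row_ann3_two_level_low_three_level_high(self, l36):
        cands = candidates_from_array(l36, uniform_levels())
        assert np.all(cands[2][:11] == -1.0) and np.all(cands[2][11:] == 1.0)

    def test_exactly_36_candidates(self, l36):
        assert candidates_from_array(l36, uniform_levels()).shape == (36, 23)

    def test_level_index_overflow_detected(self, l36):
        cells = l36.cells.copy()
        cells[0, 0] = 3  # three in a two-level column
        bad = OrthogonalArray(columns=l36.columns, cells=cells)
        with pytest.raises(ValueError):
            candidates_from_array(bad, uniform_levels())


class TestEvaluate:
    def test_exact_predictor_scores_zero(self, rng):
        X = rng.random((15, 10))
        coder = CodingConfig(kind="minmax", support=(0.0, 20.0))
        w = np.zeros(23)
        w[22] = 0.5  # constant coded output -> decodes to 10.0
        targets = np.full(15, 10.0)
        vals = evaluate_candidates(w[None, :], X, targets, coder)
        assert vals[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_candidate_against_ten_percent_targets(self, rng):
        # output 0 decodes to 0 -> every relative error is 100%
        X = rng.random((8, 10))
        coder = CodingConfig(kind="minmax", support=(0.0, 20.0))
        vals = evaluate_candidates(np.zeros((1, 23)), X, np.full(8, 10.0), coder)
        assert vals[0] == pytest.approx(100.0)

    def test_permutation_equivariant(self, l36, rng):
        X = rng.random((10, 10))
        coder = CodingConfig(kind="minmax", support=(0.0, 20.0))
        targets = rng.uniform(5, 15, size=10)
        cands = candidates_from_array(l36, uniform_levels())
        vals = evaluate_candidates(cands, X, targets, coder)
        perm = rng.permutation(36)
        assert np.array_equal(evaluate_candidates(cands[perm], X, targets, coder), vals[perm])

    def test_non_positive_targets_rejected(self, rng):
        coder = CodingConfig(kind="minmax", support=(0.0, 20.0))
        with pytest.raises(ValueError):
            run_search(rng.random((4, 10)), np.array([1.0, 0.0, 2.0, 3.0]), coder)


class TestRefine:
    def test_three_level_contraction_example(self):
        t = uniform_levels()
        winner = np.zeros(23)
        new = refine_levels(t, winner, SearchConfig(contraction=0.5))
        # three-level spacing 1.0 -> 0.5; winner value retained as center
        assert list(new.levels[11]) == [-0.5, 0.0, 0.5]

    def test_two_level_contraction_example(self):
        t = uniform_levels()
        winner = np.zeros(23)
        winner[0] = 1.0
        new = refine_levels(t, winner, SearchConfig(contraction=0.5))
        # two-level gap 2.0 -> 1.0, straddling the winner
        assert list(new.levels[0]) == [0.5, 1.5]

    def test_spacing_contracts_geometrically(self):
        t = uniform_levels()
        cfg = SearchConfig(contraction=0.5)
        for k in range(1, 5):
            t = refine_levels(t, np.zeros(23), cfg)
            assert t.spacing[11] == pytest.approx(0.5**k)
            assert t.spacing[0] == pytest.approx(2 * 0.5**k)
            assert t.iteration == k


class TestRunSearch:
    def test_first_iteration_winner_is_brute_force_argmin(self, l36, design_2013):
        """Taguchi selection and exhaustive evaluation of the 36 candidates
        must coincide — guards the plumbing between array and evaluator."""
        X, targets, _, target_coder = design_2013
        net, trace = run_search(X, targets, target_coder)
        cands = candidates_from_array(
            l36, LevelTable.initial(bias_center=0.5)
        )
        brute = evaluate_candidates(cands, X, targets, target_coder)
        assert trace.records[0].winner == f"ANN{int(np.argmin(brute)) + 1}"
        assert trace.records[0].winner_objective == pytest.approx(brute.min())

    def test_best_sequence_monotone_non_increasing(self, design_2013):
        X, targets, _, target_coder = design_2013
        _, trace = run_search(X, targets, target_coder)
        seq = trace.best_sequence()
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_bit_reproducible(self, design_2013):
        X, targets, _, target_coder = design_2013
        net1, tr1 = run_search(X, targets, target_coder)
        net2, tr2 = run_search(X, targets, target_coder)
        assert np.array_equal(net1.weights, net2.weights)
        assert tr1.best_sequence() == tr2.best_sequence()

    def test_planted_network_recovery(self, design_2013):
        """A target function generated by grid weights is recovered to
        under 0.5% training MMRE."""
        X, _, _, target_coder = design_2013
        rng = np.random.default_rng(7)
        init = LevelTable.initial()
        planted = None
        for _ in range(10):
            w = np.array([lv[rng.integers(len(lv))] for lv in init.levels])
            pct = np.asarray(target_coder.decode(build_network(w).predict(X)))
            if np.all(pct > 0):
                planted = pct
                break
        assert planted is not None
        _, trace = run_search(X, planted, target_coder)
        assert trace.best_sequence()[-1] < 0.5

    def test_constant_target_bias_convergence(self):
        """With featureless inputs the search reduces to locating the coded
        constant with the output bias: under 1% error within 8 iterations."""
        X = np.tile(np.array([0.0, 0.5, 0.25, 0.25, 0.25, 0.25, 0.5, 0.4, 1.0, 1.0]), (12, 1))
        coder = CodingConfig(kind="minmax", support=(0.0, 40.0), band=(0.2, 0.8))
        net, trace = run_search(X, np.full(12, 12.0), coder, config=SearchConfig(max_iterations=8))
        assert min(trace.best_sequence()) < 1.0
        assert net.predict(X)[0] == pytest.approx(coder.encode(12.0), abs=0.01)

    def test_constant_target_with_varying_features_still_improves(self, design_2013):
        """With informative features present the greedy contraction cannot
        null them exactly, but the error must still fall far below the
        initial candidates'."""
        X, _, _, _ = design_2013
        coder = CodingConfig(kind="minmax", support=(0.0, 40.0), band=(0.2, 0.8))
        _, trace = run_search(X, np.full(len(X), 12.0), coder)
        seq = trace.best_sequence()
        assert seq[-1] < 0.3 * seq[0]

    def test_non_convergence_flagged_not_raised(self, design_2013):
        X, targets, _, target_coder = design_2013
        net, trace = run_search(
            X, targets, target_coder, config=SearchConfig(max_iterations=2)
        )
        assert trace.n_iterations == 2
        assert not trace.converged
        assert net.weights.shape == (23,)

    def test_trace_frame_shape(self, design_2013):
        X, targets, _, target_coder = design_2013
        _, trace = run_search(X, targets, target_coder)
        df = trace.to_frame()
        assert list(df.columns) == ["iteration", "winner", "winner_objective", "best_objective"]
        assert len(df) == trace.n_iterations
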