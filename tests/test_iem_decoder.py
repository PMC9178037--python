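import numpy as np
import pytest

from shapelearn.iem_decoder import (
    ChannelBasis,
    WeightMatrix,
    channel_vector,
    decoding_evidence,
    evaluate_basis,
    evidence_per_trial,
    fit_weights,
    reconstruct_channels,
    select_most_active,
    select_voxels,
    tuning_curve,
)


def _noiseless_training(w_true, basis, reps=2):
    shapes = np.repeat(np.arange(1, basis.n_channels + 1), reps)
    patterns = np.stack([w_true @ channel_vector(basis, int(s)) for s in shapes])
    return patterns, shapes


class TestBasis:
    def test_unit_response_at_own_center(self, basis):
        for j, c in enumerate(basis.centers):
            vals = evaluate_basis(basis, c)[0]
            assert vals[j] == pytest.approx(1.0)

    def test_zero_beyond_ninety_degrees(self, basis):
        vals = evaluate_basis(basis, basis.centers[0] + 90.0)[0]
        assert vals[0] == 0.0
        assert evaluate_basis(basis, basis.centers[0] + 144.0)[0][0] == 0.0

    def test_even_symmetry(self, basis):
        for d in (10.0, 33.3, 71.0):
            left = evaluate_basis(basis, basis.centers[2] - d)[0][2]
            right = evaluate_basis(basis, basis.centers[2] + d)[0][2]
            assert left == pytest.approx(right)

    def test_nonnegative_everywhere(self, basis):
        assert np.all(evaluate_basis(basis, basis.grid) >= 0)


class TestWeightFitting:
    def test_recovers_true_weights_noiselessly(self, basis, rng):
        w_true = rng.standard_normal((40, 5))
        patterns, shapes = _noiseless_training(w_true, basis)
        w_hat = fit_weights(patterns, shapes, basis)
        np.testing.assert_allclose(w_hat.weights, w_true, atol=1e-8)

    def test_channel_patterns_give_identity(self, basis):
        # five "voxels" responding exactly like the five channels
        c_cols = np.stack([channel_vector(basis, i + 1) for i in range(5)])
        w_hat = fit_weights(c_cols, np.arange(1, 6), basis)
        np.testing.assert_allclose(w_hat.weights, np.eye(5), atol=1e-8)

    def test_voxel_rows_are_independent(self, basis, rng):
        w_true = rng.standard_normal((10, 5))
        patterns, shapes = _noiseless_training(w_true, basis)
        w_small = fit_weights(patterns, shapes, basis)
        extended = np.hstack([patterns, patterns[:, :1]])
        w_big = fit_weights(extended, shapes, basis)
        np.testing.assert_allclose(w_big.weights[:-1], w_small.weights)
        np.testing.assert_allclose(w_big.weights[-1], w_small.weights[0])

    def test_missing_shape_condition_rejected(self, basis, rng):
        patterns = rng.standard_normal((4, 10))
        with pytest.raises(ValueError, match="shape"):
            fit_weights(patterns, np.array([1, 2, 3, 4]), basis)


class TestReconstruction:
    def test_round_trip_exact(self, basis, rng):
        w_true = rng.standard_normal((30, 5))
        patterns, shapes = _noiseless_training(w_true, basis)
        w_hat = fit_weights(patterns, shapes, basis)
        c = channel_vector(basis, 4)
        rec = reconstruct_channels(w_hat, (w_true @ c)[None, :])
        np.testing.assert_allclose(rec[0], c, atol=1e-8)

    def test_zero_patterns_zero_outputs(self, basis, rng):
        w = WeightMatrix(rng.standard_normal((20, 5)))
        rec = reconstruct_channels(w, np.zeros((3, 20)))
        np.testing.assert_array_equal(rec, 0.0)

    def test_linearity(self, basis, rng):
        w = WeightMatrix(rng.standard_normal((20, 5)))
        b1, b2 = rng.standard_normal((2, 4, 20))
        lhs = reconstruct_channels(w, 2.0 * b1 - 3.0 * b2)
        rhs = 2.0 * reconstruct_channels(w, b1) - 3.0 * reconstruct_channels(w, b2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rank_deficiency_mentions_voxel_selection(self, basis):
        w = WeightMatrix(np.ones((20, 5)))
        with pytest.raises(np.linalg.LinAlgError, match="voxel"):
            reconstruct_channels(w, np.ones((2, 20)))


class TestTuningCurveAndEvidence:
    def test_one_hot_output_reproduces_basis(self, basis):
        out = np.zeros(5)
        out[1] = 1.0
        curve = tuning_curve(out, basis)
        np.testing.assert_allclose(
            curve.amplitude, evaluate_basis(basis, basis.grid)[:, 1]
        )

    def test_uniform_outputs_equal_amplitude_at_all_shapes(self, basis):
        curve = tuning_curve(np.ones(5), basis)
        at_shapes = [curve.at(basis.shape_position(i)) for i in range(1, 6)]
        np.testing.assert_allclose(at_shapes, at_shapes[0])

    def test_curve_is_linear_in_outputs(self, basis, rng):
        out = rng.standard_normal(5)
        np.testing.assert_allclose(
            tuning_curve(2.0 * out, basis).amplitude,
            2.0 * tuning_curve(out, basis).amplitude,
        )

    def test_self_curve_positive_evidence(self, basis):
        curve = tuning_curve(channel_vector(basis, 2), basis)
        assert decoding_evidence(curve, 2, 4, basis) > 0

    def test_flat_curve_zero_evidence(self, basis):
        curve = tuning_curve(np.ones(5), basis)
        assert decoding_evidence(curve, 2, 4, basis) == pytest.approx(0.0)

    def test_antisymmetry(self, basis, rng):
        curve = tuning_curve(rng.standard_normal(5), basis)
        assert decoding_evidence(curve, 2, 4, basis) == pytest.approx(
            -decoding_evidence(curve, 4, 2, basis)
        )

    def test_same_shape_rejected(self, basis):
        curve = tuning_curve(np.ones(5), basis)
        with pytest.raises(ValueError):
            decoding_evidence(curve, 2, 2, basis)

    def test_evidence_invariant_to_consistent_voxel_permutation(self, basis, rng):
        w_true = rng.standard_normal((25, 5))
        train, shapes = _noiseless_training(w_true, basis)
        test = rng.standard_normal((8, 25))
        pres = np.array([2, 4] * 4)
        alt = np.where(pres == 2, 4, 2)
        w = fit_weights(train, shapes, basis)
        ev = evidence_per_trial(w, test, pres, alt, basis)
        perm = rng.permutation(25)
        w_p = fit_weights(train[:, perm], shapes, basis)
        ev_p = evidence_per_trial(w_p, test[:, perm], pres, alt, basis)
        np.testing.assert_allclose(ev, ev_p, atol=1e-10)

    def test_pure_noise_evidence_centred_on_zero(self, basis, rng):
        w_true = rng.standard_normal((30, 5))
        train, shapes = _noiseless_training(w_true, basis, reps=4)
        w = fit_weights(train, shapes, basis)
        n_trials = 2000
        noise = rng.standard_normal((n_trials, 30))
        pres = np.resize([2, 4], n_trials)
        alt = np.where(pres == 2, 4, 2)
        ev = evidence_per_trial(w, noise, pres, alt, basis)
        sem = ev.std(ddof=1) / np.sqrt(n_trials)
        assert abs(ev.mean()) < 3 * sem


class TestVoxelSelection:
    def test_informative_voxels_rank_first_noiselessly(self, basis, rng):
        n_info, n_total = 50, 500
        w_true = np.zeros((n_total, 5))
        w_true[:n_info] = rng.standard_normal((n_info, 5))
        run_a, shapes_a = _noiseless_training(w_true, basis, reps=4)
        run_b, shapes_b = _noiseless_training(w_true, basis, reps=4)
        voxels, fraction = select_voxels(run_a, shapes_a, run_b, shapes_b, basis)
        assert fraction <= 0.1 + 1e-9
        assert set(voxels).issubset(set(range(n_info)))

    def test_identical_voxels_tie_break_to_smallest(self, basis):
        patterns = np.tile(np.linspace(1, 5, 20)[:, None], (1, 40))
        shapes = np.resize(np.arange(1, 6), 20)
        _, fraction = select_voxels(patterns, shapes, patterns, shapes, basis)
        assert fraction == pytest.approx(0.1)

    def test_too_few_voxels_rejected(self, basis, rng):
        p = rng.standard_normal((10, 5))
        shapes = np.resize(np.arange(1, 6), 10)
        with pytest.raises(ValueError):
            select_voxels(p, shapes, p, shapes, basis)

    def test_most_active_selection(self, rng):
        act = rng.standard_normal(1000)
        top = select_most_active(act, 500)
        assert len(top) == 500
        assert act[top].min() >= np.sort(act)[-500]


class TestBasisProperties:
    def test_even_symmetry_and_bounds_everywhere(self, basis):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(offset=st.floats(0.0, 180.0, allow_nan=False))
        def run(offset):
            for c in basis.centers:
                left = evaluate_basis(basis, c - offset)[0]
                right = evaluate_basis(basis, c + offset)[0]
                assert np.all(left >= 0) and np.all(left <= 1)
                j = int(np.argmin(np.abs(basis.centers - c)))
                assert left[j] == pytest.approx(right[j], abs=1e-12)

        run()
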