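import numpy as np
import pandas as pd
import pytest

from shapelearn.design import ExperimentDesign
from shapelearn.evidence_timecourse import (
    average_derivative,
    smooth,
    windowed_evidence,
)


def _toy_design(valid_flags, positions, blocks=None):
    n = len(positions)
    blocks = blocks if blocks is not None else [1] * n
    trials = pd.DataFrame(
        {
            "block": blocks,
            "trial_position": positions,
            "valid": valid_flags,
            "predicted_shape": [2] * n,
            "presented_shape": [2 if v else 4 for v in valid_flags],
        }
    )
    return ExperimentDesign(experiment="1", trials=trials,
                            counterbalance_unit=1, seed=0)


class TestWindowing:
    def test_exp1_window_four_gives_29_bins(self, exp1_design):
        ev = np.zeros(len(exp1_design.trials))
        tc = windowed_evidence(ev, exp1_design, 4)
        assert len(tc.bins) == 29
        assert tc.bins[0] == 1 and tc.bins[-1] == 29

    def test_exp2_window_sixteen_gives_113_bins(self, exp2_design):
        tc = windowed_evidence(np.zeros(512), exp2_design, 16)
        assert len(tc.bins) == 113

    def test_constant_evidence(self, exp1_design):
        tc = windowed_evidence(np.full(512, 0.7), exp1_design, 4)
        np.testing.assert_allclose(tc.valid, 0.7)
        np.testing.assert_allclose(tc.invalid, 0.7)
        np.testing.assert_allclose(tc.predicted, 0.0, atol=1e-12)
        np.testing.assert_allclose(tc.presented, 0.7)

    def test_position_valued_evidence_averages_positions(self, exp1_design):
        ev = exp1_design.trials["trial_position"].to_numpy(float)
        tc = windowed_evidence(ev, exp1_design, 4)
        expected = tc.bins + 1.5  # mean of 4 consecutive positions
        np.testing.assert_allclose(tc.valid, expected)
        np.testing.assert_allclose(tc.invalid, expected)

    def test_bin_without_invalid_trials_is_missing_not_zero(self):
        d = _toy_design(
            valid_flags=[True, True, True, False],
            positions=[1, 2, 3, 4],
        )
        tc = windowed_evidence(np.array([1.0, 1.0, 1.0, -1.0]), d, 2)
        assert np.isnan(tc.invalid[0]) and np.isnan(tc.predicted[0])
        assert tc.n_invalid[0] == 0
        assert np.isfinite(tc.invalid[-1])

    def test_bin_count_closed_form(self, exp1_design):
        ev = np.zeros(512)
        for w in (1, 2, 4, 8, 16):
            tc = windowed_evidence(ev, exp1_design, w)
            assert len(tc.bins) == 32 - w + 1

    def test_average_complement_convention_is_affine(self, exp1_design, rng):
        ev = rng.standard_normal(512)
        diff = windowed_evidence(ev, exp1_design, 4, convention="difference")
        avg = windowed_evidence(ev, exp1_design, 4, convention="average_complement")
        np.testing.assert_allclose(avg.predicted, diff.predicted / 2 + 0.5)


class TestSmoothing:
    def _tc(self, values, exp1_design):
        tc = windowed_evidence(np.zeros(512), exp1_design, 4)
        object.__setattr__(tc, "predicted", np.asarray(values, float))
        return tc

    def test_halfwidth_zero_is_identity(self, exp1_design, rng):
        tc = windowed_evidence(rng.standard_normal(512), exp1_design, 4)
        assert smooth(tc, 0) is tc

    def test_impulse_response_is_uniform_kernel(self, exp1_design):
        vals = np.zeros(29)
        vals[14] = 1.0
        tc = self._tc(vals, exp1_design)
        sm = smooth(tc, 4)
        np.testing.assert_allclose(sm.predicted[10:19], 1.0 / 9.0)
        assert sm.predicted[9] == 0.0 and sm.predicted[19] == 0.0

    def test_constant_series_unchanged(self, exp1_design):
        tc = self._tc(np.full(29, 0.3), exp1_design)
        np.testing.assert_allclose(smooth(tc, 4).predicted, 0.3)

    def test_truncated_edges_average_available_bins(self, exp1_design):
        vals = np.arange(29, dtype=float)
        sm = smooth(self._tc(vals, exp1_design), 4)
        assert sm.predicted[0] == pytest.approx(np.mean(vals[:5]))
        assert sm.predicted[-1] == pytest.approx(np.mean(vals[-5:]))
        # interior of a linear series is preserved; global mean shifts only
        # by a bounded edge term
        np.testing.assert_allclose(sm.predicted[4:-4], vals[4:-4])
        assert abs(sm.predicted.mean() - vals.mean()) <= 4 * 8 / 29

    def test_missing_bins_skipped_within_window(self, exp1_design):
        vals = np.full(29, 1.0)
        vals[5] = np.nan
        sm = smooth(self._tc(vals, exp1_design), 2)
        np.testing.assert_allclose(sm.predicted[np.isfinite(sm.predicted)], 1.0)


class TestDerivative:
    def test_telescoping_identity(self, exp1_design, rng):
        vals = rng.standard_normal(29)
        tc = windowed_evidence(np.zeros(512), exp1_design, 4)
        object.__setattr__(tc, "predicted", vals)
        d = average_derivative(tc)
        assert d == pytest.approx((vals[-1] - vals[0]) / 28)

    def test_constant_zero_and_increasing_positive(self, exp1_design):
        tc = windowed_evidence(np.zeros(512), exp1_design, 4)
        assert average_derivative(tc) == pytest.approx(0.0)
        object.__setattr__(tc, "predicted", np.arange(29, dtype=float))
        assert average_derivative(tc) > 0

    def test_half_ranges(self, exp2_design):
        ev = exp2_design.trials["trial_position"].to_numpy(float)
        tc = windowed_evidence(ev, exp2_design, 16)
        d1 = average_derivative(tc, bin_range=(1, 64), series="valid")
        d2 = average_derivative(tc, bin_range=(65, 128), series="valid")
        assert d1 == pytest.approx(1.0) and d2 == pytest.approx(1.0)

    def test_empty_range_rejected(self, exp1_design):
        tc = windowed_evidence(np.zeros(512), exp1_design, 4)
        with pytest.raises(ValueError):
            average_derivative(tc, bin_range=(100, 200))


class TestProperties:
    def test_bin_count_and_constant_smoothing_for_any_window(self, exp1_design):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(window=st.integers(min_value=1, max_value=32),
               halfwidth=st.integers(min_value=0, max_value=10),
               level=st.floats(-2, 2, allow_nan=False))
        def run(window, halfwidth, level):
            tc = windowed_evidence(np.full(512, level), exp1_design, window)
            assert len(tc.bins) == 32 - window + 1
            sm = smooth(tc, halfwidth)
            np.testing.assert_allclose(sm.valid, level, atol=1e-12)
            np.testing.assert_allclose(sm.predicted, 0.0, atol=1e-12)

        run()
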