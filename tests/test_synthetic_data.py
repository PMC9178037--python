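import numpy as np
import pytest

from shapelearn.lss_glm import hrf_function, lss_estimate
from shapelearn.pipeline import RunConfig, decode_participant
from shapelearn.synthetic_data import (
    GroundTruthDynamics,
    simulate_bold,
    simulate_participant,
    simulate_roi_pair,
)


def _decode(part, voxel_selection=False):
    cfg = RunConfig(experiment="2", voxel_selection=voxel_selection)
    return decode_participant(part, cfg)


class TestDynamics:
    def test_expected_contrast_switches_sign(self):
        dyn = GroundTruthDynamics()
        t = np.arange(1, 129)
        contrast = dyn.expected_contrast(t)
        assert contrast[40] < 0 < contrast[-1]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthDynamics(error_slope=0.0)
        with pytest.raises(ValueError):
            GroundTruthDynamics(error_midpoint=300.0)
        with pytest.raises(ValueError):
            GroundTruthDynamics(error_amplitude=0.3)

    def test_rescaling_to_short_blocks(self):
        dyn = GroundTruthDynamics.for_positions(32)
        assert dyn.error_midpoint == pytest.approx(8.0)
        assert dyn.prediction_midpoint == pytest.approx(24.0)


class TestSimulateParticipant:
    def test_presented_only_content_decodes_every_trial(self, exp2_design):
        # pure stimulus representation: no cue content, unit presented gain
        dyn = GroundTruthDynamics(
            error_amplitude=0.0, prediction_amplitude=0.0, presented_gain=1.0
        )
        part = simulate_participant(exp2_design, dyn, noise_sd=0.0, seed=0)
        trials = _decode(part)
        assert (trials["evidence"] > 0).all()

    def test_prediction_only_content_tracks_cue(self, exp2_design):
        # pure cue representation: evidence positive on valid trials and
        # negative (in presented-shape terms) on invalid trials
        dyn = GroundTruthDynamics(
            error_amplitude=0.0, prediction_amplitude=2.0,
            prediction_midpoint=1.0, prediction_slope=0.99,
            presented_gain=0.0,
        )
        part = simulate_participant(exp2_design, dyn, noise_sd=0.0, seed=0)
        trials = _decode(part)
        valid = trials["valid"].to_numpy(bool)
        assert (trials.loc[valid, "evidence"] > 0).all()
        assert (trials.loc[~valid, "evidence"] < 0).all()

    def test_seed_determinism_is_bitwise(self, exp2_design):
        a = simulate_participant(exp2_design, seed=42)
        b = simulate_participant(exp2_design, seed=42)
        np.testing.assert_array_equal(a.test_patterns.patterns,
                                      b.test_patterns.patterns)
        np.testing.assert_array_equal(a.train_patterns[0].patterns,
                                      b.train_patterns[0].patterns)

    def test_noise_attenuates_recovered_signal(self, exp2_design):
        # noisy training data inflate the weight Gram matrix, so the mean
        # evidence for the presented shape shrinks as noise grows
        dyn = GroundTruthDynamics(
            error_amplitude=0.0, prediction_amplitude=0.0, presented_gain=1.0
        )
        means = []
        for noise in (0.0, 4.0, 16.0):
            vals = []
            for seed in range(3):
                part = simulate_participant(
                    exp2_design, dyn, noise_sd=noise, n_voxels=60,
                    n_informative=30, seed=seed,
                )
                vals.append(_decode(part)["evidence"].mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_informative_exceeding_voxels_rejected(self, exp2_design):
        with pytest.raises(ValueError):
            simulate_participant(exp2_design, n_voxels=10, n_informative=20)

    def test_negative_noise_rejected(self, exp2_design):
        with pytest.raises(ValueError):
            simulate_participant(exp2_design, noise_sd=-1.0)

    def test_noiseless_pipeline_recovers_switch_signs(self, exp2_design):
        part = simulate_participant(exp2_design, noise_sd=0.0, seed=5)
        trials = _decode(part)
        from shapelearn.evidence_timecourse import smooth, windowed_evidence

        tc = smooth(windowed_evidence(trials["evidence"].to_numpy(),
                                      exp2_design, 16), 16)
        assert tc.predicted[10] < 0 < tc.predicted[-1]


class TestRoiPair:
    def test_late_coupling_raises_late_correlation(self, exp2_design):
        from shapelearn.connectivity import informational_connectivity

        a, b = simulate_roi_pair(exp2_design, coupling_amplitude=0.8, seed=1)
        ev_a = _decode(a)["evidence"].to_numpy()
        ev_b = _decode(b)["evidence"].to_numpy()
        tc = informational_connectivity(ev_a, ev_b, exp2_design, 16)
        assert tc.last_r > tc.first_r


class TestSimulateBold:
    def test_single_trial_is_scaled_hrf(self):
        bold = simulate_bold(np.array([[2.5]]), np.array([0.0]), noise_sd=0.0)
        h = hrf_function()
        t = np.arange(bold.series.shape[0]) * 1.0
        np.testing.assert_allclose(bold.series[:, 0], 2.5 * h(t), atol=1e-12)

    def test_superposition_and_lss_recovery(self, rng):
        betas = rng.standard_normal((2, 3))
        onsets = np.array([0.0, 40.0])
        bold = simulate_bold(betas, onsets, noise_sd=0.0)
        single0 = simulate_bold(betas[:1], onsets[:1], noise_sd=0.0)
        # before the second onset only the first trial contributes
        n = single0.series.shape[0]
        np.testing.assert_allclose(bold.series[:n], single0.series, atol=1e-12)
        est = lss_estimate(bold)
        np.testing.assert_allclose(est, betas, atol=1e-6)

    def test_zero_betas_pure_noise_is_zero_mean(self):
        bold = simulate_bold(np.zeros((3, 50)), np.array([0.0, 20.0, 40.0]),
                             noise_sd=1.0, seed=0)
        assert abs(bold.series.mean()) < 0.05

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_bold(np.ones((2, 1)), np.array([0.0, 20.0]), noise_sd=-0.1)
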