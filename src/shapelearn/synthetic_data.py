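"""Synthetic multivoxel data with known representational dynamics.

The generator mirrors the decoder's linear encoding model: voxel patterns
are a true weight matrix applied to channel-space content plus Gaussian
noise.  Shape-only (training) trials carry the presented shape's channel
vector at unit gain.  Prediction (test) trials mix two sources whose
gains follow scripted learning dynamics over trial position t:

* a *prediction* gain alpha(t) on the cued shape's channel vector
  (present on valid and invalid trials alike), and
* a *prediction-error* gain on the presented shape's channel vector,
  added on invalid trials only, on top of a constant baseline gain for
  the stimulus on screen.

Both gains are sigmoids of trial position, so the cue-isolating
valid-minus-invalid evidence contrast of the full pipeline is, in the
noiseless limit, the double sigmoid

    error_amplitude * sig(t; error) + prediction_amplitude * sig(t; prediction)

with a negative early (prediction-error) phase and a positive late
(prediction) phase — the representational switch the analysis is built
to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign, generate_design
from .iem_decoder import ChannelBasis, channel_vector
from .lss_glm import HrfParams, hrf_function

__all__ = [
    "GroundTruthDynamics",
    "VoxelPatternSet",
    "SyntheticParticipant",
    "BoldTimeseries",
    "simulate_participant",
    "simulate_roi_pair",
    "simulate_bold",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroundTruthDynamics:
    """Scripted representational dynamics over trial position.

    Amplitudes are in decoding-evidence units: ``error_amplitude`` is the
    (negative) asymptote the early prediction-error phase contributes to
    the valid-minus-invalid contrast, ``prediction_amplitude`` the
    (positive) late asymptote.  Midpoints are trial positions; slopes are
    per trial.  ``presented_gain`` is the constant channel gain of the
    shape on screen, shared by valid and invalid trials.
    """

    error_amplitude: float = -0.3
    prediction_amplitude: float = 0.4
    error_midpoint: float = 32.0
    prediction_midpoint: float = 96.0
    error_slope: float = 0.2
    prediction_slope: float = 0.2
    presented_gain: float = 0.2
    n_positions: int = 128

    def __post_init__(self) -> None:
        if self.error_slope <= 0 or self.prediction_slope <= 0:
            raise ValueError("slopes must be positive")
        for m in (self.error_midpoint, self.prediction_midpoint):
            if not 0 < m <= self.n_positions:
                raise ValueError("midpoints must lie within the block")
        if not 0 <= -self.error_amplitude <= 1:
            raise ValueError("error_amplitude must lie in [-1, 0]")
        if not 0 <= self.prediction_amplitude / 2 <= 1:
            raise ValueError("prediction_amplitude must lie in [0, 2]")
        if self.presented_gain < 0:
            raise ValueError("presented_gain must be non-negative")

    @classmethod
    def for_positions(cls, n_positions: int, **overrides) -> "GroundTruthDynamics":
        """Defaults rescaled to a block of ``n_positions`` trials (error
        phase centred at 1/4, prediction phase at 3/4 of the block)."""
        scale = 128.0 / n_positions
        params = dict(
            error_midpoint=0.25 * n_positions,
            prediction_midpoint=0.75 * n_positions,
            error_slope=0.2 * scale,
            prediction_slope=0.2 * scale,
            n_positions=n_positions,
        )
        params.update(overrides)
        return cls(**params)

    def prediction_gain(self, t) -> np.ndarray:
        """alpha(t): cued-shape content on every cued trial."""
        return (self.prediction_amplitude / 2.0) * _sigmoid(
            self.prediction_slope * (np.asarray(t, float) - self.prediction_midpoint)
        )

    def error_gain(self, t) -> np.ndarray:
        """Extra presented-shape content on invalid trials."""
        return (-self.error_amplitude) * _sigmoid(
            self.error_slope * (np.asarray(t, float) - self.error_midpoint)
        )

    def expected_contrast(self, t) -> np.ndarray:
        """Noiseless valid-minus-invalid evidence (up to the basis-overlap
        factor, which is ~1 for 72 deg channel spacing)."""
        t = np.asarray(t, float)
        return (
            self.error_amplitude
            * _sigmoid(self.error_slope * (t - self.error_midpoint))
            + self.prediction_amplitude
            * _sigmoid(self.prediction_slope * (t - self.prediction_midpoint))
        )


@dataclass(frozen=True)
class VoxelPatternSet:
    """Trials x voxels activity patterns with their trial labels."""

    patterns: np.ndarray
    labels: pd.DataFrame
    roi_label: str = "hippocampus"

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.labels):
            raise ValueError("one label row per pattern row is required")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns must be finite")

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset_voxels(self, idx: np.ndarray) -> "VoxelPatternSet":
        return replace(self, patterns=self.patterns[:, idx])


@dataclass(frozen=True)
class SyntheticParticipant:
    """One simulated participant-ROI: ground truth plus generated data."""

    true_weights: np.ndarray  # voxels x channels
    noise_sd: float
    n_voxels: int
    n_informative: int
    train_patterns: tuple[VoxelPatternSet, ...]  # the two shape-only runs
    test_patterns: VoxelPatternSet  # the prediction runs
    dynamics: GroundTruthDynamics
    seed: int


@dataclass(frozen=True)
class BoldTimeseries:
    """Voxelwise BOLD with the single-trial betas that generated it."""

    tr_seconds: float
    series: np.ndarray  # time x voxels
    event_onsets: np.ndarray  # seconds
    true_betas: np.ndarray  # trials x voxels

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        duration = self.series.shape[0] * self.tr_seconds
        if np.any(np.asarray(self.event_onsets) >= duration):
            raise ValueError("event onsets must fall within the series")


def _true_weight_matrix(n_voxels: int, n_informative: int, n_channels: int,
                        rng: np.random.Generator) -> np.ndarray:
    if n_informative > n_voxels:
        raise ValueError("n_informative cannot exceed n_voxels")
    w = np.zeros((n_voxels, n_channels))
    w[:n_informative] = rng.standard_normal((n_informative, n_channels))
    return w


def _shape_only_patterns(design: ExperimentDesign, w: np.ndarray, noise_sd: float,
                         basis: ChannelBasis, rng: np.random.Generator,
                         roi_label: str) -> VoxelPatternSet:
    shapes = design.trials["presented_shape"].to_numpy()
    content = np.stack([channel_vector(basis, int(s)) for s in shapes])  # (t, k)
    patterns = content @ w.T
    if noise_sd > 0:
        patterns = patterns + noise_sd * rng.standard_normal(patterns.shape)
    return VoxelPatternSet(patterns=patterns, labels=design.trials.copy(),
                           roi_label=roi_label)


def _prediction_patterns(
    design: ExperimentDesign,
    dynamics: GroundTruthDynamics,
    w: np.ndarray,
    noise_sd: float,
    basis: ChannelBasis,
    rng: np.random.Generator,
    roi_label: str,
    coupling_gain: np.ndarray | None = None,
    shared_latent: np.ndarray | None = None,
) -> VoxelPatternSet:
    trials = design.trials
    t = trials["trial_position"].to_numpy(float)
    valid = trials["valid"].to_numpy(bool)
    pred = trials["predicted_shape"].to_numpy(int)
    pres = trials["presented_shape"].to_numpy(int)

    alpha = dynamics.prediction_gain(t)
    beta = np.full(len(t), dynamics.presented_gain)
    beta[~valid] += dynamics.error_gain(t[~valid])
    if coupling_gain is not None:
        beta = beta + coupling_gain * shared_latent

    c_pred = np.stack([channel_vector(basis, int(s)) for s in pred])
    c_pres = np.stack([channel_vector(basis, int(s)) for s in pres])
    content = alpha[:, None] * c_pred + beta[:, None] * c_pres
    patterns = content @ w.T
    if noise_sd > 0:
        patterns = patterns + noise_sd * rng.standard_normal(patterns.shape)
    return VoxelPatternSet(patterns=patterns, labels=trials.copy(),
                           roi_label=roi_label)


def simulate_participant(
    design: ExperimentDesign,
    dynamics: GroundTruthDynamics | None = None,
    noise_sd: float = 4.0,
    n_voxels: int = 200,
    n_informative: int = 100,
    seed: int = 0,
    roi_label: str = "hippocampus",
    basis: ChannelBasis | None = None,
    shape_only_designs: tuple[ExperimentDesign, ExperimentDesign] | None = None,
    _coupling_gain: np.ndarray | None = None,
    _shared_latent: np.ndarray | None = None,
    _weights: np.ndarray | None = None,
) -> SyntheticParticipant:
    """Simulate one participant-ROI from a prediction design.

    Two shape-only runs (decoder training data) are generated from seeds
    derived from ``seed`` unless supplied.  All randomness (weights,
    noise, shape-only orderings) is seed-deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    basis = basis or ChannelBasis()
    dynamics = dynamics or GroundTruthDynamics.for_positions(design.trials_per_block)
    rng = np.random.default_rng(seed)
    if shape_only_designs is None:
        d1 = generate_design("shape_only", seed=int(rng.integers(2**31)))
        d2 = generate_design("shape_only", seed=int(rng.integers(2**31)))
        shape_only_designs = (d1, d2)
    w = _weights if _weights is not None else _true_weight_matrix(
        n_voxels, n_informative, basis.n_channels, rng
    )
    train = tuple(
        _shape_only_patterns(d, w, noise_sd, basis, rng, roi_label)
        for d in shape_only_designs
    )
    test = _prediction_patterns(
        design, dynamics, w, noise_sd, basis, rng, roi_label,
        coupling_gain=_coupling_gain, shared_latent=_shared_latent,
    )
    return SyntheticParticipant(
        true_weights=w, noise_sd=noise_sd, n_voxels=n_voxels,
        n_informative=n_informative, train_patterns=train, test_patterns=test,
        dynamics=dynamics, seed=seed,
    )


def simulate_roi_pair(
    design: ExperimentDesign,
    dynamics: GroundTruthDynamics | None = None,
    coupling_amplitude: float = 0.5,
    coupling_midpoint: float | None = None,
    coupling_slope: float = 0.2,
    noise_sd: float = 4.0,
    n_voxels: int = 200,
    n_informative: int = 100,
    seed: int = 0,
    roi_labels: tuple[str, str] = ("posterior_subiculum", "entorhinal_cortex"),
) -> tuple[SyntheticParticipant, SyntheticParticipant]:
    """Two ROIs whose presented-shape gains share a latent fluctuation.

    A standard-normal latent value per trial is scaled by a sigmoid
    coupling gain (midpoint defaulting to 3/4 of the block) and added to
    the presented-shape gain of *both* ROIs, so their trialwise decoding
    evidence co-fluctuates late but not early in the blocks — the
    informational-connectivity effect.
    """
    n_pos = design.trials_per_block
    dynamics = dynamics or GroundTruthDynamics.for_positions(n_pos)
    if coupling_midpoint is None:
        coupling_midpoint = 0.75 * n_pos
    rng = np.random.default_rng(seed)
    t = design.trials["trial_position"].to_numpy(float)
    gain = coupling_amplitude * _sigmoid(coupling_slope * (t - coupling_midpoint))
    latent = rng.standard_normal(len(t))
    parts = []
    for i, roi in enumerate(roi_labels):
        parts.append(
            simulate_participant(
                design, dynamics, noise_sd=noise_sd, n_voxels=n_voxels,
                n_informative=n_informative, seed=int(rng.integers(2**31)),
                roi_label=roi, _coupling_gain=gain, _shared_latent=latent,
            )
        )
    return parts[0], parts[1]


def simulate_bold(
    true_betas: np.ndarray,
    event_onsets: np.ndarray,
    hrf_params: HrfParams = HrfParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> BoldTimeseries:
    """Voxelwise BOLD built from known single-trial betas.

    The series is the superposition of each trial's beta times the HRF at
    its onset, sampled at the TR, plus i.i.d. Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    true_betas = np.atleast_2d(np.asarray(true_betas, float))
    onsets = np.sort(np.asarray(event_onsets, float))
    if true_betas.shape[0] != len(onsets):
        raise ValueError("one beta row per event is required")
    duration = onsets[-1] + hrf_params.duration + tr_seconds
    t_grid = np.arange(0.0, duration, tr_seconds)
    h = hrf_function(hrf_params)
    design_cols = np.stack([h(t_grid - o) for o in onsets])  # (trials, time)
    series = design_cols.T @ true_betas
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series = series + noise_sd * rng.standard_normal(series.shape)
    return BoldTimeseries(tr_seconds=tr_seconds, series=series,
                          event_onsets=onsets, true_betas=true_betas)
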