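"""Forward-model (inverted encoding) shape decoder.

The decoder assumes each voxel's shape selectivity is a weighted sum of
five hypothetical channels with idealised tuning curves — half-wave
rectified sinusoids raised to the fifth power, equally spaced (72 deg
apart) on a circularised shape axis, with shape i centred on channel i.

Training relates the voxels x shapes matrix of shape-only responses
B_train (m x n) to the channel outputs C_train (k x n) through a weight
matrix W (m x k),

    B_train = W @ C_train + N,        W_hat = B Ct (C Ct)^-1,

and testing inverts the fitted weights to reconstruct channel outputs
from new activity patterns,

    C_test_hat = (Wt W)^-1 Wt B_test.

The reconstructed outputs weight the basis functions into a shape tuning
curve, and decoding evidence is the curve's amplitude at the presented
shape minus its amplitude at the non-presented alternative (positive =
evidence for the presented shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelBasis",
    "WeightMatrix",
    "TuningCurve",
    "evaluate_basis",
    "channel_vector",
    "fit_weights",
    "reconstruct_channels",
    "tuning_curve",
    "decoding_evidence",
    "evidence_per_trial",
    "select_voxels",
    "select_most_active",
]


@dataclass(frozen=True)
class ChannelBasis:
    """Five rectified-sinusoid-to-the-fifth channels on a 360 deg axis."""

    n_channels: int = 5
    exponent: int = 5
    grid_step_deg: float = 1.0

    @property
    def centers(self) -> np.ndarray:
        """Channel centres in degrees; shape i sits at centre i."""
        return np.arange(self.n_channels) * (360.0 / self.n_channels)

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.grid_step_deg)

    def shape_position(self, shape_index: int) -> float:
        """Axis position (deg) of 1-based ``shape_index``."""
        if not 1 <= shape_index <= self.n_channels:
            raise ValueError(f"shape index {shape_index} outside 1..{self.n_channels}")
        return float(self.centers[shape_index - 1])


@dataclass(frozen=True)
class WeightMatrix:
    """Fitted channel weights, one row per voxel."""

    weights: np.ndarray  # m voxels x k channels
    trained_on: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class TuningCurve:
    """Reconstructed shape tuning curve on the dense circular axis."""

    axis: np.ndarray  # degrees
    amplitude: np.ndarray

    def at(self, position_deg: float) -> float:
        idx = int(np.argmin(np.abs(self.axis - position_deg % 360.0)))
        return float(self.amplitude[idx])


def evaluate_basis(basis: ChannelBasis, x) -> np.ndarray:
    """Channel values at axis position(s) ``x`` (degrees).

    Channel j responds max(0, cos(d))^exponent where d is the circular
    distance from x to centre j; the response is 1 at the centre and 0
    from 90 deg outwards.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    delta = np.deg2rad(x[:, None] - basis.centers[None, :])
    vals = np.maximum(0.0, np.cos(delta)) ** basis.exponent
    # rectification boundary: cos(90 deg) is O(1e-17) in floating point,
    # so its fifth power is denormal noise — snap to the exact zero
    vals[vals < 1e-12] = 0.0
    return vals  # (len(x), k)


def channel_vector(basis: ChannelBasis, shape_index: int) -> np.ndarray:
    """Idealised channel output vector (length k) for one shape."""
    return evaluate_basis(basis, basis.shape_position(shape_index))[0]


def _train_matrix(basis: ChannelBasis) -> np.ndarray:
    """C_train, k x n with one column per shape condition."""
    cols = [channel_vector(basis, i + 1) for i in range(basis.n_channels)]
    return np.column_stack(cols)


def aggregate_by_shape(patterns: np.ndarray, shapes: np.ndarray, n_shapes: int = 5) -> np.ndarray:
    """Mean pattern per shape condition -> voxels x shapes matrix."""
    cols = []
    for s in range(1, n_shapes + 1):
        mask = shapes == s
        if not mask.any():
            raise ValueError(f"no training trials for shape {s}")
        cols.append(patterns[mask].mean(axis=0))
    return np.column_stack(cols)


def fit_weights(
    train_patterns: np.ndarray,
    train_shapes: np.ndarray,
    basis: ChannelBasis | None = None,
    trained_on: str = "",
) -> WeightMatrix:
    """Least-squares channel weights from shape-only training data.

    ``train_patterns`` is trials x voxels with per-trial shape labels
    ``train_shapes`` (1-based); trials are averaged per shape before the
    regression, so n equals the number of shape conditions.
    """
    basis = basis or ChannelBasis()
    b_train = aggregate_by_shape(train_patterns, np.asarray(train_shapes), basis.n_channels)
    c_train = _train_matrix(basis)
    gram = c_train @ c_train.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"channel Gram matrix is singular (condition number {cond:.2e})"
        )
    w = b_train @ c_train.T @ np.linalg.inv(gram)
    return WeightMatrix(weights=w, trained_on=trained_on)


def reconstruct_channels(weights: WeightMatrix, test_patterns: np.ndarray) -> np.ndarray:
    """Invert the encoding model: trials x channels outputs for B_test."""
    w = weights.weights
    test_patterns = np.atleast_2d(np.asarray(test_patterns, dtype=float))
    if test_patterns.shape[1] != w.shape[0]:
        raise ValueError(
            f"test patterns have {test_patterns.shape[1]} voxels, weights {w.shape[0]}"
        )
    gram = w.T @ w
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "weight matrix is rank deficient; consider selecting informative "
            f"voxels (condition number {cond:.2e})"
        )
    return np.linalg.solve(gram, w.T @ test_patterns.T).T


def tuning_curve(channel_outputs: np.ndarray, basis: ChannelBasis | None = None) -> TuningCurve:
    """Weighted average of the basis functions for one trial's outputs."""
    basis = basis or ChannelBasis()
    outputs = np.asarray(channel_outputs, dtype=float)
    if outputs.shape != (basis.n_channels,):
        raise ValueError(f"expected {basis.n_channels} channel outputs")
    grid_vals = evaluate_basis(basis, basis.grid)  # (g, k)
    return TuningCurve(axis=basis.grid, amplitude=grid_vals @ outputs)


def decoding_evidence(curve: TuningCurve, presented: int, alternative: int,
                      basis: ChannelBasis | None = None) -> float:
    """Tuning-curve amplitude at the presented shape minus the alternative."""
    if presented == alternative:
        raise ValueError("presented and alternative shapes must differ")
    basis = basis or ChannelBasis()
    return curve.at(basis.shape_position(presented)) - curve.at(
        basis.shape_position(alternative)
    )


def evidence_per_trial(
    weights: WeightMatrix,
    test_patterns: np.ndarray,
    presented: np.ndarray,
    alternative: np.ndarray,
    basis: ChannelBasis | None = None,
) -> np.ndarray:
    """Vectorised per-trial decoding evidence.

    Equivalent to reconstructing channels, building each trial's tuning
    curve and differencing its amplitudes at the presented and alternative
    shape positions; computed as a single matrix product.
    """
    basis = basis or ChannelBasis()
    outputs = reconstruct_channels(weights, test_patterns)  # (t, k)
    presented = np.asarray(presented, dtype=int)
    alternative = np.asarray(alternative, dtype=int)
    pos_pres = np.array([basis.shape_position(s) for s in presented])
    pos_alt = np.array([basis.shape_position(s) for s in alternative])
    bp = evaluate_basis(basis, pos_pres)  # (t, k)
    ba = evaluate_basis(basis, pos_alt)
    return np.einsum("tk,tk->t", outputs, bp - ba)


# ---------------------------------------------------------------------------
# voxel selection
# ---------------------------------------------------------------------------

def _mean_evidence_shapes_2_4(
    weights: WeightMatrix, patterns: np.ndarray, shapes: np.ndarray,
    basis: ChannelBasis,
) -> float:
    mask = np.isin(shapes, (2, 4))
    pres = shapes[mask]
    alt = np.where(pres == 2, 4, 2)
    # tolerant reconstruction: candidate subsets may be rank deficient
    # (e.g. duplicated voxels); least squares scores them instead of failing
    outputs = np.linalg.lstsq(weights.weights, patterns[mask].T, rcond=None)[0].T
    bp = evaluate_basis(basis, np.array([basis.shape_position(s) for s in pres]))
    ba = evaluate_basis(basis, np.array([basis.shape_position(s) for s in alt]))
    return float(np.einsum("tk,tk->t", outputs, bp - ba).mean())


def select_voxels(
    run_a_patterns: np.ndarray,
    run_a_shapes: np.ndarray,
    run_b_patterns: np.ndarray,
    run_b_shapes: np.ndarray,
    basis: ChannelBasis | None = None,
    fractions: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Cross-validated informativeness-ranked voxel selection.

    Voxels are ranked by the standard deviation of their fitted channel
    weights (how differently they respond to the five channels), using
    both shape-only runs.  For each candidate fraction (10%..100% of the
    ranking) the decoder is trained on one run and tested on the other
    (both directions, averaged) and scored by mean decoding evidence on
    shapes 2 and 4; the best-scoring fraction wins, ties going to the
    smallest voxel count.

    Returns the selected voxel indices (in ranking order) and the chosen
    fraction.
    """
    basis = basis or ChannelBasis()
    n_vox = run_a_patterns.shape[1]
    if n_vox < 10:
        raise ValueError("voxel selection requires at least 10 voxels")
    if fractions is None:
        fractions = np.arange(0.1, 1.01, 0.1)
    both = np.vstack([run_a_patterns, run_b_patterns])
    both_shapes = np.concatenate([run_a_shapes, run_b_shapes])
    w_all = fit_weights(both, both_shapes, basis)
    info = w_all.weights.std(axis=1)
    ranking = np.argsort(-info, kind="stable")
    best_score, best_count = -np.inf, None
    for frac in fractions:
        count = max(int(round(frac * n_vox)), basis.n_channels)
        subset = ranking[:count]
        score = 0.0
        for (tr_p, tr_s, te_p, te_s) in (
            (run_a_patterns, run_a_shapes, run_b_patterns, run_b_shapes),
            (run_b_patterns, run_b_shapes, run_a_patterns, run_a_shapes),
        ):
            w = fit_weights(tr_p[:, subset], tr_s, basis)
            score += _mean_evidence_shapes_2_4(w, te_p[:, subset], np.asarray(te_s), basis)
        score /= 2.0
        if score > best_score + 1e-12:
            best_score, best_count, best_frac = score, count, frac
    return ranking[:best_count], float(best_frac)


def select_most_active(activation: np.ndarray, n_voxels: int = 500) -> np.ndarray:
    """Alternative selection rule: top-n voxels of a supplied activation
    statistic (used for retinotopic visual ROIs)."""
    activation = np.asarray(activation, dtype=float)
    n = min(n_voxels, len(activation))
    return np.argsort(-activation, kind="stable")[:n]
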