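"""Single-trial response estimation (Least-Squares-Separate).

Each trial's multivoxel response is estimated from the BOLD time series by
its own GLM: the trial of interest is one regressor (a delta at trial
onset convolved with a double-gamma haemodynamic response function, HRF,
plus its temporal derivative) and all remaining trials are combined into a
single nuisance regressor (also with derivative).  The coefficient of the
trial-of-interest HRF regressor, per voxel, is that trial's activity
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HrfParams",
    "hrf_function",
    "double_gamma_hrf",
    "hrf_regressor",
    "lss_estimate",
]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "undershoot_ratio", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < self.undershoot_delay:
            raise ValueError("duration must cover the undershoot delay")


def hrf_function(params: HrfParams = HrfParams()):
    """Continuous peak-normalised double-gamma response, h(t).

    Uses the difference-of-gammas form with the peak term
    (t/d1)^(d1/b1) exp(-(t-d1)/b1), which peaks exactly at ``peak_delay``;
    h(t) = 0 for t <= 0 and beyond ``duration``.
    """
    d1, b1 = params.peak_delay, params.peak_dispersion
    d2, b2 = params.undershoot_delay, params.undershoot_dispersion
    c = params.undershoot_ratio

    def raw(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = (t > 0) & (t <= params.duration)
        tp = t[pos]
        peak = (tp / d1) ** (d1 / b1) * np.exp(-(tp - d1) / b1)
        under = (tp / d2) ** (d2 / b2) * np.exp(-(tp - d2) / b2)
        out[pos] = peak - c * under
        return out

    norm = raw(np.linspace(0.0, params.duration, 4096)).max()

    def h(t):
        return raw(t) / norm

    return h


def double_gamma_hrf(t_grid: np.ndarray, params: HrfParams = HrfParams(),
                     dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Sampled HRF and its finite-difference temporal derivative."""
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing")
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    h = hrf_function(params)
    deriv = (h(t_grid + dt) - h(t_grid - dt)) / (2.0 * dt)
    return h(t_grid), deriv


def hrf_regressor(t_grid: np.ndarray, onsets, params: HrfParams = HrfParams(),
                  dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Summed event regressor and its derivative regressor.

    Delta functions at the ``onsets`` convolved with the HRF, evaluated at
    the sample times ``t_grid``.
    """
    h = hrf_function(params)
    t_grid = np.asarray(t_grid, dtype=float)
    reg = np.zeros_like(t_grid)
    dreg = np.zeros_like(t_grid)
    for onset in np.atleast_1d(onsets):
        lag = t_grid - onset
        reg += h(lag)
        dreg += (h(lag + dt) - h(lag - dt)) / (2.0 * dt)
    return reg, dreg


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the offending columns from the QR diagonal
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )


def lss_estimate(bold, events=None, hrf: HrfParams = HrfParams(),
                 nuisance: np.ndarray | None = None) -> np.ndarray:
    """Least-Squares-Separate single-trial betas.

    Parameters
    ----------
    bold:
        Object with ``series`` (time x voxels), ``tr_seconds`` and
        (optionally) ``event_onsets``; a plain (series, tr) tuple also
        works if ``events`` is given.
    events:
        Trial onsets in seconds; defaults to ``bold.event_onsets``.
    nuisance:
        Optional time x regressors matrix (e.g. motion parameters),
        appended to every trial's model.

    Returns
    -------
    trials x voxels matrix of the trial-of-interest HRF coefficients.
    """
    if hasattr(bold, "series"):
        series, tr = np.asarray(bold.series, float), float(bold.tr_seconds)
        if events is None:
            events = bold.event_onsets
    else:
        series, tr = np.asarray(bold[0], float), float(bold[1])
    if events is None:
        raise ValueError("trial onsets are required")
    onsets = np.asarray(events, dtype=float)
    if len(onsets) < 2:
        raise ValueError("LSS requires at least 2 events")
    if series.ndim == 1:
        series = series[:, None]
    t_grid = np.arange(series.shape[0]) * tr

    betas = np.empty((len(onsets), series.shape[1]))
    for i in range(len(onsets)):
        others = np.delete(onsets, i)
        xi, dxi = hrf_regressor(t_grid, [onsets[i]], hrf)
        xo, dxo = hrf_regressor(t_grid, others, hrf)
        cols = [xi, dxi, xo, dxo]
        names = ["trial_hrf", "trial_derivative", "others_hrf", "others_derivative"]
        if nuisance is not None:
            nuis = np.atleast_2d(np.asarray(nuisance, float))
            if nuis.shape[0] != series.shape[0]:
                nuis = nuis.T
            cols += list(nuis.T)
            names += [f"nuisance_{j}" for j in range(nuis.shape[1])]
        cols.append(np.ones_like(t_grid))
        names.append("intercept")
        x = np.column_stack(cols)
        _check_rank(x, names)
        coef, *_ = np.linalg.lstsq(x, series, rcond=None)
        betas[i] = coef[0]
    return betas
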