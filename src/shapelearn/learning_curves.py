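"""Sigmoid learning-curve fits.

Learning timecourses are quantified by bounded least-squares sigmoid
fits: a single sigmoid A / (1 + exp(-k (x - x0))) with amplitude A in
[-1, 1], slope k in [0.01, 1] and midpoint x0 within the block; or a sum
of two sigmoids whose midpoints are constrained to the first and second
half of the block respectively, letting early and late dynamics differ
(and in particular letting an early negative prediction-error phase
coexist with a late positive prediction phase).  Optimisation is a
seeded multistart of bounded local minimisations, following the original
procedure of 100 random restarts within the parameter box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SigmoidFit",
    "DoubleSigmoidFit",
    "sigmoid",
    "fit_single_sigmoid",
    "fit_double_sigmoid",
]

AMPLITUDE_BOUNDS = (-1.0, 1.0)
SLOPE_BOUNDS = (0.01, 1.0)
DEFAULT_N_STARTS = 100


def sigmoid(x, amplitude: float, slope: float, midpoint: float) -> np.ndarray:
    return amplitude / (1.0 + np.exp(-slope * (np.asarray(x, float) - midpoint)))


@dataclass(frozen=True)
class SigmoidFit:
    amplitude: float
    slope: float
    midpoint: float
    sse: float
    n_starts: int

    def predict(self, x) -> np.ndarray:
        return sigmoid(x, self.amplitude, self.slope, self.midpoint)


@dataclass(frozen=True)
class DoubleSigmoidFit:
    early: SigmoidFit
    late: SigmoidFit
    sse: float

    def predict(self, x) -> np.ndarray:
        return self.early.predict(x) + self.late.predict(x)


def _clean(y, x):
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if x is None else np.asarray(x, float)
    keep = np.isfinite(y)
    if not keep.any():
        raise ValueError("timecourse is entirely missing")
    return y[keep], x[keep]


def _multistart(objective, bounds, n_starts, seed, extra_starts=()):
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [0.5 * (lo + hi), *extra_starts]
    starts += list(lo + rng.random((n_starts, len(bounds))) * (hi - lo))
    best, best_fun = None, np.inf
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds, jac=True)
        if res.fun < best_fun:
            best, best_fun = res.x, float(res.fun)
    return best, best_fun


def _sigmoid_terms(x, p):
    """Value and parameter gradient of one sigmoid component."""
    a, k, x0 = p
    s = 1.0 / (1.0 + np.exp(-k * (x - x0)))
    ds = s * (1.0 - s)
    return a * s, np.stack([s, a * ds * (x - x0), -a * k * ds])


def fit_single_sigmoid(
    timecourse,
    x=None,
    midpoint_bounds: tuple[float, float] | None = None,
    amplitude_bounds: tuple[float, float] = AMPLITUDE_BOUNDS,
    slope_bounds: tuple[float, float] = SLOPE_BOUNDS,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> SigmoidFit:
    """Bounded least-squares single-sigmoid fit.

    ``timecourse`` may be an array of per-bin values (missing bins NaN)
    or an object with ``predicted`` and ``bins`` attributes; ``x`` gives
    the bins' trial positions (defaults to 1..n or the object's bins).
    ``midpoint_bounds`` defaults to the span of ``x``.
    """
    if hasattr(timecourse, "predicted"):
        x = timecourse.bins if x is None else x
        timecourse = timecourse.predicted
    y, x = _clean(timecourse, x)
    if len(y) < 4:
        raise ValueError("single-sigmoid fit needs >= 4 non-missing bins")
    if midpoint_bounds is None:
        midpoint_bounds = (float(x.min()), float(x.max()))
    bounds = [amplitude_bounds, slope_bounds, midpoint_bounds]

    def objective(p):
        f, grad = _sigmoid_terms(x, p)
        r = f - y
        return float(np.sum(r**2)), 2.0 * grad @ r

    best, sse = _multistart(objective, bounds, n_starts, seed)
    return SigmoidFit(amplitude=float(best[0]), slope=float(best[1]),
                      midpoint=float(best[2]), sse=sse, n_starts=n_starts)


def fit_double_sigmoid(
    timecourse,
    x=None,
    half_split: float | None = None,
    midpoint_bounds_early: tuple[float, float] | None = None,
    midpoint_bounds_late: tuple[float, float] | None = None,
    amplitude_bounds: tuple[float, float] = AMPLITUDE_BOUNDS,
    slope_bounds: tuple[float, float] = SLOPE_BOUNDS,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> DoubleSigmoidFit:
    """Joint bounded fit of a sum of two sigmoids.

    The early sigmoid's midpoint is constrained to the first half of the
    block and the late one's to the second half; ``half_split`` (e.g. 64
    for 128-trial blocks, 16 for 32-trial blocks) places the boundary,
    defaulting to the midpoint of the data span.  Both amplitudes are
    free in [-1, 1], so no sign priors are imposed.  The best single-
    sigmoid solution (late amplitude zero) is seeded as one start, which
    guarantees the double fit never has a larger residual than the
    nested single fit.
    """
    if hasattr(timecourse, "predicted"):
        x = timecourse.bins if x is None else x
        timecourse = timecourse.predicted
    y, x = _clean(timecourse, x)
    if len(y) < 7:
        raise ValueError("double-sigmoid fit needs >= 7 non-missing bins")
    if half_split is None:
        half_split = float(x.min() + x.max()) / 2.0
    if midpoint_bounds_early is None:
        midpoint_bounds_early = (float(x.min()), float(half_split))
    if midpoint_bounds_late is None:
        midpoint_bounds_late = (float(half_split) + 1.0, float(max(x.max(), half_split + 2)))
    bounds = [
        amplitude_bounds, slope_bounds, midpoint_bounds_early,
        amplitude_bounds, slope_bounds, midpoint_bounds_late,
    ]

    def objective(p):
        f1, g1 = _sigmoid_terms(x, p[:3])
        f2, g2 = _sigmoid_terms(x, p[3:])
        r = f1 + f2 - y
        return float(np.sum(r**2)), 2.0 * np.concatenate([g1, g2]) @ r

    single = fit_single_sigmoid(
        y, x,
        midpoint_bounds=(float(x.min()), float(x.max())),
        amplitude_bounds=amplitude_bounds, slope_bounds=slope_bounds,
        n_starts=max(n_starts // 2, 1), seed=seed,
    )
    late_mid = 0.5 * (midpoint_bounds_late[0] + midpoint_bounds_late[1])
    early_mid = 0.5 * (midpoint_bounds_early[0] + midpoint_bounds_early[1])
    m_early = float(np.clip(single.midpoint, *midpoint_bounds_early))
    m_late = float(np.clip(single.midpoint, *midpoint_bounds_late))
    embedded = [
        [single.amplitude, single.slope, m_early, 0.0, 0.5, late_mid],
        [0.0, 0.5, early_mid, single.amplitude, single.slope, m_late],
    ]
    best, sse = _multistart(objective, bounds, n_starts, seed, extra_starts=embedded)
    early = SigmoidFit(float(best[0]), float(best[1]), float(best[2]),
                       sse=sse, n_starts=n_starts)
    late = SigmoidFit(float(best[3]), float(best[4]), float(best[5]),
                      sse=sse, n_starts=n_starts)
    return DoubleSigmoidFit(early=early, late=late, sse=sse)
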