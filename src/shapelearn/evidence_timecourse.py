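"""Condition-wise learning timecourses from per-trial decoding evidence.

A sliding window over trial positions pools trials across blocks: within
each window, evidence is averaged separately for validly and invalidly
predicted shapes.  The valid-minus-invalid contrast isolates the cued
(predicted) shape content — the presented shapes are identical in both
trial types — while their average tracks the shape on screen.  The binned
series is then smoothed with a truncated moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = ["EvidenceTimecourse", "windowed_evidence", "smooth", "average_derivative"]


@dataclass(frozen=True)
class EvidenceTimecourse:
    """Per-bin evidence series; bins are window start positions.

    ``predicted`` is valid - invalid under the default ``"difference"``
    convention, or (valid + (1 - invalid)) / 2 under the
    ``"average_complement"`` convention (the two differ by the affine map
    x -> x/2 + 1/2).  Bins with no invalid trials are missing (NaN), not
    zero.
    """

    bins: np.ndarray  # window start trial positions
    valid: np.ndarray
    invalid: np.ndarray
    predicted: np.ndarray
    presented: np.ndarray
    n_valid: np.ndarray
    n_invalid: np.ndarray
    window_len: int
    smooth_halfwidth: int = 0
    convention: str = "difference"

    def __post_init__(self) -> None:
        n = len(self.bins)
        for name in ("valid", "invalid", "predicted", "presented"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must share the bin grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins,
                "valid": self.valid,
                "invalid": self.invalid,
                "predicted": self.predicted,
                "presented": self.presented,
                "n_valid_trials": self.n_valid,
                "n_invalid_trials": self.n_invalid,
            }
        )


def _combine(valid: np.ndarray, invalid: np.ndarray, convention: str) -> np.ndarray:
    if convention == "difference":
        return valid - invalid
    if convention == "average_complement":
        return (valid + (1.0 - invalid)) / 2.0
    raise ValueError(f"unknown predicted-evidence convention {convention!r}")


def windowed_evidence(
    per_trial_evidence: np.ndarray,
    design: ExperimentDesign,
    window_len: int,
    convention: str = "difference",
) -> EvidenceTimecourse:
    """Sliding-window condition averages of per-trial evidence.

    ``per_trial_evidence`` is aligned row-for-row with
    ``design.trials``.  Window starts run from position 1 to
    ``n_positions - window_len + 1``; each window pools trials of all
    blocks whose trial position falls inside it.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    trials = design.prediction_trials()
    ev = np.asarray(per_trial_evidence, dtype=float)
    if len(ev) != len(trials):
        raise ValueError("evidence must cover all prediction trials")
    pos = trials["trial_position"].to_numpy()
    is_valid = trials["valid"].to_numpy(bool)
    n_pos = int(pos.max())
    starts = np.arange(1, n_pos - window_len + 2)

    valid = np.full(len(starts), np.nan)
    invalid = np.full(len(starts), np.nan)
    n_valid = np.zeros(len(starts), dtype=int)
    n_invalid = np.zeros(len(starts), dtype=int)
    for i, s in enumerate(starts):
        in_win = (pos >= s) & (pos <= s + window_len - 1)
        v = ev[in_win & is_valid]
        iv = ev[in_win & ~is_valid]
        n_valid[i], n_invalid[i] = len(v), len(iv)
        if len(v):
            valid[i] = v.mean()
        if len(iv):
            invalid[i] = iv.mean()
    return EvidenceTimecourse(
        bins=starts,
        valid=valid,
        invalid=invalid,
        predicted=_combine(valid, invalid, convention),
        presented=(valid + invalid) / 2.0,
        n_valid=n_valid,
        n_invalid=n_invalid,
        window_len=window_len,
        convention=convention,
    )


def _moving_average(y: np.ndarray, halfwidth: int) -> np.ndarray:
    out = np.full_like(y, np.nan, dtype=float)
    for i in range(len(y)):
        seg = y[max(0, i - halfwidth): i + halfwidth + 1]
        seg = seg[np.isfinite(seg)]
        if len(seg):
            out[i] = seg.mean()
    return out


def smooth(timecourse: EvidenceTimecourse, halfwidth: int) -> EvidenceTimecourse:
    """Truncated moving average over bins (window = 2*halfwidth + 1).

    Edges average over the available bins only; missing bins are skipped
    within each window and stay missing only if the whole window is.
    Applied to the contrast and condition series alike (smoothing after
    the valid/invalid contrast).
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if halfwidth == 0:
        return timecourse
    return replace(
        timecourse,
        valid=_moving_average(timecourse.valid, halfwidth),
        invalid=_moving_average(timecourse.invalid, halfwidth),
        predicted=_moving_average(timecourse.predicted, halfwidth),
        presented=_moving_average(timecourse.presented, halfwidth),
        smooth_halfwidth=halfwidth,
    )


def average_derivative(
    timecourse: EvidenceTimecourse,
    bin_range: tuple[float, float] | None = None,
    series: str = "predicted",
) -> float:
    """Mean first difference of a series over a trial-position range.

    On a complete series this telescopes to (last - first)/(n_bins - 1).
    Missing bins are dropped; differences between surviving neighbours
    are divided by their bin spacing.
    """
    y = getattr(timecourse, series)
    x = np.asarray(timecourse.bins, dtype=float)
    if bin_range is not None:
        lo, hi = bin_range
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(y) < 2:
        raise ValueError("derivative needs at least 2 non-missing bins in range")
    return float(np.mean(np.diff(y) / np.diff(x)))
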