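"""Informational connectivity.

Two regions are "informationally connected" when their trialwise decoding
evidence co-fluctuates: within each sliding window of trial positions
(pooled across blocks), the Pearson correlation between the regions'
raw per-trial evidence is computed, yielding a timecourse of r values.
Learning-related change is tested by a paired t-test of the final
window's r against the first window's r across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .group_stats import GroupTestResult, group_ttest

__all__ = [
    "ConnectivityTimecourse",
    "informational_connectivity",
    "first_vs_last_contrast",
]


@dataclass(frozen=True)
class ConnectivityTimecourse:
    """Windowed inter-ROI correlations of decoding evidence."""

    windows: np.ndarray  # (n_windows, 2) inclusive trial-position spans
    r: np.ndarray
    n_trials: np.ndarray
    roi_pair: tuple[str, str]

    def __post_init__(self) -> None:
        finite = self.r[np.isfinite(self.r)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def first_r(self) -> float:
        return float(self.r[0])

    @property
    def last_r(self) -> float:
        return float(self.r[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.windows[:, 0],
                "window_end": self.windows[:, 1],
                "r": self.r,
                "n_trials": self.n_trials,
            }
        )


def informational_connectivity(
    evidence_a: np.ndarray,
    evidence_b: np.ndarray,
    design: ExperimentDesign,
    window_len: int,
    roi_pair: tuple[str, str] = ("roi_a", "roi_b"),
    valid_filter: bool | None = None,
) -> ConnectivityTimecourse:
    """Windowed Pearson correlation of two ROIs' per-trial evidence.

    Windows follow the evidence-timecourse scheme (starts 1 to
    n_positions - window_len + 1); trials of all blocks whose position
    falls in the window are pooled.  Valid and invalid trials are pooled
    by default; ``valid_filter`` restricts to one condition.  Windows
    with zero variance in either series give a missing r, not zero.
    """
    trials = design.prediction_trials()
    a = np.asarray(evidence_a, dtype=float)
    b = np.asarray(evidence_b, dtype=float)
    if len(a) != len(trials) or len(b) != len(trials):
        raise ValueError("evidence series must cover all prediction trials")
    pos = trials["trial_position"].to_numpy()
    keep = np.ones(len(trials), dtype=bool)
    if valid_filter is not None:
        keep = trials["valid"].to_numpy(bool) == valid_filter
    n_pos = int(pos.max())
    starts = np.arange(1, n_pos - window_len + 2)
    windows = np.column_stack([starts, starts + window_len - 1])
    r = np.full(len(starts), np.nan)
    n_tr = np.zeros(len(starts), dtype=int)
    for i, s in enumerate(starts):
        m = keep & (pos >= s) & (pos <= s + window_len - 1)
        n_tr[i] = int(m.sum())
        if n_tr[i] < 3:
            continue
        ai, bi = a[m], b[m]
        if ai.std() == 0 or bi.std() == 0:
            continue
        r[i] = float(np.corrcoef(ai, bi)[0, 1])
    return ConnectivityTimecourse(windows=windows, r=r, n_trials=n_tr,
                                  roi_pair=roi_pair)


def first_vs_last_contrast(
    timecourses: Sequence[ConnectivityTimecourse],
) -> GroupTestResult:
    """Paired t-test of last-window minus first-window r across
    participants; participants missing either window are dropped with a
    warning."""
    first, last = [], []
    dropped = 0
    for tc in timecourses:
        f, l = tc.first_r, tc.last_r
        if np.isfinite(f) and np.isfinite(l):
            first.append(f)
            last.append(l)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"dropped {dropped} participant(s) with missing first/last window r"
        )
    if len(first) < 2:
        raise ValueError("need >= 2 participants with both windows present")
    diffs = np.asarray(last) - np.asarray(first)
    if np.all(diffs == 0):
        # no change anywhere: the contrast is exactly null
        return GroupTestResult(statistic=0.0, dof=(len(diffs) - 1,),
                               p_value=1.0, direction="none", kind="paired_t")
    return group_ttest(np.asarray(last), paired_with=np.asarray(first))
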