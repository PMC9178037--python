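"""Group-level inference.

Timecourse-wide inference uses non-parametric cluster-based permutation
tests: per-bin one-sample t statistics are thresholded at the two-tailed
p = 0.05 critical value, contiguous same-sign supra-threshold bins are
collected into clusters scored by their summed t, and cluster p-values
come from the maximal cluster statistic over random per-participant sign
flips (the exchangeability-preserving permutation for a one-sample
timecourse test, with familywise control via the max statistic).  Simple
one-sample / paired t and repeated-measures F wrappers cover the scalar
group tests (all two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "GroupTestResult",
    "cluster_permutation_test",
    "group_ttest",
    "repeated_measures_F",
]


@dataclass(frozen=True)
class Cluster:
    start_bin: int  # inclusive, index into the bin axis
    end_bin: int  # inclusive
    sum_t: float
    p_value: float


@dataclass(frozen=True)
class ClusterTestResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    threshold_t: float
    threshold_p: float
    n_permutations: int
    seed: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    dof: tuple[int, ...]
    p_value: float
    direction: str  # "positive" / "negative" / "none"
    kind: str


def _one_sample_t(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise one-sample t against 0, NaN-aware; returns (t, n)."""
    mask = np.isfinite(data)
    n = mask.sum(axis=0)
    x = np.where(mask, data, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x.sum(axis=0) / n
        var = (np.sum(x**2, axis=0) - n * mean**2) / (n - 1)
        t = mean / np.sqrt(var / n)
    t[n < 2] = np.nan
    return t, n


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal runs of same-sign supra-threshold t; NaNs break adjacency."""
    clusters = []
    i, nbins = 0, len(t)
    while i < nbins:
        ti = t[i]
        if not np.isfinite(ti) or abs(ti) <= threshold:
            i += 1
            continue
        sign = np.sign(ti)
        j = i
        total = 0.0
        while j < nbins and np.isfinite(t[j]) and abs(t[j]) > threshold and np.sign(t[j]) == sign:
            total += t[j]
            j += 1
        clusters.append((i, j - 1, total))
        i = j
    return clusters


def _max_cluster_stat(t_matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Per-row maximum |summed t| over clusters, vectorised over rows."""
    n_rows, n_bins = t_matrix.shape
    best = np.zeros(n_rows)
    run_pos = np.zeros(n_rows)
    run_neg = np.zeros(n_rows)
    for b in range(n_bins):
        col = t_matrix[:, b]
        finite = np.isfinite(col)
        col = np.where(finite, col, 0.0)
        pos = finite & (col > threshold)
        neg = finite & (col < -threshold)
        run_pos = np.where(pos, run_pos + col, 0.0)
        run_neg = np.where(neg, run_neg - col, 0.0)
        best = np.maximum(best, np.maximum(run_pos, run_neg))
    return best


def cluster_permutation_test(
    data: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test on participants x bins.

    The cluster-forming threshold is the two-tailed critical t at
    ``alpha_cluster`` for the per-bin df; each of ``n_perm`` permutations
    flips every participant's sign independently (the same flip across
    all bins) and records its maximal absolute cluster sum; observed
    clusters are scored against that null with the add-one rule, so
    p-values lie in [1/(n_perm + 1), 1].
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a participants x bins matrix with N >= 2")
    n_part, n_bins = data.shape
    mask = np.isfinite(data)
    if np.any(mask.sum(axis=0) == 0):
        raise ValueError("all-missing bins are not allowed")
    counts = mask.sum(axis=0)
    df = np.maximum(counts - 1, 1)
    # df varies only where participants have missing bins; use the modal df
    # for a single scalar threshold and guard rare low-count bins via NaN t
    threshold = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, np.median(df)))

    t_obs, _ = _one_sample_t(data)
    obs_clusters = _find_clusters(t_obs, threshold)

    rng = np.random.default_rng(seed)
    x = np.where(mask, data, 0.0)
    ssq = np.sum(x**2, axis=0)  # invariant under sign flips
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_part))
    sums = signs @ x  # (n_perm, bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = (ssq[None, :] - counts[None, :] * means**2) / (counts[None, :] - 1)
        var = np.maximum(var, 0.0)
        t_null = means / np.sqrt(var / counts[None, :])
    t_null[:, counts < 2] = np.nan
    null_max = _max_cluster_stat(t_null, threshold)

    clusters = [
        Cluster(
            start_bin=s,
            end_bin=e,
            sum_t=float(tot),
            p_value=float((np.sum(null_max >= abs(tot)) + 1) / (n_perm + 1)),
        )
        for s, e, tot in obs_clusters
    ]
    return ClusterTestResult(
        clusters=clusters, t_values=t_obs, threshold_t=threshold,
        threshold_p=alpha_cluster, n_permutations=n_perm, seed=seed,
    )


def group_ttest(values, paired_with=None, popmean: float = 0.0) -> GroupTestResult:
    """Two-sided one-sample (or paired) t-test with df = N - 1."""
    a = np.asarray(values, dtype=float)
    if paired_with is not None:
        a = a - np.asarray(paired_with, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 2:
        raise ValueError("need at least 2 participants")
    if np.std(a, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(a, popmean)
    direction = "none"
    if res.pvalue < 1:
        direction = "positive" if res.statistic > 0 else "negative"
    return GroupTestResult(
        statistic=float(res.statistic), dof=(len(a) - 1,),
        p_value=float(res.pvalue), direction=direction,
        kind="paired_t" if paired_with is not None else "one_sample_t",
    )


def repeated_measures_F(data: np.ndarray) -> GroupTestResult:
    """One-way repeated-measures F on a participants x levels matrix.

    Classical decomposition with the subject effect removed:
    F(levels - 1, (levels - 1)(N - 1)) = MS_condition / MS_error.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need N >= 2 participants and >= 2 levels")
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise ValueError("zero error variance: F statistic undefined")
    f = (ss_cond / df1) / ms_err
    return GroupTestResult(
        statistic=float(f), dof=(df1, df2),
        p_value=float(stats.f.sf(f, df1, df2)),
        direction="none", kind="repeated_measures_F",
    )
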