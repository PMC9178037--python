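"""Self-validation suites: oracle recoveries and Monte-Carlo calibration.

Each function here runs a slice of the pipeline under known ground truth
and summarises how well it is recovered: exact design structure, the
noiseless encoding-model round trip, single-trial beta recovery, sigmoid
parameter recovery, familywise error calibration of the cluster
permutation test, and the statistical power of the end-to-end
representational-switch and connectivity analyses on synthetic groups.
They back both the acceptance script and the heavier integration tests.
"""

from __future__ import annotations

import numpy as np

from . import design as design_mod
from . import group_stats
from . import iem_decoder as iem
from . import learning_curves as lc
from . import synthetic_data as synth
from .connectivity import first_vs_last_contrast, informational_connectivity
from .evidence_timecourse import smooth, windowed_evidence
from .lss_glm import lss_estimate
from .pipeline import RunConfig, decode_participant, derive_seed

__all__ = [
    "design_structure_summary",
    "iem_roundtrip_error",
    "lss_recovery_error",
    "sigmoid_recovery",
    "cluster_fwer",
    "exhaustive_permutation_gap",
    "switch_recovery_rate",
    "connectivity_power",
]


def design_structure_summary(seed: int = 0) -> dict:
    """Marginal structure of freshly generated designs (percentages)."""
    d1 = design_mod.generate_design(1, seed)
    d2 = design_mod.generate_design(2, derive_seed(seed, "d2"))
    so = design_mod.generate_design("shape_only", derive_seed(seed, "so"))
    t1, t2 = d1.trials, d2.trials
    shape_counts = so.trials["presented_shape"].value_counts()
    return {
        "exp1_valid_pct": 100.0 * t1["valid"].mean(),
        "exp1_same_pct": 100.0 * (t1["same_different"] == "same").mean(),
        "exp2_valid_pct": 100.0 * t2["valid"].mean(),
        "exp1_trials_per_block": int(t1.groupby("block").size().iloc[0]),
        "exp2_trials_per_block": int(t2.groupby("block").size().iloc[0]),
        "shape_only_n_trials": int(len(so.trials)),
        "shape_only_shape_pct": 100.0 * shape_counts.max() / len(so.trials),
    }


def iem_roundtrip_error(seed: int = 0, n_voxels: int = 60) -> float:
    """Max absolute error of the noiseless weight + channel round trip."""
    basis = iem.ChannelBasis()
    rng = np.random.default_rng(seed)
    w_true = rng.standard_normal((n_voxels, basis.n_channels))
    shapes = np.repeat(np.arange(1, 6), 2)
    train = np.stack([w_true @ iem.channel_vector(basis, int(s)) for s in shapes])
    w_hat = iem.fit_weights(train, shapes, basis)
    err_w = np.abs(w_hat.weights - w_true).max()
    c = iem.channel_vector(basis, 3)
    rec = iem.reconstruct_channels(w_hat, (w_true @ c)[None, :])
    return float(max(err_w, np.abs(rec[0] - c).max()))


def lss_recovery_error(seed: int = 0, n_trials: int = 8, n_voxels: int = 4) -> float:
    """Max |beta error| for noiseless BOLD with non-overlapping events."""
    rng = np.random.default_rng(seed)
    onsets = np.arange(n_trials) * 35.0
    betas = rng.standard_normal((n_trials, n_voxels))
    bold = synth.simulate_bold(betas, onsets, noise_sd=0.0)
    est = lss_estimate(bold)
    return float(np.abs(est - betas).max())


def sigmoid_recovery(seed: int = 0) -> dict:
    """Noiseless single- and double-sigmoid parameter recovery."""
    x1 = np.arange(1, 30, dtype=float)
    truth1 = (-0.2, 0.3, 20.0)
    y1 = lc.sigmoid(x1, *truth1)
    f1 = lc.fit_single_sigmoid(y1, x1, midpoint_bounds=(1.0, 32.0),
                               n_starts=100, seed=seed)
    x2 = np.arange(1, 114, dtype=float)
    truth2 = ((-0.15, 0.2, 40.0), (0.2, 0.2, 96.0))
    y2 = lc.sigmoid(x2, *truth2[0]) + lc.sigmoid(x2, *truth2[1])
    f2 = lc.fit_double_sigmoid(y2, x2, half_split=64,
                               midpoint_bounds_early=(1.0, 64.0),
                               midpoint_bounds_late=(65.0, 128.0),
                               n_starts=100, seed=seed)
    return {
        "single_amplitude_error": abs(f1.amplitude - truth1[0]),
        "single_midpoint_error": abs(f1.midpoint - truth1[2]),
        "double_early_amplitude_error": abs(f2.early.amplitude - truth2[0][0]),
        "double_late_amplitude_error": abs(f2.late.amplitude - truth2[1][0]),
    }


def cluster_fwer(n_datasets: int = 500, n_participants: int = 24,
                 n_bins: int = 29, n_perm: int = 10_000, seed: int = 0) -> float:
    """Familywise false-positive rate of the cluster test on pure-noise
    participant x bin data at nominal alpha = 0.05."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_datasets):
        data = rng.standard_normal((n_participants, n_bins))
        res = group_stats.cluster_permutation_test(
            data, n_perm=n_perm, seed=derive_seed(seed, "fwer", i)
        )
        hits += any(c.p_value < 0.05 for c in res.clusters)
    return hits / n_datasets


def exhaustive_permutation_gap(seed: int = 0, n_perm: int = 10_000) -> float:
    """Largest |Monte-Carlo p - exhaustive p| over the observed clusters
    for an N = 8, 5-bin dataset (all 2^8 sign flips enumerated)."""
    import itertools

    rng = np.random.default_rng(seed)
    data = rng.standard_normal((8, 5)) + 0.8
    res = group_stats.cluster_permutation_test(data, n_perm=n_perm,
                                               seed=derive_seed(seed, "mc"))
    null = []
    for signs in itertools.product((-1.0, 1.0), repeat=8):
        flipped = np.asarray(signs)[:, None] * data
        t, _ = group_stats._one_sample_t(flipped)
        null.append(group_stats._max_cluster_stat(t[None, :], res.threshold_t)[0])
    null = np.asarray(null)
    gaps = [
        abs(c.p_value - float(np.mean(null >= abs(c.sum_t))))
        for c in res.clusters
    ]
    return max(gaps) if gaps else 0.0


def _group_amplitudes(config: RunConfig, group_seed: int,
                      n_starts: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant early/late double-sigmoid amplitudes for one
    simulated group run end to end (design -> simulate -> decode ->
    timecourse -> double fit)."""
    early, late = [], []
    n_pos = config.half_split * 2
    for p in range(config.n_participants):
        d = design_mod.generate_design(config.experiment,
                                       derive_seed(group_seed, "design", p))
        dyn = config.make_dynamics(d.trials_per_block)
        part = synth.simulate_participant(
            d, dyn, noise_sd=config.noise_sd, n_voxels=config.n_voxels,
            n_informative=config.n_informative,
            seed=derive_seed(group_seed, "sim", p),
        )
        trials = decode_participant(part, config)
        tc = smooth(
            windowed_evidence(trials["evidence"].to_numpy(), d, config.window_len),
            config.smooth_halfwidth,
        )
        fit = lc.fit_double_sigmoid(
            tc, half_split=config.half_split,
            midpoint_bounds_early=(1.0, float(config.half_split)),
            midpoint_bounds_late=(float(config.half_split) + 1, float(n_pos)),
            n_starts=n_starts, seed=derive_seed(group_seed, "fit", p),
        )
        early.append(fit.early.amplitude)
        late.append(fit.late.amplitude)
    return np.asarray(early), np.asarray(late)


def switch_recovery_rate(n_groups: int = 50, n_participants: int = 24,
                         seed: int = 0, n_starts: int = 20) -> float:
    """Fraction of simulated groups in which the full pipeline finds the
    representational switch: group early amplitude significantly negative
    AND late amplitude significantly positive (two-sided p < 0.05)."""
    config = RunConfig(experiment="2", n_participants=n_participants, seed=seed)
    hits = 0
    for g in range(n_groups):
        early, late = _group_amplitudes(config, derive_seed(seed, "group", g),
                                        n_starts)
        t_early = group_stats.group_ttest(early)
        t_late = group_stats.group_ttest(late)
        hits += (
            t_early.p_value < 0.05 and t_early.statistic < 0
            and t_late.p_value < 0.05 and t_late.statistic > 0
        )
    return hits / n_groups


def connectivity_power(n_groups: int = 200, n_participants: int = 24,
                       seed: int = 0, n_voxels: int = 100,
                       n_informative: int = 50) -> float:
    """Power of the last-minus-first-window connectivity contrast when a
    shared latent signal couples two ROIs late in the blocks."""
    config = RunConfig(experiment="2", voxel_selection=False,
                       n_voxels=n_voxels, n_informative=n_informative)
    hits = 0
    for g in range(n_groups):
        gseed = derive_seed(seed, "conn", g)
        tcs = []
        for p in range(n_participants):
            d = design_mod.generate_design("2", derive_seed(gseed, "design", p))
            part_a, part_b = synth.simulate_roi_pair(
                d, config.make_dynamics(d.trials_per_block),
                coupling_amplitude=config.coupling_amplitude,
                noise_sd=config.noise_sd, n_voxels=n_voxels,
                n_informative=n_informative,
                seed=derive_seed(gseed, "pair", p),
            )
            ev_a = decode_participant(part_a, config)["evidence"].to_numpy()
            ev_b = decode_participant(part_b, config)["evidence"].to_numpy()
            tcs.append(informational_connectivity(ev_a, ev_b, d,
                                                  config.window_len))
        res = first_vs_last_contrast(tcs)
        hits += res.p_value < 0.05 and res.statistic > 0
    return hits / n_groups
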