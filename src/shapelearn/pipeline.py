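"""Configuration and end-to-end orchestration.

A :class:`RunConfig` gathers every tunable of the analysis — experiment
id, generator dynamics, decoder settings, window/smoothing lengths, fit
bounds and stats parameters — under a single master seed from which every
stochastic stage derives its own seed deterministically.  ``run_pipeline``
executes design -> simulate -> (optional LSS) -> decode -> timecourse ->
fit -> stats -> connectivity, writing each stage's outputs (TSV tables,
array containers with JSON sidecars, JSON reports) into a run directory;
rerunning with the same config reproduces every file bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import design as design_mod
from . import evidence_timecourse as evt
from . import group_stats
from . import iem_decoder as iem
from . import learning_curves as lc
from . import synthetic_data as synth

logger = logging.getLogger("shapelearn")

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "save_patterns", "load_patterns"]

#: analysis defaults per experiment: (window_len, smooth_halfwidth, half_split)
EXPERIMENT_WINDOWS = {"1": (4, 4, 16), "2": (16, 16, 64)}


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic per-stage seed (< 2**31) from the master seed."""
    mix = zlib.crc32("/".join(str(t) for t in tokens).encode())
    return int(np.random.SeedSequence([int(master_seed), mix]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, serialisable to YAML."""

    experiment: str = "2"
    n_participants: int = 24
    roi_labels: tuple[str, ...] = ("hippocampus",)
    connectivity_pair: tuple[str, str] | None = None
    # generator
    dynamics: dict = field(default_factory=dict)  # GroundTruthDynamics overrides
    noise_sd: float = 4.0
    n_voxels: int = 200
    n_informative: int = 100
    coupling_amplitude: float = 0.5
    run_lss: bool = False
    # decoder
    n_channels: int = 5
    basis_exponent: int = 5
    voxel_selection: bool = True
    # timecourse (None -> experiment defaults)
    window_len: int | None = None
    smooth_halfwidth: int | None = None
    # fits
    n_starts: int = 100
    # stats
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.experiment = str(self.experiment)
        if self.experiment not in EXPERIMENT_WINDOWS:
            raise ValueError("experiment must be '1' or '2'")
        self.roi_labels = tuple(self.roi_labels)
        if self.connectivity_pair is not None:
            self.connectivity_pair = tuple(self.connectivity_pair)
        w, s, _ = EXPERIMENT_WINDOWS[self.experiment]
        if self.window_len is None:
            self.window_len = w
        if self.smooth_halfwidth is None:
            self.smooth_halfwidth = s

    @property
    def half_split(self) -> int:
        return EXPERIMENT_WINDOWS[self.experiment][2]

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["roi_labels"] = list(self.roi_labels)
        if self.connectivity_pair is not None:
            payload["connectivity_pair"] = list(self.connectivity_pair)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def basis(self) -> iem.ChannelBasis:
        return iem.ChannelBasis(n_channels=self.n_channels, exponent=self.basis_exponent)

    def make_dynamics(self, n_positions: int) -> synth.GroundTruthDynamics:
        return synth.GroundTruthDynamics.for_positions(n_positions, **self.dynamics)


# ---------------------------------------------------------------------------
# array container I/O (binary array + JSON sidecar)
# ---------------------------------------------------------------------------

def save_patterns(path: Path, pattern_set: synth.VoxelPatternSet, meta: dict) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), patterns=pattern_set.patterns)
    pattern_set.labels.to_csv(path.with_suffix(".labels.tsv"), sep="\t", index=False)
    sidecar = {"roi_label": pattern_set.roi_label, **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_patterns(path: Path) -> synth.VoxelPatternSet:
    path = Path(path)
    patterns = np.load(path.with_suffix(".npz"))["patterns"]
    labels = pd.read_csv(path.with_suffix(".labels.tsv"), sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return synth.VoxelPatternSet(patterns=patterns, labels=labels,
                                 roi_label=sidecar["roi_label"])


def _provenance_header(config: RunConfig, stage: str, seed: int) -> str:
    return (f"# config_hash={config.config_hash}\n"
            f"# stage={stage}\n# seed={seed}\n")


def _write_tsv(path: Path, frame: pd.DataFrame, config: RunConfig, stage: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, stage, seed))
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_design(config: RunConfig, run_dir: Path) -> list[design_mod.ExperimentDesign]:
    out = run_dir / "designs"
    out.mkdir(parents=True, exist_ok=True)
    designs = []
    for p in range(config.n_participants):
        seed = derive_seed(config.seed, "design", p)
        d = design_mod.generate_design(config.experiment, seed)
        design_mod.write_events(d, out / f"sub-{p:02d}_events.tsv")
        designs.append(d)
    logger.info("design: %d participants, %d trials each",
                len(designs), len(designs[0].trials))
    return designs


def stage_simulate(config: RunConfig, run_dir: Path,
                   designs: list[design_mod.ExperimentDesign]) -> dict:
    out = run_dir / "patterns"
    out.mkdir(parents=True, exist_ok=True)
    participants: dict[tuple[int, str], synth.SyntheticParticipant] = {}
    for p, d in enumerate(designs):
        dyn = config.make_dynamics(d.trials_per_block)
        for roi in config.roi_labels:
            seed = derive_seed(config.seed, "simulate", p, roi)
            part = synth.simulate_participant(
                d, dyn, noise_sd=config.noise_sd, n_voxels=config.n_voxels,
                n_informative=config.n_informative, seed=seed, roi_label=roi,
                basis=config.basis(),
            )
            participants[(p, roi)] = part
            meta = {"participant": p, "seed": seed, "config_hash": config.config_hash}
            save_patterns(out / f"sub-{p:02d}_{roi}_test", part.test_patterns, meta)
            for r, ps in enumerate(part.train_patterns):
                save_patterns(out / f"sub-{p:02d}_{roi}_train{r + 1}", ps, meta)
    logger.info("simulate: %d participant-ROI datasets", len(participants))
    return participants


def decode_participant(part: synth.SyntheticParticipant, config: RunConfig) -> pd.DataFrame:
    """Voxel selection, weight fitting and per-trial evidence for one
    participant-ROI; returns the test-trial table with an ``evidence``
    column."""
    basis = config.basis()
    (run_a, run_b) = part.train_patterns
    a_shapes = run_a.labels["presented_shape"].to_numpy()
    b_shapes = run_b.labels["presented_shape"].to_numpy()
    if config.voxel_selection:
        voxels, fraction = iem.select_voxels(
            run_a.patterns, a_shapes, run_b.patterns, b_shapes, basis
        )
    else:
        voxels = np.arange(part.test_patterns.n_voxels)
        fraction = 1.0
    train_patterns = np.vstack([run_a.patterns, run_b.patterns])[:, voxels]
    train_shapes = np.concatenate([a_shapes, b_shapes])
    weights = iem.fit_weights(train_patterns, train_shapes, basis,
                              trained_on="shape_only_runs_1+2")
    trials = part.test_patterns.labels.copy()
    pres = trials["presented_shape"].to_numpy(int)
    alt = np.where(pres == 2, 4, 2)
    trials["evidence"] = iem.evidence_per_trial(
        weights, part.test_patterns.patterns[:, voxels], pres, alt, basis
    )
    trials.attrs["selected_fraction"] = fraction
    trials.attrs["n_selected_voxels"] = len(voxels)
    return trials


def stage_decode(config: RunConfig, run_dir: Path, participants: dict) -> dict:
    out = run_dir / "evidence"
    out.mkdir(parents=True, exist_ok=True)
    evidence: dict[tuple[int, str], pd.DataFrame] = {}
    for (p, roi), part in participants.items():
        trials = decode_participant(part, config)
        evidence[(p, roi)] = trials
        _write_tsv(out / f"sub-{p:02d}_{roi}_evidence.tsv", trials, config,
                   "decode", part.seed)
    logger.info("decode: %d evidence tables", len(evidence))
    return evidence


def stage_timecourse(config: RunConfig, run_dir: Path,
                     designs: list, evidence: dict) -> dict:
    out = run_dir / "timecourses"
    out.mkdir(parents=True, exist_ok=True)
    timecourses: dict[tuple[int, str], evt.EvidenceTimecourse] = {}
    for (p, roi), trials in evidence.items():
        tc = evt.windowed_evidence(trials["evidence"].to_numpy(), designs[p],
                                   config.window_len)
        tc = evt.smooth(tc, config.smooth_halfwidth)
        timecourses[(p, roi)] = tc
        _write_tsv(out / f"sub-{p:02d}_{roi}_timecourse.tsv", tc.to_frame(),
                   config, "timecourse", config.seed)
    logger.info("timecourse: %d series (%d bins)", len(timecourses),
                len(next(iter(timecourses.values())).bins))
    return timecourses


def stage_fit(config: RunConfig, run_dir: Path, timecourses: dict) -> pd.DataFrame:
    n_pos = EXPERIMENT_WINDOWS[config.experiment][2] * 2
    rows = []
    for (p, roi), tc in timecourses.items():
        seed = derive_seed(config.seed, "fit", p, roi)
        single = lc.fit_single_sigmoid(
            tc, midpoint_bounds=(1.0, float(n_pos)),
            n_starts=config.n_starts, seed=seed,
        )
        double = lc.fit_double_sigmoid(
            tc, half_split=config.half_split,
            midpoint_bounds_early=(1.0, float(config.half_split)),
            midpoint_bounds_late=(float(config.half_split) + 1, float(n_pos)),
            n_starts=config.n_starts, seed=seed,
        )
        rows.append({
            "participant": p, "roi": roi, "model": "single",
            "amplitude": single.amplitude, "slope": single.slope,
            "midpoint": single.midpoint, "sse": single.sse,
            "n_starts": config.n_starts, "seed": seed,
        })
        rows.append({
            "participant": p, "roi": roi, "model": "double",
            "amplitude_early": double.early.amplitude,
            "slope_early": double.early.slope,
            "midpoint_early": double.early.midpoint,
            "amplitude_late": double.late.amplitude,
            "slope_late": double.late.slope,
            "midpoint_late": double.late.midpoint,
            "sse": double.sse, "n_starts": config.n_starts, "seed": seed,
        })
    fits = pd.DataFrame(rows)
    _write_tsv(run_dir / "fits.tsv", fits, config, "fit", config.seed)
    logger.info("fit: %d rows", len(fits))
    return fits


def stage_stats(config: RunConfig, run_dir: Path, timecourses: dict,
                fits: pd.DataFrame) -> dict:
    results: dict = {"config_hash": config.config_hash, "rois": {}}
    for roi in config.roi_labels:
        matrix = np.vstack([
            timecourses[(p, roi)].predicted
            for p in range(config.n_participants)
        ])
        seed = derive_seed(config.seed, "stats", roi)
        ct = group_stats.cluster_permutation_test(
            matrix, alpha_cluster=config.alpha, n_perm=config.n_perm, seed=seed
        )
        bins = timecourses[(0, roi)].bins
        roi_res = {
            "cluster_test": {
                "threshold_t": ct.threshold_t,
                "n_permutations": ct.n_permutations,
                "seed": seed,
                "clusters": [
                    {
                        "start_bin": int(c.start_bin),
                        "end_bin": int(c.end_bin),
                        "start_trial": int(bins[c.start_bin]),
                        "end_trial": int(bins[c.end_bin]) + config.window_len - 1,
                        "sum_t": c.sum_t,
                        "p_value": c.p_value,
                    }
                    for c in ct.clusters
                ],
            }
        }
        froi = fits[fits["roi"] == roi]
        single_amp = froi.loc[froi["model"] == "single", "amplitude"].to_numpy()
        dbl = froi[froi["model"] == "double"]
        for name, vals in (
            ("single_amplitude", single_amp),
            ("early_amplitude", dbl["amplitude_early"].to_numpy()),
            ("late_amplitude", dbl["amplitude_late"].to_numpy()),
        ):
            t = group_stats.group_ttest(vals)
            roi_res[name] = {
                "mean": float(np.mean(vals)), "t": t.statistic,
                "df": t.dof[0], "p": t.p_value,
            }
        results["rois"][roi] = roi_res
    (run_dir / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    logger.info("stats: %d ROIs", len(results["rois"]))
    return results


def stage_connectivity(config: RunConfig, run_dir: Path,
                       designs: list) -> dict | None:
    if config.connectivity_pair is None:
        return None
    out = run_dir / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    tcs = []
    for p, d in enumerate(designs):
        seed = derive_seed(config.seed, "connectivity", p)
        part_a, part_b = synth.simulate_roi_pair(
            d, config.make_dynamics(d.trials_per_block),
            coupling_amplitude=config.coupling_amplitude,
            noise_sd=config.noise_sd, n_voxels=config.n_voxels,
            n_informative=config.n_informative, seed=seed,
            roi_labels=config.connectivity_pair,
        )
        ev_a = decode_participant(part_a, config)["evidence"].to_numpy()
        ev_b = decode_participant(part_b, config)["evidence"].to_numpy()
        tc = conn.informational_connectivity(
            ev_a, ev_b, d, config.window_len, roi_pair=config.connectivity_pair
        )
        tcs.append(tc)
        _write_tsv(out / f"sub-{p:02d}_connectivity.tsv", tc.to_frame(),
                   config, "connectivity", seed)
    contrast = conn.first_vs_last_contrast(tcs)
    result = {
        "roi_pair": list(config.connectivity_pair),
        "mean_first_r": float(np.nanmean([tc.first_r for tc in tcs])),
        "mean_last_r": float(np.nanmean([tc.last_r for tc in tcs])),
        "last_minus_first_t": contrast.statistic,
        "df": contrast.dof[0],
        "p": contrast.p_value,
    }
    (run_dir / "connectivity.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    logger.info("connectivity: t(%d)=%.2f", contrast.dof[0], contrast.statistic)
    return result


def run_pipeline(config: RunConfig, run_dir) -> dict:
    """Execute every stage; returns the stats (and connectivity) results."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stage = "design"
        designs = stage_design(config, run_dir)
        stage = "simulate"
        participants = stage_simulate(config, run_dir, designs)
        stage = "decode"
        evidence = stage_decode(config, run_dir, participants)
        stage = "timecourse"
        timecourses = stage_timecourse(config, run_dir, designs, evidence)
        stage = "fit"
        fits = stage_fit(config, run_dir, timecourses)
        stage = "stats"
        stats_results = stage_stats(config, run_dir, timecourses, fits)
        stage = "connectivity"
        conn_results = stage_connectivity(config, run_dir, designs)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
    if conn_results is not None:
        stats_results["connectivity"] = conn_results
    return stats_results
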