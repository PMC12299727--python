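"""End-to-end experiment: simulate -> preprocess -> marker truth (M1) ->
train/detect (M2) -> cycle parameters -> quality filter -> agreement
report, reproducible from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, cycles, marker_events, prep
from .agreement import AgreementAnalysis, AgreementResults
from .detector import ModelSpec, SplitPlan, WindowClassifier, detect_trial_events, split_by_subject
from .prep import STREAMS, FilterSpec
from .simulate import SimulationConfig, SyntheticTrial, generate_cohort

log = logging.getLogger(__name__)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    """All stage parameters; one master seed drives every stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_length: float = 0.200
    hop: float = 0.100
    detect_hop: float = 0.020  # finer inference hop; see docs/methods.md
    label_band: tuple[float, float] = (0.45, 0.55)
    model: ModelSpec = field(default_factory=ModelSpec)
    split_fraction: float = 0.8
    stride_bounds: tuple[float, float] = (0.4, 2.5)
    threshold: float = 0.5
    refractory: float = 0.4
    n_boot: int = 1000
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return _stage_seed(self.seed, stage)


def validate_config(raw: dict | None) -> ExperimentConfig:
    """Build a normalized config from a (possibly partial) plain dict.

    Unknown keys, an inverted label band or a cutoff at/above Nyquist are
    reported together in one error.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    kw: dict = {}
    nested = {"simulation": SimulationConfig, "filter": FilterSpec, "model": ModelSpec}
    for key, cls in nested.items():
        sub = raw.pop(key, {})
        try:
            if isinstance(sub, dict):
                for k in ("speeds", "placements", "conv_channels"):
                    if k in sub:
                        sub[k] = tuple(sub[k])
                kw[key] = cls(**sub)
            else:
                kw[key] = sub
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key, val in raw.items():
        if key not in known:
            errors.append(f"unknown key {key!r}")
        else:
            kw[key] = tuple(val) if key in ("label_band", "stride_bounds") else val
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = ExperimentConfig(**kw)
    lo, hi = cfg.label_band
    if not 0.0 <= lo < hi <= 1.0:
        errors.append(f"label_band {cfg.label_band} inverted or out of [0, 1]")
    if cfg.filter.cutoff >= 100.0 / 2.0:
        errors.append(f"filter cutoff {cfg.filter.cutoff} Hz >= Nyquist at 100 Hz")
    if not 0.0 < cfg.split_fraction < 1.0:
        errors.append(f"split_fraction {cfg.split_fraction} leaves an empty partition")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


@dataclass
class ExperimentRun:
    """Everything an experiment produced, for inspection and persistence."""

    config: ExperimentConfig
    manifest: pd.DataFrame
    split: SplitPlan
    m1_cycles: pd.DataFrame
    m2_cycles: pd.DataFrame
    paired: pd.DataFrame
    exclusions: dict[str, dict[str, int]]
    results: AgreementResults
    detectors: dict


def _trial_cycles(events: pd.DataFrame, trial: SyntheticTrial,
                  stride_bounds: tuple[float, float]) -> tuple[pd.DataFrame, dict]:
    cyc = cycles.compute_cycles(events, trial.trial_id)
    cyc, tally = cycles.filter_cycles(cyc, trial.transitions, stride_bounds)
    cyc["trial_id"] = trial.trial_id
    return cyc, tally


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentRun:
    """Execute the full pipeline; persist intermediates when out_dir given."""
    sim_cfg = dataclasses.replace(config.simulation,
                                  seed=config.stage_seed("simulate"))
    log.info("simulating cohort: %d subjects x %d speeds x %d placements",
             sim_cfg.n_subjects, len(sim_cfg.speeds), len(sim_cfg.placements))
    trials, manifest = generate_cohort(sim_cfg)
    by_id = {t.trial_id: t for t in trials}

    log.info("preprocessing and labeling %d trials", len(trials))
    datasets = {}
    series = {}
    m1_frames = []
    excl_m1: dict[str, int] = {}
    for trial in trials:
        t, x, _ = prep.preprocess_series(trial.imu, config.filter)
        series[trial.trial_id] = (t, x)
        ds = prep.segment_windows(t, x, trial.trial_id,
                                  config.window_length, config.hop)
        ev = marker_events.extract_marker_events(trial.markers, config.filter)
        prep.label_windows(ds, ev, config.label_band)
        datasets[trial.trial_id] = ds
        cyc, tally = _trial_cycles(ev, trial, config.stride_bounds)
        m1_frames.append(cyc)
        for k, v in tally.items():
            excl_m1[k] = excl_m1.get(k, 0) + v
    m1_cycles = pd.concat(m1_frames, ignore_index=True)

    split = split_by_subject(manifest, config.split_fraction,
                             config.stage_seed("split"))
    log.info("split: train=%s test=%s", split.train_subjects, split.test_subjects)
    train_ids = manifest.loc[manifest["subject"].isin(split.train_subjects),
                             "trial_id"]
    train_sets = [datasets[tid] for tid in train_ids]

    detectors = {}
    model_seed = config.stage_seed("model")
    for i, stream in enumerate(STREAMS):
        spec = dataclasses.replace(config.model, seed=model_seed + i)
        model = WindowClassifier.from_datasets(train_sets, stream, spec)
        detectors[stream] = model.fit()
        log.info("trained %s: %s", stream,
                 detectors[stream].report.epoch_loss[-1:])

    log.info("detecting events on %d test subjects", len(split.test_subjects))
    test_ids = manifest.loc[manifest["subject"].isin(split.test_subjects),
                            "trial_id"]
    m2_frames = []
    paired_frames = []
    excl_m2: dict[str, int] = {}
    for tid in test_ids:
        trial = by_id[tid]
        t, x = series[tid]
        dense = prep.segment_windows(t, x, tid, config.window_length,
                                     config.detect_hop)
        ev2 = detect_trial_events(detectors, dense,
                                  config.threshold, config.refractory)
        cyc2, tally = _trial_cycles(ev2, trial, config.stride_bounds)
        m2_frames.append(cyc2)
        for k, v in tally.items():
            excl_m2[k] = excl_m2.get(k, 0) + v
        cyc1 = m1_cycles[m1_cycles["trial_id"] == tid]
        pair, dropped = agreement.match_cycles(cyc1, cyc2)
        if dropped:
            log.info("trial %s: %d unmatched cycles", tid, dropped)
        if not pair.empty:
            meta = manifest.set_index("trial_id").loc[tid]
            pair = pair.assign(trial_id=tid, subject=meta["subject"],
                               speed=meta["speed"], placement=meta["placement"])
            paired_frames.append(pair)
    m2_cycles = pd.concat(m2_frames, ignore_index=True)
    paired = pd.concat(paired_frames, ignore_index=True)

    results = AgreementAnalysis(paired).fit(n_boot=config.n_boot,
                                            seed=config.stage_seed("stats"))
    run = ExperimentRun(config, manifest, split, m1_cycles, m2_cycles, paired,
                        {"m1": excl_m1, "m2": excl_m2}, results, detectors)
    if out_dir is not None:
        _persist(run, Path(out_dir))
    return run


def _persist(run: ExperimentRun, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    run.manifest.to_csv(out / "manifest.csv", index=False)
    run.m1_cycles.to_csv(out / "cycles_m1.csv", index=False, float_format="%.6f")
    run.m2_cycles.to_csv(out / "cycles_m2.csv", index=False, float_format="%.6f")
    run.paired.to_csv(out / "paired_cycles.csv", index=False, float_format="%.6f")
    run.results.save_tables(out)
    meta = {
        "seed": run.config.seed,
        "stage_seeds": {s: run.config.stage_seed(s)
                        for s in ("simulate", "split", "model", "stats")},
        "train_subjects": list(run.split.train_subjects),
        "test_subjects": list(run.split.test_subjects),
        "exclusions": run.exclusions,
    }
    (out / "run_manifest.json").write_text(json.dumps(meta, indent=2))
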