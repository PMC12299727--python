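"""Synthetic treadmill-gait cohort generator.

Produces, for each subject x speed x placement cell, a trial containing

* a six-channel IMU record (3-axis acceleration in g, 3-axis angular rate
  in deg/s) sampled at 1259 Hz, emulating a smartphone-sized sensor carried
  loosely in the hand, trouser pocket or jacket pocket;
* bilateral vertical marker trajectories (calcaneus and first metatarsal,
  mm, 100 Hz) whose local minima coincide with the true heel strikes and
  toe-offs;
* the exact ground-truth event schedule and per-cycle temporal parameters.

The event schedule is built first (alternating heel strikes and toe-offs
per side, with per-subject stride time, stance fraction and left/right
phase asymmetry, plus per-cycle stride jitter); markers and IMU channels
are then rendered from that schedule, so every downstream stage can be
validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PLACEMENTS = ("hand", "trouser", "jacket")

#: Placement-dependent signal model: transient attenuation (loose coupling
#: damps the impact), broadband accelerometer noise (g), mechanical delay
#: jitter between the skeletal event and the sensed transient (s), and the
#: amplitude of the low-frequency pendulum artifact of a swinging jacket (g).
PLACEMENT_EFFECTS = {
    "hand": {"atten": 1.00, "noise_g": 0.02, "delay_sd": 0.004, "pendulum_g": 0.0},
    "trouser": {"atten": 0.85, "noise_g": 0.055, "delay_sd": 0.007, "pendulum_g": 0.0},
    "jacket": {"atten": 0.60, "noise_g": 0.08, "delay_sd": 0.015, "pendulum_g": 0.25},
}

IMU_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
MARKER_COLUMNS = ["t", "calc_L_z", "calc_R_z", "meta_L_z", "meta_R_z"]

# Marker waveform geometry (mm / fraction of swing). The swing bump apex is
# the "foot motion peak"; placing it at 57.6% of swing puts the next heel
# strike at ~18% and the next toe-off at ~76% of the apex-to-apex interval,
# inside the 0-30% and 40-80% search bands with margin for stride jitter.
CALC_BASE_MM = 40.0
CALC_BUMP_MM = 110.0
META_BASE_MM = 25.0
META_BUMP_MM = 60.0
DIP_DEPTH_MM = 6.0
DIP_HALFWIDTH_S = 0.05
DIP_CLEARANCE_S = 0.07  # swing bump ends this far before the next dip
SWING_APEX_FRACTION = 0.576

# IMU transient shape: a low-frequency deceleration pulse (survives the
# 10 Hz low-pass used downstream) plus a damped high-frequency impact burst.
HS_PULSE_HALFWIDTH_S = 0.055
TO_PULSE_HALFWIDTH_S = 0.075
TO_AMPLITUDE_SCALE = 0.55
BURST_FREQ_HZ = 18.0
BURST_DECAY_S = 0.05


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait parameters (invariant across speeds and placements)."""

    subject_id: str
    base_stride_time: float  # s, referenced to 1.25 m/s
    stance_fraction: float  # of cycle, in (0.5, 0.7)
    double_support_fraction: float  # of cycle
    stride_cv: float  # per-cycle stride-time coefficient of variation
    impact_amplitude: float  # g, heel-strike transient at the source
    asymmetry_ratio: float  # right/left phase multiplier, near 1

    def __post_init__(self) -> None:
        if not 0.8 <= self.base_stride_time <= 1.6:
            raise ValueError(f"base_stride_time {self.base_stride_time} outside [0.8, 1.6] s")
        if not 0.5 < self.stance_fraction < 0.7:
            raise ValueError(f"stance_fraction {self.stance_fraction} outside (0.5, 0.7)")
        if not 0.05 < self.double_support_fraction < 0.2:
            raise ValueError("double_support_fraction outside (0.05, 0.2)")
        if self.double_support_fraction > 2.0 * (self.stance_fraction - 0.5) + 1e-9:
            raise ValueError("double support incompatible with stance fraction")


@dataclass
class SimulationConfig:
    """Cohort-level design: factors, sampling rates and noise levels."""

    n_subjects: int = 10
    speeds: tuple[float, ...] = (1.0, 1.25, 1.5)
    placements: tuple[str, ...] = PLACEMENTS
    trial_duration: float = 90.0  # s
    fs_imu: float = 1259.0  # Hz
    fs_mocap: float = 100.0  # Hz
    marker_noise_mm: float = 0.5
    placement_noise: dict[str, float] = field(
        default_factory=lambda: {p: PLACEMENT_EFFECTS[p]["noise_g"] for p in PLACEMENTS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 10.0 <= self.trial_duration <= 600.0:
            raise ValueError("trial_duration outside supported range [10, 600] s")
        if self.fs_imu <= 0 or self.fs_mocap <= 0:
            raise ValueError("sampling rates must be positive")
        unknown = set(self.placements) - set(PLACEMENTS)
        if unknown:
            raise ValueError(f"unknown placements: {sorted(unknown)}")


@dataclass
class SyntheticTrial:
    """One recording: IMU + markers + exact ground truth."""

    trial_id: str
    subject_id: str
    speed: float
    placement: str
    imu: pd.DataFrame  # IMU_COLUMNS
    markers: pd.DataFrame  # MARKER_COLUMNS
    truth_events: pd.DataFrame  # columns t, event (HS/TO), side (L/R)
    truth_cycles: pd.DataFrame  # side, t_start, stride, stance, swing, double_support
    transitions: np.ndarray  # condition-boundary timestamps, possibly empty


def speed_adjusted_stride(base_stride_time: float, speed: float) -> float:
    """Stride time at a given belt speed (shorter when walking faster).

    Power-law scaling referenced to 1.25 m/s with exponent 0.3, a typical
    treadmill stride-time/speed relationship.
    """
    return float(base_stride_time * (1.25 / speed) ** 0.3)


def draw_subject_profile(rng: np.random.Generator, config: SimulationConfig,
                         subject_id: str = "S00") -> SubjectProfile:
    """Draw one subject's gait parameters.

    Ranges are chosen so that, across all configured speeds and the
    per-cycle stride jitter, every cycle's double-support time lands in the
    physiological 0.1-0.2 s band and stride times in roughly 0.97-1.26 s.
    """
    ds_fraction = rng.uniform(0.110, 0.150)
    return SubjectProfile(
        subject_id=subject_id,
        base_stride_time=rng.uniform(1.02, 1.18),
        stance_fraction=0.5 + ds_fraction / 2.0,
        double_support_fraction=ds_fraction,
        stride_cv=rng.uniform(0.008, 0.018),
        impact_amplitude=rng.uniform(1.2, 2.2),
        asymmetry_ratio=rng.uniform(0.99, 1.01),
    )


def _event_schedule(profile: SubjectProfile, speed: float, duration: float,
                    rng: np.random.Generator,
                    transitions: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the alternating HS/TO schedule and the per-cycle truth table."""
    t_mean = speed_adjusted_stride(profile.base_stride_time, speed)
    sf = profile.stance_fraction
    phase = 0.5 * profile.asymmetry_ratio

    # Left heel strikes: start offset, then per-cycle jittered stride times
    # (jitter clamped at 3 sigma so parameter bands hold for every cycle).
    # Transitions transiently lengthen strides by 5% within +/-1 s.
    n_max = int(np.ceil(duration / (t_mean * 0.8))) + 2
    eps = np.clip(rng.standard_normal(n_max), -3.0, 3.0)
    strides = t_mean * (1.0 + profile.stride_cv * eps)
    start = rng.uniform(0.3, 0.5)
    l_hs = start + np.concatenate([[0.0], np.cumsum(strides[:-1])])
    if transitions.size:
        for tr in transitions:
            strides[np.abs(l_hs - tr) < 1.0] *= 1.05
        l_hs = start + np.concatenate([[0.0], np.cumsum(strides[:-1])])
    keep = l_hs < duration - 0.2
    l_hs, strides = l_hs[keep], strides[keep]

    r_hs = l_hs + phase * strides
    l_to = l_hs + sf * strides
    r_to = r_hs[:-1] + sf * np.diff(r_hs)

    rows = []
    for times, ev, side in ((l_hs, "HS", "L"), (l_to, "TO", "L"),
                            (r_hs, "HS", "R"), (r_to, "TO", "R")):
        for t in times:
            if 0.0 <= t < duration:
                rows.append((t, ev, side))
    events = pd.DataFrame(rows, columns=["t", "event", "side"])
    events = events.sort_values("t", kind="stable").reset_index(drop=True)

    # Per-cycle truth from the schedule arithmetic. Each cycle has two
    # double-support phases, each ending with a contralateral toe-off:
    #   L cycle k: [l_hs[k], r_to[k-1]] and [r_hs[k], l_to[k]]
    #   R cycle k: [r_hs[k], l_to[k]]   and [l_hs[k+1], r_to[k]]
    # The first left cycle lacks a preceding right toe-off and is dropped.
    cyc = []
    for k in range(1, len(l_hs) - 1):
        ds = (r_to[k - 1] - l_hs[k]) + (l_to[k] - r_hs[k])
        cyc.append(("L", l_hs[k], l_hs[k + 1] - l_hs[k], l_to[k] - l_hs[k], ds))
    for k in range(len(r_hs) - 1):
        if k + 1 >= len(l_hs) or k >= len(r_to):
            break
        ds = (l_to[k] - r_hs[k]) + (r_to[k] - l_hs[k + 1])
        cyc.append(("R", r_hs[k], r_hs[k + 1] - r_hs[k], r_to[k] - r_hs[k], ds))
    truth_cycles = pd.DataFrame(
        cyc, columns=["side", "t_start", "stride", "stance", "double_support"])
    truth_cycles["swing"] = truth_cycles["stride"] - truth_cycles["stance"]
    truth_cycles = truth_cycles[
        truth_cycles["t_start"] + truth_cycles["stride"] < duration
    ][["side", "t_start", "stride", "stance", "swing", "double_support"]]
    truth_cycles = truth_cycles.sort_values(["side", "t_start"]).reset_index(drop=True)
    return events, truth_cycles


def _raised_cosine(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth unit pulse supported on [center - halfwidth, center + halfwidth]."""
    u = (t - center) / halfwidth
    out = np.zeros_like(t)
    m = np.abs(u) < 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _marker_track(t: np.ndarray, hs: np.ndarray, to: np.ndarray, base: float,
                  bump: float, dip_at: np.ndarray) -> np.ndarray:
    """Vertical marker model: baseline, swing bump, event dips.

    The bump spans each swing phase, rising as a half-cosine from the
    dip-clearance margin after TO_k to its apex at SWING_APEX_FRACTION of
    swing, and falling back to the baseline with zero slope shortly before
    the next event dip, so each dip sits on a locally flat baseline and is
    the only local minimum in its neighborhood.
    """
    z = np.full_like(t, base)
    for k in range(len(to)):
        nxt = hs[hs > to[k]]
        if not nxt.size:
            break
        t0 = to[k] + DIP_CLEARANCE_S
        t1 = nxt[0] - DIP_CLEARANCE_S
        apex = to[k] + SWING_APEX_FRACTION * (nxt[0] - to[k])
        if not t0 < apex < t1:
            continue
        seg = (t >= t0) & (t <= t1)
        ts = t[seg]
        rise = ts <= apex
        prof = np.empty_like(ts)
        prof[rise] = 0.5 * (1.0 - np.cos(np.pi * (ts[rise] - t0) / (apex - t0)))
        prof[~rise] = 0.5 * (1.0 + np.cos(np.pi * (ts[~rise] - apex) / (t1 - apex)))
        z[seg] += bump * prof
    for te in dip_at:
        z -= DIP_DEPTH_MM * _raised_cosine(t, te, DIP_HALFWIDTH_S)
    return z


def _add_transient(sig: dict[str, np.ndarray], t: np.ndarray, te: float,
                   mix: dict[str, float], amp: float, halfwidth: float) -> None:
    i0 = np.searchsorted(t, te - halfwidth)
    i1 = np.searchsorted(t, te + 4 * BURST_DECAY_S)
    ts = t[i0:i1]
    pulse = _raised_cosine(ts, te, halfwidth)
    tail = ts - te
    burst = np.where(tail >= 0,
                     np.exp(-np.maximum(tail, 0.0) / BURST_DECAY_S)
                     * np.sin(2 * np.pi * BURST_FREQ_HZ * tail),
                     0.0)
    wave = amp * (0.7 * pulse + 0.5 * burst)
    for ch, w in mix.items():
        sig[ch][i0:i1] += w * wave


# Channel mixes give the four event streams distinct multichannel
# signatures; left-side events are attenuated (the sensor rides on the
# right side of the body) and flip the sign of the gyroscope response.
HS_MIX_R = {"acc_z": 1.0, "acc_x": 0.40, "gyr_x": 55.0}
HS_MIX_L = {"acc_z": 0.65, "acc_y": 0.35, "gyr_x": -45.0}
TO_MIX_R = {"acc_x": 0.70, "acc_z": 0.25, "gyr_z": 50.0}
TO_MIX_L = {"acc_y": 0.55, "acc_z": 0.20, "gyr_z": -40.0}


def simulate_trial(profile: SubjectProfile, speed: float, placement: str,
                   config: SimulationConfig, rng: np.random.Generator,
                   transitions: Sequence[float] = ()) -> SyntheticTrial:
    """Render one trial (events, markers, IMU) for a subject at one condition."""
    duration = float(config.trial_duration)
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("trial duration must be finite and positive")
    if not np.isfinite(speed) or speed <= 0:
        raise ValueError("speed must be finite and positive")
    if placement not in PLACEMENT_EFFECTS:
        raise ValueError(f"unknown placement {placement!r}")

    transitions = np.asarray(sorted(transitions), dtype=float)
    events, truth_cycles = _event_schedule(profile, speed, duration, rng, transitions)
    hs_l = events.query("event == 'HS' and side == 'L'")["t"].to_numpy()
    hs_r = events.query("event == 'HS' and side == 'R'")["t"].to_numpy()
    to_l = events.query("event == 'TO' and side == 'L'")["t"].to_numpy()
    to_r = events.query("event == 'TO' and side == 'R'")["t"].to_numpy()

    # --- markers at the mocap rate -------------------------------------
    t_mk = np.arange(0.0, duration, 1.0 / config.fs_mocap)
    markers = pd.DataFrame({
        "t": t_mk,
        "calc_L_z": _marker_track(t_mk, hs_l, to_l, CALC_BASE_MM, CALC_BUMP_MM, hs_l),
        "calc_R_z": _marker_track(t_mk, hs_r, to_r, CALC_BASE_MM, CALC_BUMP_MM, hs_r),
        "meta_L_z": _marker_track(t_mk, hs_l, to_l, META_BASE_MM, META_BUMP_MM, to_l),
        "meta_R_z": _marker_track(t_mk, hs_r, to_r, META_BASE_MM, META_BUMP_MM, to_r),
    })
    if config.marker_noise_mm > 0:
        for c in MARKER_COLUMNS[1:]:
            markers[c] += rng.normal(0.0, config.marker_noise_mm, t_mk.size)

    # --- IMU at the sensor rate ----------------------------------------
    eff = PLACEMENT_EFFECTS[placement]
    noise_g = config.placement_noise.get(placement, eff["noise_g"])
    t_imu = np.arange(0.0, duration, 1.0 / config.fs_imu)
    sig = {c: np.zeros_like(t_imu) for c in IMU_COLUMNS[1:]}

    # gravity projection with slow orientation drift (deg-scale wobble)
    theta = np.deg2rad(4.0) * np.sin(2 * np.pi * 0.05 * t_imu + rng.uniform(0, 2 * np.pi))
    sig["acc_z"] += np.cos(theta)
    sig["acc_x"] += np.sin(theta)

    # stride-periodic body motion, phase-locked to the left-side cycle
    ph = 2 * np.pi * np.interp(t_imu, hs_l, np.arange(hs_l.size),
                               left=0.0, right=float(hs_l.size - 1))
    sig["acc_x"] += 0.10 * np.sin(2 * ph)
    sig["acc_y"] += 0.08 * np.sin(ph + 0.7)
    sig["gyr_y"] += 30.0 * np.sin(ph)
    sig["gyr_x"] += 12.0 * np.sin(2 * ph + 1.1)

    # event transients, delayed by placement-dependent mechanical jitter
    amp = profile.impact_amplitude * eff["atten"]
    for times, mix, scale, hw in (
            (hs_r, HS_MIX_R, 1.0, HS_PULSE_HALFWIDTH_S),
            (hs_l, HS_MIX_L, 1.0, HS_PULSE_HALFWIDTH_S),
            (to_r, TO_MIX_R, TO_AMPLITUDE_SCALE, TO_PULSE_HALFWIDTH_S),
            (to_l, TO_MIX_L, TO_AMPLITUDE_SCALE, TO_PULSE_HALFWIDTH_S)):
        delays = rng.normal(0.0, eff["delay_sd"], times.size)
        for te, d in zip(times, delays):
            _add_transient(sig, t_imu, te + d, mix, amp * scale, hw)

    if eff["pendulum_g"] > 0:  # loose jacket sways at its own frequency
        pend_ph = 2 * np.pi * 0.9 * t_imu + rng.uniform(0, 2 * np.pi)
        sig["acc_x"] += eff["pendulum_g"] * np.sin(pend_ph)
        sig["acc_y"] += 0.6 * eff["pendulum_g"] * np.sin(0.77 * pend_ph + 1.0)
        sig["gyr_z"] += 20.0 * np.sin(0.5 * pend_ph)

    for ch in sig:
        sd = noise_g * (250.0 if ch.startswith("gyr") else 1.0)
        sig[ch] += rng.normal(0.0, sd, t_imu.size)

    imu = pd.DataFrame({"t": t_imu, **sig})[IMU_COLUMNS]
    trial_id = f"{profile.subject_id}_v{speed:g}_{placement}"
    return SyntheticTrial(trial_id, profile.subject_id, speed, placement,
                          imu, markers, events, truth_cycles, transitions)


def generate_cohort(config: SimulationConfig,
                    out_dir: str | Path | None = None,
                    force: bool = False) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Simulate the full subject x speed x placement factorial.

    Returns the trials and a manifest (trial_id, subject, speed, placement,
    paths when written). With ``out_dir`` the per-trial CSVs and
    ``manifest.csv`` are written; an existing cohort directory is refused
    unless ``force`` is set.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects (train/test split downstream)")
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)

    trials: list[SyntheticTrial] = []
    rows = []
    for i, seq in enumerate(subj_seqs):
        sid = f"S{i:02d}"
        streams = seq.spawn(1 + len(config.speeds) * len(config.placements))
        profile = draw_subject_profile(np.random.default_rng(streams[0]), config, sid)
        j = 1
        for speed in config.speeds:
            for placement in config.placements:
                rng = np.random.default_rng(streams[j]); j += 1
                trial = simulate_trial(profile, speed, placement, config, rng)
                trials.append(trial)
                rows.append({"trial_id": trial.trial_id, "subject": sid,
                             "speed": speed, "placement": placement})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        out.mkdir(parents=True, exist_ok=True)
        for trial in trials:
            d = out / trial.trial_id
            d.mkdir(exist_ok=True)
            trial.imu.to_csv(d / "imu.csv", index=False, float_format="%.6f")
            trial.markers.to_csv(d / "markers.csv", index=False, float_format="%.6f")
            trial.truth_events.to_csv(d / "events.csv", index=False, float_format="%.6f")
            pd.DataFrame({"t": trial.transitions}).to_csv(
                d / "transitions.csv", index=False, float_format="%.6f")
        manifest = manifest.assign(path=[t.trial_id for t in trials])
        manifest.to_csv(out / "manifest.csv", index=False)
    return trials, manifest
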