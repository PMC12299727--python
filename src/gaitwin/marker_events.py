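"""Ground-truth gait events from vertical foot-marker trajectories.

Heel strike is the local minimum of the calcaneus vertical trajectory in
the first 30% of the interval between successive foot-motion peaks (the
swing apexes of the calcaneus track); toe-off is the local minimum of the
metatarsal trajectory between 40% and 80% of the same interval. Interior
local minima are preferred; on a monotone band the band's global minimum
(possibly a boundary sample) is used, and ties break toward earlier time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .prep import FilterSpec, lowpass_butterworth

log = logging.getLogger(__name__)

HS_BAND = (0.0, 0.30)
TO_BAND = (0.40, 0.80)


@dataclass(frozen=True)
class GaitEvent:
    """A typed, sided, timestamped gait event."""

    time: float
    type: str  # "HS" | "TO"
    side: str  # "L" | "R"
    source: str = "marker"  # "truth" | "marker" | "model"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.type not in ("HS", "TO") or self.side not in ("L", "R"):
            raise ValueError(f"bad event {self.type}/{self.side}")


@dataclass
class PeakSeries:
    """Per-stride foot-motion peak times for one side."""

    times: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")


def find_foot_motion_peaks(t: np.ndarray, z: np.ndarray, side: str = "L",
                           min_prominence: float = 10.0,
                           min_separation: float = 0.4) -> PeakSeries:
    """Swing-apex peaks of a (filtered) vertical marker trajectory.

    Parameters are in mm and seconds; defaults suit stride times >= 0.8 s
    and a swing lift of ~100 mm.
    """
    z = np.asarray(z, float)
    if z.size < 3 or np.ptp(z) == 0:
        return PeakSeries(np.empty(0), side)
    rate = 1.0 / np.median(np.diff(t))
    idx, _ = find_peaks(z, prominence=min_prominence,
                        distance=max(1, int(round(min_separation * rate))))
    return PeakSeries(t[idx], side)


def _band_minimum(t: np.ndarray, z: np.ndarray, t0: float, t1: float) -> float | None:
    """Time of the minimum of z on [t0, t1]: interior local minima first,
    global band minimum as fallback; earliest sample on ties."""
    i0, i1 = np.searchsorted(t, [t0, t1 + 1e-12])
    if i1 - i0 < 3:
        warnings.warn(f"band [{t0:.3f}, {t1:.3f}] s shorter than 3 samples; skipped")
        return None
    seg = z[i0:i1]
    interior = np.nonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
    if interior.size:
        k = interior[np.argmin(seg[interior])]
    else:
        k = int(np.argmin(seg))
    return float(t[i0 + k])


def _detect_in_bands(t: np.ndarray, z: np.ndarray, peaks: PeakSeries,
                     band: tuple[float, float], ev_type: str) -> list[GaitEvent]:
    if peaks.times.size < 2:
        return []
    out = []
    for p0, p1 in zip(peaks.times[:-1], peaks.times[1:]):
        delta = p1 - p0
        te = _band_minimum(t, z, p0 + band[0] * delta, p0 + band[1] * delta)
        if te is not None:
            out.append(GaitEvent(te, ev_type, peaks.side, "marker"))
    return out


def detect_heel_strikes(t: np.ndarray, calcaneus_z: np.ndarray,
                        peaks: PeakSeries) -> list[GaitEvent]:
    """One heel strike per inter-peak interval, in its first 30%."""
    return _detect_in_bands(t, calcaneus_z, peaks, HS_BAND, "HS")


def detect_toe_offs(t: np.ndarray, metatarsal_z: np.ndarray,
                    peaks: PeakSeries) -> list[GaitEvent]:
    """One toe-off per inter-peak interval, between its 40% and 80%."""
    return _detect_in_bands(t, metatarsal_z, peaks, TO_BAND, "TO")


def assemble_event_streams(hs: list[GaitEvent], to: list[GaitEvent],
                           side: str) -> pd.DataFrame:
    """Merge one side's HS and TO lists into a validated alternating stream.

    Events are sorted; where two events of the same type are adjacent the
    later one is dropped (logged), enforcing HS/TO alternation.
    """
    ev = sorted(hs + to, key=lambda e: (e.time, e.type))
    kept: list[GaitEvent] = []
    for e in ev:
        if e.side != side:
            raise ValueError(f"event side {e.side} != stream side {side}")
        if kept and kept[-1].type == e.type:
            log.info("dropping %s at %.3f s (breaks alternation)", e.type, e.time)
            continue
        kept.append(e)
    return pd.DataFrame([{"t": e.time, "event": e.type, "side": e.side} for e in kept],
                        columns=["t", "event", "side"])


def extract_marker_events(markers: pd.DataFrame,
                          filter_spec: FilterSpec = FilterSpec(),
                          min_prominence: float = 10.0,
                          min_separation: float = 0.4,
                          prefiltered: bool = False) -> pd.DataFrame:
    """Full marker pipeline for one trial's ``markers`` frame.

    Low-pass filters the four trajectories (10 Hz zero-phase by default),
    finds per-side foot-motion peaks on the calcaneus track, and applies
    the band-minimum rules. Returns a combined events frame (t, event,
    side) sorted by time.
    """
    t = markers["t"].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    streams = []
    for side in ("L", "R"):
        calc = markers[f"calc_{side}_z"].to_numpy()
        meta = markers[f"meta_{side}_z"].to_numpy()
        if not prefiltered:
            calc = lowpass_butterworth(calc, rate, filter_spec)
            meta = lowpass_butterworth(meta, rate, filter_spec)
        peaks = find_foot_motion_peaks(t, calc, side, min_prominence, min_separation)
        hs = detect_heel_strikes(t, calc, peaks)
        to = detect_toe_offs(t, meta, peaks)
        streams.append(assemble_event_streams(hs, to, side))
    out = pd.concat(streams, ignore_index=True)
    return out.sort_values("t", kind="stable").reset_index(drop=True)
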