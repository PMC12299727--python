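"""IMU preprocessing: resampling, low-pass filtering, robust scaling,
windowing and window labeling.

The processing chain mirrors standard practice for window-based gait event
classification: downsample the sensor stream to the mocap rate (100 Hz),
low-pass at 10 Hz with a zero-phase 4th-order Butterworth, scale each
channel robustly (median/IQR), cut 200 ms windows with a 100 ms hop, and
mark a window positive for an event stream only when an event falls in the
central 45-55% band of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

#: The four event streams, one binary label (and one detector) each.
STREAMS = ("HS_L", "HS_R", "TO_L", "TO_R")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (zero-phase by default)."""

    order: int = 4
    cutoff: float = 10.0  # Hz
    zero_phase: bool = True


@dataclass
class WindowedDataset:
    """Fixed-length overlapping windows from one trial.

    ``X`` has shape (n_windows, samples_per_window, n_channels); ``starts``
    holds window onset times (s, half-open support [start, start+length)).
    ``labels`` maps stream name -> binary vector once labeled.
    """

    trial_id: str
    X: np.ndarray
    starts: np.ndarray
    length: float = 0.200
    hop: float = 0.100
    rate: float = 100.0
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    scaler: pd.DataFrame | None = None  # channel, median, iqr, degenerate

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.length / 2.0

    def __len__(self) -> int:
        return len(self.starts)


def resample_to(t: np.ndarray, x: np.ndarray, target_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Downsample a uniformly sampled (possibly multichannel) series.

    An anti-alias zero-phase Butterworth (8th order at 0.45x the target
    rate) is applied before linear interpolation onto the half-open target
    grid t' = 0, 1/r, ..., < duration. Handles non-integer rate ratios such
    as 1259 -> 100 Hz. Upsampling and non-finite input are rejected.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need a 1-D time base with >= 2 samples")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values in input series")
    src_rate = 1.0 / np.median(np.diff(t))
    if target_rate > src_rate + 1e-9:
        raise ValueError(f"upsampling {src_rate:.6g} -> {target_rate:.6g} Hz not supported")
    duration = t[-1] - t[0] + 1.0 / src_rate
    t_out = t[0] + np.arange(0.0, duration - 1e-12, 1.0 / target_rate)
    if abs(target_rate - src_rate) < 1e-9:
        return t_out, x[: t_out.size].copy()
    sos = signal.butter(8, 0.45 * target_rate, btype="low", fs=src_rate, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=0)
    if y.ndim == 1:
        out = np.interp(t_out, t, y)
    else:
        out = np.column_stack([np.interp(t_out, t, y[:, j]) for j in range(y.shape[1])])
    return t_out, out


def lowpass_butterworth(x: np.ndarray, rate: float,
                        spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass filter along axis 0; zero-phase (filtfilt) unless disabled."""
    if spec.cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {rate / 2} Hz")
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=rate, output="sos")
    x = np.asarray(x, float)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def robust_scale(x: np.ndarray, channel_names: list[str] | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Center by the median and scale by the IQR, per channel.

    Quartiles use linear interpolation between order statistics. A channel
    with zero IQR is flagged degenerate and its scale falls back to 1, so
    constant channels map to zeros.
    """
    x_in = np.asarray(x, float)
    one_d = x_in.ndim == 1
    x = x_in[:, None] if one_d else x_in
    if x.shape[0] < 4:
        raise ValueError("need >= 4 samples per channel for quartiles")
    med = np.median(x, axis=0)
    q1, q3 = np.percentile(x, [25, 75], axis=0)
    iqr = q3 - q1
    degenerate = iqr <= 0
    scale = np.where(degenerate, 1.0, iqr)
    params = pd.DataFrame({
        "channel": channel_names if channel_names is not None else
        [f"ch{j}" for j in range(x.shape[1])],
        "median": med, "iqr": iqr, "degenerate": degenerate,
    })
    scaled = (x - med) / scale
    return (scaled.ravel() if one_d else scaled), params


def segment_windows(t: np.ndarray, x: np.ndarray, trial_id: str = "",
                    length: float = 0.200, hop: float = 0.100) -> WindowedDataset:
    """Cut overlapping fixed-length windows; trailing partials are dropped."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    rate = 1.0 / np.median(np.diff(t))
    n_per = int(round(length * rate))
    hop_n = int(round(hop * rate))
    duration = t.size / rate
    if duration < length - 1e-9:
        warnings.warn(f"series shorter than one window ({duration:.3f} s < {length} s)")
        X = np.empty((0, n_per, x.shape[1] if x.ndim > 1 else 1))
        return WindowedDataset(trial_id, X, np.empty(0), length, hop, rate)
    n_win = (t.size - n_per) // hop_n + 1
    idx = np.arange(n_per)[None, :] + hop_n * np.arange(n_win)[:, None]
    X = x[idx] if x.ndim > 1 else x[idx][..., None]
    starts = t[0] + hop * np.arange(n_win)
    return WindowedDataset(trial_id, X, starts, length, hop, rate)


def label_windows(dataset: WindowedDataset, events: pd.DataFrame,
                  band: tuple[float, float] = (0.45, 0.55)) -> WindowedDataset:
    """Mark windows containing an event near their center, per stream.

    A window [s, s+L) is positive for a stream iff some event time t of
    that stream satisfies s + band[0]*L <= t <= s + band[1]*L (endpoints
    inclusive). With the default central 10% band and 50% overlap this
    labels at most one window per event.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"label band {band} must satisfy 0 <= lo < hi <= 1")
    L = dataset.length
    for stream in STREAMS:
        ev, side = stream.split("_")
        times = events.loc[(events["event"] == ev) & (events["side"] == side), "t"].to_numpy()
        lab = np.zeros(len(dataset), dtype=np.int8)
        for te in times:
            hit = (dataset.starts + lo * L <= te) & (te <= dataset.starts + hi * L)
            lab |= hit.astype(np.int8)
        dataset.labels[stream] = lab
    return dataset


def preprocess_series(imu: pd.DataFrame, filter_spec: FilterSpec = FilterSpec(),
                      target_rate: float = 100.0
                      ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Resample, low-pass filter and robust-scale one trial's IMU frame.

    Returns the target time base, the scaled channel block and the scaler
    parameters.
    """
    channels = [c for c in imu.columns if c != "t"]
    t, x = resample_to(imu["t"].to_numpy(), imu[channels].to_numpy(), target_rate)
    x = lowpass_butterworth(x, target_rate, filter_spec)
    x, scaler = robust_scale(x, channels)
    return t, x, scaler


def prepare_trial(imu: pd.DataFrame, trial_id: str = "",
                  filter_spec: FilterSpec = FilterSpec(),
                  target_rate: float = 100.0,
                  length: float = 0.200, hop: float = 0.100) -> WindowedDataset:
    """Full preprocessing for one trial's raw IMU frame.

    Resample to ``target_rate``, low-pass filter, robust-scale each channel
    and window the result. Labels are attached separately (they require an
    event source).

    The hop only sets how densely window onsets sample the trial; training
    uses the standard 100 ms hop, while detection benefits from a finer one
    (the classifier is deliberately shift-sensitive, so inference windows
    must sample time shifts at least as finely as the labeling band).
    """
    t, x, scaler = preprocess_series(imu, filter_spec, target_rate)
    ds = segment_windows(t, x, trial_id, length, hop)
    ds.scaler = scaler
    return ds


def save_windows(dataset: WindowedDataset, out_dir) -> None:
    """Persist a windowed dataset as flat CSVs (portable reference schema)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, p, c = dataset.X.shape
    flat = pd.DataFrame({
        "window_id": np.repeat(np.arange(n), p * c),
        "channel": np.tile(np.repeat(np.arange(c), 1), n * p),
        "sample_index": np.tile(np.repeat(np.arange(p), c), n),
        "value": dataset.X.reshape(-1),
    })
    flat.to_csv(out / "windows.csv", index=False)
    pd.DataFrame({"window_id": np.arange(n), "start": dataset.starts}).to_csv(
        out / "starts.csv", index=False)
    if dataset.labels:
        rows = [{"window_id": i, "stream": s, "label": int(v)}
                for s, lab in dataset.labels.items() for i, v in enumerate(lab)]
        pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    if dataset.scaler is not None:
        dataset.scaler.to_csv(out / "scaler.csv", index=False)
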