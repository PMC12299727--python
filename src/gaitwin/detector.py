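"""Windowed gait-event detection: one conv+LSTM classifier per event
stream (HS-L, HS-R, TO-L, TO-R), trained on marker-labeled windows, plus
the reconstruction of continuous event times from window probabilities.

`WindowClassifier` follows the model/results idiom: construct it from the
training windows and labels, call :meth:`WindowClassifier.fit`, and use
the returned :class:`ClassifierResults` for prediction and reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, ConvLSTMNet
from .prep import STREAMS, WindowedDataset


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the per-stream window classifier."""

    conv_channels: tuple[int, ...] = (16, 32)
    kernel: int = 5
    recurrent_units: int = 32
    dropout: float = 0.10
    epochs: int = 12
    batch_size: int = 256
    learning_rate: float = 3e-3
    positive_class_weight: float | None = None  # None -> negatives/positives
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate out of range")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if any(c <= 0 for c in self.conv_channels) or self.recurrent_units <= 0:
            raise ValueError("layer widths must be positive")


@dataclass
class SplitPlan:
    """Subject-level train/test partition."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    fraction: float = 0.8

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("subjects leak across the split")


def split_by_subject(manifest: pd.DataFrame, fraction: float = 0.8,
                     seed: int = 0) -> SplitPlan:
    """Random subject-wise split; every subject ends up on exactly one side."""
    subjects = sorted(manifest["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects to split")
    n_train = int(round(fraction * len(subjects)))
    if n_train < 1 or n_train >= len(subjects):
        raise ValueError(f"fraction {fraction} leaves an empty partition")
    order = np.random.default_rng(seed).permutation(len(subjects))
    train = tuple(subjects[i] for i in sorted(order[:n_train]))
    test = tuple(subjects[i] for i in sorted(order[n_train:]))
    return SplitPlan(train, test, fraction)


def leave_one_subject_out(manifest: pd.DataFrame) -> list[SplitPlan]:
    """All leave-one-subject-out splits (alternative to the 80/20 split)."""
    subjects = sorted(manifest["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    return [SplitPlan(tuple(s for s in subjects if s != held), (held,), 0.0)
            for held in subjects]


@dataclass
class TrainReport:
    stream: str
    epoch_loss: list[float] = field(default_factory=list)
    holdout_precision: float = float("nan")
    holdout_recall: float = float("nan")
    holdout_f1: float = float("nan")
    pos_weight: float = 1.0


@dataclass
class ClassifierResults:
    """A fitted per-stream detector."""

    stream: str
    spec: ModelSpec
    net: ConvLSTMNet
    report: TrainReport

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """One probability per window, order preserved."""
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(f"window shape {X.shape[1:]} != trained shape "
                             f"{self.input_shape}")
        chunks = [self.net.predict_proba(X[i:i + 8192])
                  for i in range(0, len(X), 8192)]
        return np.concatenate(chunks) if chunks else np.empty(0)

    input_shape: tuple[int, int] = (20, 6)

    def summary(self) -> str:
        r = self.report
        lines = [f"WindowClassifier [{self.stream}]",
                 f"  conv channels     : {self.spec.conv_channels} (kernel {self.spec.kernel})",
                 f"  recurrent units   : {self.spec.recurrent_units}",
                 f"  epochs / batch    : {self.spec.epochs} / {self.spec.batch_size}",
                 f"  positive weight   : {r.pos_weight:.1f}",
                 f"  final train loss  : {r.epoch_loss[-1]:.4f}" if r.epoch_loss
                 else "  final train loss  : n/a",
                 f"  holdout P/R/F1    : {r.holdout_precision:.3f} / "
                 f"{r.holdout_recall:.3f} / {r.holdout_f1:.3f}"]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / f"{self.stream}_weights.npz",
                 *self.net.get_weights())
        (out / f"{self.stream}_spec.json").write_text(
            json.dumps({"stream": self.stream, "spec": asdict(self.spec),
                        "input_shape": list(self.input_shape),
                        "format_version": 1}, indent=2))


def load_classifier(model_dir, stream: str) -> ClassifierResults:
    """Load a detector saved by :meth:`ClassifierResults.save`."""
    d = Path(model_dir)
    meta = json.loads((d / f"{stream}_spec.json").read_text())
    spec_kw = meta["spec"]
    spec_kw["conv_channels"] = tuple(spec_kw["conv_channels"])
    spec = ModelSpec(**spec_kw)
    shape = tuple(meta["input_shape"])
    net = ConvLSTMNet(shape[1], spec.conv_channels, spec.kernel,
                      spec.recurrent_units, seed=spec.seed)
    with np.load(d / f"{stream}_weights.npz") as z:
        net.set_weights([z[f"arr_{i}"] for i in range(len(z.files))])
    res = ClassifierResults(stream, spec, net, TrainReport(stream=stream))
    res.input_shape = shape
    return res


class WindowClassifier:
    """Binary window classifier for one event stream.

    Parameters
    ----------
    X : (n_windows, samples, channels) scaled window block
    y : binary labels for one stream
    spec : ModelSpec
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: ModelSpec = ModelSpec(),
                 stream: str = "HS_R"):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float).ravel()
        if self.X.ndim != 3 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, samples, channels) aligned with y")
        self.spec = spec
        self.stream = stream

    @classmethod
    def from_datasets(cls, datasets: list[WindowedDataset], stream: str,
                      spec: ModelSpec = ModelSpec()) -> "WindowClassifier":
        X = np.concatenate([d.X for d in datasets])
        y = np.concatenate([d.labels[stream] for d in datasets])
        return cls(X, y, spec, stream)

    def fit(self, holdout_fraction: float = 0.1) -> ClassifierResults:
        """Train with Adam on class-weighted BCE; deterministic per seed."""
        spec = self.spec
        n_pos = int(self.y.sum())
        n_neg = len(self.y) - n_pos
        if spec.epochs > 0 and (n_pos == 0 or n_neg == 0):
            raise ValueError("training labels contain a single class")
        pos_weight = (spec.positive_class_weight
                      if spec.positive_class_weight is not None
                      else (n_neg / max(n_pos, 1)))

        rng = np.random.default_rng(spec.seed)
        net = ConvLSTMNet(self.X.shape[2], spec.conv_channels, spec.kernel,
                          spec.recurrent_units, seed=spec.seed)
        n = len(self.y)
        n_hold = int(round(holdout_fraction * n)) if spec.epochs > 0 else 0
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        Xtr, ytr = self.X[train], self.y[train]

        opt = Adam(net, lr=spec.learning_rate)
        report = TrainReport(stream=self.stream, pos_weight=float(pos_weight))
        for _ in range(spec.epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for i0 in range(0, len(order), spec.batch_size):
                sel = order[i0:i0 + spec.batch_size]
                loss = net.loss_and_grads(Xtr[sel], ytr[sel], pos_weight,
                                          dropout=spec.dropout, rng=rng)
                opt.step()
                losses.append(loss)
            report.epoch_loss.append(float(np.mean(losses)))

        if n_hold:
            p = net.predict_proba(self.X[hold]) >= 0.5
            yh = self.y[hold] > 0.5
            tp = int(np.sum(p & yh))
            report.holdout_precision = tp / max(int(p.sum()), 1)
            report.holdout_recall = tp / max(int(yh.sum()), 1)
            pr, rc = report.holdout_precision, report.holdout_recall
            report.holdout_f1 = 2 * pr * rc / max(pr + rc, 1e-12)

        results = ClassifierResults(self.stream, spec, net, report)
        results.input_shape = self.X.shape[1:]
        return results


@dataclass
class DetectedEvents:
    """Reconstructed event times with confidences for one stream."""

    stream: str
    times: np.ndarray
    confidences: np.ndarray


def reconstruct_events(probabilities: np.ndarray, window_starts: np.ndarray,
                       window_length: float = 0.200, hop: float = 0.100,
                       threshold: float = 0.5, refractory: float = 0.4,
                       stream: str = "") -> DetectedEvents:
    """Turn per-window probabilities into continuous event times.

    Supra-threshold windows are grouped into runs of temporally adjacent
    windows; each run yields one candidate at the confidence-weighted mean
    of the member window centers, with the run's peak probability as its
    confidence. Candidates closer than ``refractory`` seconds keep only
    the highest-confidence member (ties to the earlier candidate).
    """
    p = np.asarray(probabilities, float)
    starts = np.asarray(window_starts, float)
    centers = starts + window_length / 2.0
    hot = np.nonzero(p >= threshold)[0]
    if hot.size == 0:
        return DetectedEvents(stream, np.empty(0), np.empty(0))
    runs = np.split(hot, np.nonzero(np.diff(hot) > 1)[0] + 1)
    cand_t = np.array([np.sum(p[r] * centers[r]) / np.sum(p[r]) for r in runs])
    cand_c = np.array([p[r].max() for r in runs])

    order = np.lexsort((cand_t, -cand_c))  # best confidence first, then earlier
    kept_t: list[float] = []
    kept_c: list[float] = []
    for k in order:
        if all(abs(cand_t[k] - t) >= refractory for t in kept_t):
            kept_t.append(cand_t[k])
            kept_c.append(cand_c[k])
    idx = np.argsort(kept_t)
    return DetectedEvents(stream, np.asarray(kept_t)[idx], np.asarray(kept_c)[idx])


def detect_trial_events(results_by_stream: dict[str, ClassifierResults],
                        dataset: WindowedDataset, threshold: float = 0.5,
                        refractory: float = 0.4) -> pd.DataFrame:
    """Apply the four fitted detectors to one preprocessed trial."""
    frames = []
    for stream in STREAMS:
        res = results_by_stream[stream]
        p = res.predict_proba(dataset.X)
        det = reconstruct_events(p, dataset.starts, dataset.length, dataset.hop,
                                 threshold, refractory, stream)
        ev, side = stream.split("_")
        frames.append(pd.DataFrame({"t": det.times, "event": ev, "side": side,
                                    "confidence": det.confidences}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("t", kind="stable").reset_index(drop=True)
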