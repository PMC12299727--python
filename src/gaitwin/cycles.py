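"""Per-cycle temporal gait parameters and the cycle quality filter.

A gait cycle runs from one heel strike to the next ipsilateral heel
strike. Within each cycle: stance = heel strike to the next ipsilateral
toe-off, swing = that toe-off to the cycle-closing heel strike, and double
support = total time inside the cycle during which both feet are in their
stance phase (computed by intersecting the two sides' stance intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CYCLE_COLUMNS = ["cycle_id", "side", "t_start", "stride", "stance", "swing",
                 "double_support", "valid", "exclusion_reason"]
PARAMETERS = ("stride", "stance", "swing", "double_support")


@dataclass(frozen=True)
class CycleParams:
    cycle_id: str
    side: str
    t_start: float
    stride: float
    stance: float
    swing: float
    double_support: float
    valid: bool
    exclusion_reason: str = "none"


def _stance_intervals(side_events: pd.DataFrame) -> list[tuple[float, float]]:
    """Stance intervals [HS, next TO] of one side's alternating stream.

    A stream beginning with a toe-off contributes a leading interval open
    to the left; a trailing heel strike contributes one open to the right.
    """
    iv: list[tuple[float, float]] = []
    open_start: float | None = None
    for _, row in side_events.iterrows():
        if row["event"] == "HS":
            open_start = row["t"]
        else:  # TO
            iv.append((-np.inf if open_start is None else open_start, row["t"]))
            open_start = None
    if open_start is not None:
        iv.append((open_start, np.inf))
    return iv


def _overlap(iv_a: list[tuple[float, float]], lo: float, hi: float) -> float:
    """Total length of intervals intersected with [lo, hi)."""
    total = 0.0
    for a, b in iv_a:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


def compute_cycles(events: pd.DataFrame, trial_id: str = "") -> pd.DataFrame:
    """Derive per-cycle parameters from a bilateral event frame.

    ``events`` needs columns t/event/side with per-side alternation already
    enforced. Cycles missing their ipsilateral toe-off are kept but flagged
    incomplete (durations NaN).
    """
    rows = []
    for side in ("L", "R"):
        mine = events[events["side"] == side].sort_values("t")
        other = events[events["side"] != side].sort_values("t")
        other_stance = _stance_intervals(other)
        hs = mine.loc[mine["event"] == "HS", "t"].to_numpy()
        to = mine.loc[mine["event"] == "TO", "t"].to_numpy()
        for k in range(len(hs) - 1):
            h0, h1 = hs[k], hs[k + 1]
            cid = f"{trial_id}:{side}{k:03d}"
            mid_to = to[(to > h0) & (to < h1)]
            if mid_to.size != 1:
                rows.append((cid, side, h0, h1 - h0, np.nan, np.nan, np.nan,
                             False, "incomplete"))
                continue
            stance = float(mid_to[0] - h0)
            swing = float(h1 - mid_to[0])
            own = [(h0, float(mid_to[0]))]
            ds = sum(_overlap(other_stance, max(a, h0), min(b, h1)) for a, b in own)
            rows.append((cid, side, h0, h1 - h0, stance, swing, ds, True, "none"))
    out = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    return out.sort_values(["side", "t_start"]).reset_index(drop=True)


def filter_cycles(cycles: pd.DataFrame, transitions=(),
                  stride_bounds: tuple[float, float] = (0.4, 2.5)
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cycle quality filter; returns (cycles, exclusion tally).

    Order of precedence per cycle: incomplete, negative duration,
    transition span, implausible stride. The returned frame keeps all
    cycles with updated valid/exclusion_reason fields.
    """
    transitions = np.asarray(list(transitions), float)
    out = cycles.copy()
    tally = {"none": 0, "negative_duration": 0, "transition": 0,
             "implausible": 0, "incomplete": 0}
    for i, row in out.iterrows():
        reason = "none"
        durations = (row["stride"], row["stance"], row["swing"], row["double_support"])
        if row["exclusion_reason"] == "incomplete":
            reason = "incomplete"
        elif any(pd.notna(d) and d < 0 for d in durations):
            reason = "negative_duration"
        elif transitions.size and np.any(
                (transitions >= row["t_start"]) &
                (transitions < row["t_start"] + row["stride"])):
            reason = "transition"
        elif not stride_bounds[0] <= row["stride"] <= stride_bounds[1]:
            reason = "implausible"
        tally[reason] += 1
        out.loc[i, "exclusion_reason"] = reason
        out.loc[i, "valid"] = reason == "none"
    return out, tally


def symmetry_index(left_values, right_values) -> float:
    """Normalized absolute left/right mean difference, in percent:
    SI = 100 * |mean(R) - mean(L)| / (0.5 * (mean(R) + mean(L)))."""
    left = np.asarray(list(left_values), float)
    right = np.asarray(list(right_values), float)
    if left.size == 0 or right.size == 0:
        raise ValueError("both sides must be non-empty")
    ml, mr = left.mean(), right.mean()
    return float(100.0 * abs(mr - ml) / (0.5 * (mr + ml)))


def aggregate_by_condition(cycles: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Mean of each parameter per subject x speed x placement, sides pooled.

    ``cycles`` must carry a trial_id column matching the manifest; only
    valid cycles contribute. Conditions with zero valid cycles are omitted
    (logged).
    """
    valid = cycles.loc[cycles["valid"].astype(bool)].merge(manifest, on="trial_id")
    rows = []
    for (subject, speed, placement), grp in valid.groupby(
            ["subject", "speed", "placement"], sort=True):
        for param in PARAMETERS:
            rows.append({"subject": subject, "speed": speed, "placement": placement,
                         "parameter": param, "mean": grp[param].mean(),
                         "n_cycles": len(grp)})
    expected = manifest[["subject", "speed", "placement"]].drop_duplicates()
    seen = {(r["subject"], r["speed"], r["placement"]) for r in rows}
    for _, cond in expected.iterrows():
        if (cond["subject"], cond["speed"], cond["placement"]) not in seen:
            log.warning("no valid cycles for condition %s", tuple(cond))
    return pd.DataFrame(rows)
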