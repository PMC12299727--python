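"""Agreement statistics between experimental (M1) and predicted (M2)
gait parameters: relative RMSE summaries, Pearson association with
weak/moderate/strong tiers, and Bland-Altman bias / 95% limits of
agreement.

`AgreementAnalysis` is the model object: it is built from per-cycle or
per-condition paired data and `fit()` returns an `AgreementResults`
carrying the three report tables and a `summary()`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cycles import PARAMETERS

log = logging.getLogger(__name__)

TIER_THRESHOLDS = (0.3, 0.6)  # weak < 0.3 <= moderate < 0.6 <= strong


def match_cycles(m1_cycles: pd.DataFrame, m2_cycles: pd.DataFrame,
                 tolerance: float = 0.25) -> tuple[pd.DataFrame, int]:
    """Pair cycles from two event sources by nearest heel-strike time.

    Greedy nearest-first matching within ``tolerance`` seconds, per side;
    each cycle is used at most once. Returns the paired frame (columns
    ``<param>_m1`` / ``<param>_m2``) and the count of unmatched cycles.
    """
    pairs = []
    dropped = 0
    for side in ("L", "R"):
        a = m1_cycles[(m1_cycles["side"] == side) & m1_cycles["valid"]].reset_index(drop=True)
        b = m2_cycles[(m2_cycles["side"] == side) & m2_cycles["valid"]].reset_index(drop=True)
        if a.empty or b.empty:
            dropped += len(a) + len(b)
            continue
        cand = [(abs(a.loc[i, "t_start"] - b.loc[j, "t_start"]), i, j)
                for i in a.index for j in b.index
                if abs(a.loc[i, "t_start"] - b.loc[j, "t_start"]) <= tolerance]
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            row = {"side": side, "t_start": a.loc[i, "t_start"]}
            for p in PARAMETERS:
                row[f"{p}_m1"] = a.loc[i, p]
                row[f"{p}_m2"] = b.loc[j, p]
            pairs.append(row)
        dropped += (len(a) - len(used_a)) + (len(b) - len(used_b))
    out = pd.DataFrame(pairs).sort_values("t_start").reset_index(drop=True) \
        if pairs else pd.DataFrame()
    return out, dropped


def rrmse(m1, m2) -> float:
    """Relative RMSE in percent: 100 * RMS(m2 - m1) / mean(m1)."""
    m1 = np.asarray(list(m1), float)
    m2 = np.asarray(list(m2), float)
    if m1.size == 0 or m1.size != m2.size:
        raise ValueError("need equal-length non-empty series")
    denom = m1.mean()
    if denom <= 0:
        raise ValueError("mean of the reference series must be positive")
    return float(100.0 * np.sqrt(np.mean((m2 - m1) ** 2)) / denom)


def summarize_rrmse(values, n_boot: int = 1000, seed: int = 0) -> dict:
    """Median/IQR of per-condition rRMSE values plus a bootstrap CI.

    The 95% CI is a seeded percentile bootstrap of the *mean*; under the
    right-skew typical of rRMSE distributions the sample median can fall
    below the CI's lower bound. Skewness is Fisher-Pearson g1.
    """
    v = np.asarray(list(values), float)
    if v.size > 2:
        skewness = float(stats.skew(v, bias=True)) if np.ptp(v) > 0 else 0.0
    else:
        skewness = np.nan
    out = {"median": float(np.median(v)),
           "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
           "skewness": skewness,
           "n": int(v.size)}
    if v.size < 3:
        out.update(ci_low=np.nan, ci_high=np.nan, ci_ok=False)
        return out
    rng = np.random.default_rng(seed)
    boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    out.update(ci_low=float(lo), ci_high=float(hi), ci_ok=True)
    return out


def pearson_association(m1, m2) -> dict:
    """Pearson r with two-sided p and the weak/moderate/strong tier."""
    m1 = np.asarray(list(m1), float)
    m2 = np.asarray(list(m2), float)
    if m1.size < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(m1) == 0 or np.std(m2) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(m1, m2)
    tier = ("weak" if r < TIER_THRESHOLDS[0]
            else "moderate" if r < TIER_THRESHOLDS[1] else "strong")
    return {"r": float(r), "p": float(p), "tier": tier}


def bland_altman(m1, m2) -> dict:
    """Bias and 95% limits of agreement of differences d = M1 - M2."""
    m1 = np.asarray(list(m1), float)
    m2 = np.asarray(list(m2), float)
    if m1.size < 2 or m1.size != m2.size:
        raise ValueError("need n >= 2 paired values")
    d = m1 - m2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return {"bias": bias, "loa_low": lo, "loa_high": hi, "pct_within": within}


@dataclass
class AgreementResults:
    """Fitted agreement battery; tables mirror the usual report layout."""

    rrmse_table: pd.DataFrame      # parameter, speed, placement, median, iqr, ci...
    pearson_table: pd.DataFrame    # parameter, speed, placement, r, p, tier, stars
    bland_altman_table: pd.DataFrame  # parameter, placement, bias, loa, pct_within
    per_condition_rrmse: pd.DataFrame  # subject-level rRMSE values

    def summary(self) -> str:
        lines = ["Agreement analysis (experimental M1 vs predicted M2)",
                 "=" * 56, "", "Relative RMSE (%) by parameter (pooled):"]
        pooled = self.per_condition_rrmse.groupby("parameter")["rrmse"].median()
        for p in PARAMETERS:
            if p in pooled:
                lines.append(f"  {p:<15s} median {pooled[p]:6.2f}")
        lines.append("")
        lines.append("Pearson association (condition-level means, pooled):")
        for p in PARAMETERS:
            sub = self.per_condition_rrmse[self.per_condition_rrmse["parameter"] == p]
            try:
                pa = self.pooled_pearson(p)
            except ValueError:
                continue
            lines.append(f"  {p:<15s} r={pa['r']:+.3f} ({pa['tier']})"
                         f"{_stars(pa['p'])}  n={len(sub)}")
        for _, row in self.pearson_table.iterrows():
            lines.append(f"  {row['parameter']:<15s} v={row['speed']:<5} "
                         f"{row['placement']:<8s} r={row['r']:+.3f} "
                         f"({row['tier']}){row['stars']}")
        lines.append("")
        lines.append("Bland-Altman (s):")
        for _, row in self.bland_altman_table.iterrows():
            lines.append(f"  {row['parameter']:<15s} {row['placement']:<8s} "
                         f"bias={row['bias']:+.4f} "
                         f"LoA=[{row['loa_low']:+.4f}, {row['loa_high']:+.4f}] "
                         f"{row['pct_within']:.1f}% within")
        return "\n".join(lines)

    def pooled_median_rrmse(self, parameter: str) -> float:
        """Median per-condition rRMSE pooled over speeds and placements (%)."""
        sub = self.per_condition_rrmse
        return float(sub.loc[sub["parameter"] == parameter, "rrmse"].median())

    def pooled_pearson(self, parameter: str) -> dict:
        """Pearson r over all subject x speed x placement condition means."""
        sub = self.per_condition_rrmse[self.per_condition_rrmse["parameter"] == parameter]
        return pearson_association(sub["m1_mean"], sub["m2_mean"])

    def pooled_within_loa(self) -> float:
        """% of Bland-Altman points within the 95% limits, pooled over the
        parameters (limits computed per parameter across all conditions)."""
        total = 0
        within = 0.0
        for param, sub in self.per_condition_rrmse.groupby("parameter"):
            ba = bland_altman(sub["m1_mean"], sub["m2_mean"])
            total += len(sub)
            within += ba["pct_within"] * len(sub) / 100.0
        return float(100.0 * within / total)

    def save_tables(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rrmse_table.to_csv(out / "table1_rrmse.csv", index=False)
        self.pearson_table.to_csv(out / "table2_pearson.csv", index=False)
        self.bland_altman_table.to_csv(out / "bland_altman.csv", index=False)

    def plot_bland_altman(self, parameter: str = "stride"):
        """One Bland-Altman panel per placement for a parameter."""
        import matplotlib.pyplot as plt

        sub = self._ba_points[self._ba_points["parameter"] == parameter]
        placements = sorted(sub["placement"].unique())
        fig, axes = plt.subplots(1, len(placements), figsize=(4 * len(placements), 3.2),
                                 squeeze=False)
        for ax, pl in zip(axes[0], placements):
            pts = sub[sub["placement"] == pl]
            d = pts["m1"] - pts["m2"]
            avg = (pts["m1"] + pts["m2"]) / 2
            ax.scatter(avg, d, s=12)
            if len(pts) >= 2:
                ba = bland_altman(pts["m1"], pts["m2"])
                for y, ls in ((ba["bias"], "-"), (ba["loa_low"], "--"),
                              (ba["loa_high"], "--")):
                    ax.axhline(y, ls=ls, color="k", lw=0.8)
            ax.set_title(f"{parameter} / {pl}")
            ax.set_xlabel("mean of M1, M2 (s)")
            ax.set_ylabel("M1 - M2 (s)")
        fig.tight_layout()
        return fig

    _ba_points: pd.DataFrame = None  # set by AgreementAnalysis.fit


def _stars(p: float) -> str:
    return "**" if p < 0.001 else "*" if p < 0.05 else ""


class AgreementAnalysis:
    """Agreement model over paired per-cycle parameters.

    Built from a long frame with one row per matched cycle carrying
    subject/speed/placement keys and ``<param>_m1`` / ``<param>_m2``
    columns (see :func:`match_cycles`). ``fit`` computes, per parameter:

    * per subject x speed x placement rRMSE, summarized per speed x
      placement cell (median, IQR, bootstrap 95% CI of the mean);
    * Pearson r between condition-level means, tiered;
    * Bland-Altman bias and 95% limits of agreement per placement, one
      point per subject x speed x placement.
    """

    def __init__(self, paired: pd.DataFrame, parameters=PARAMETERS):
        required = {"subject", "speed", "placement"}
        if not required <= set(paired.columns):
            raise ValueError(f"paired frame must carry keys {sorted(required)}")
        self.paired = paired
        self.parameters = tuple(parameters)

    @classmethod
    def from_dataframe(cls, paired: pd.DataFrame, **kw) -> "AgreementAnalysis":
        return cls(paired, **kw)

    def fit(self, n_boot: int = 1000, seed: int = 0) -> AgreementResults:
        per_cond = []
        for (param, subject, speed, placement), grp in self._iter_cells():
            per_cond.append({
                "parameter": param, "subject": subject, "speed": speed,
                "placement": placement,
                "rrmse": rrmse(grp[f"{param}_m1"], grp[f"{param}_m2"]),
                "m1_mean": grp[f"{param}_m1"].mean(),
                "m2_mean": grp[f"{param}_m2"].mean(),
                "n_cycles": len(grp)})
        per_cond = pd.DataFrame(per_cond)

        rr_rows, pe_rows, ba_rows = [], [], []
        for param in self.parameters:
            sub = per_cond[per_cond["parameter"] == param]
            for (speed, placement), cell in sub.groupby(["speed", "placement"]):
                s = summarize_rrmse(cell["rrmse"], n_boot=n_boot, seed=seed)
                rr_rows.append({"parameter": param, "speed": speed,
                                "placement": placement, **s})
                if len(cell) >= 3 and cell["m1_mean"].std() > 0:
                    pa = pearson_association(cell["m1_mean"], cell["m2_mean"])
                    pe_rows.append({"parameter": param, "speed": speed,
                                    "placement": placement, **pa,
                                    "stars": _stars(pa["p"])})
            for placement, cell in sub.groupby("placement"):
                if len(cell) < 2:
                    log.warning("Bland-Altman cell %s/%s has n=%d < 2; omitted",
                                param, placement, len(cell))
                    continue
                ba = bland_altman(cell["m1_mean"], cell["m2_mean"])
                ba_rows.append({"parameter": param, "placement": placement,
                                **ba, "n": len(cell)})

        results = AgreementResults(
            rrmse_table=pd.DataFrame(rr_rows),
            pearson_table=pd.DataFrame(pe_rows),
            bland_altman_table=pd.DataFrame(ba_rows),
            per_condition_rrmse=per_cond)
        results._ba_points = per_cond.rename(
            columns={"m1_mean": "m1", "m2_mean": "m2"})
        return results

    def _iter_cells(self):
        for param in self.parameters:
            cols = [f"{param}_m1", f"{param}_m2"]
            ok = self.paired.dropna(subset=cols)
            for key, grp in ok.groupby(["subject", "speed", "placement"]):
                if len(grp):
                    yield (param, *key), grp
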