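"""Agreement kernels vs independent brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitwin.agreement import (AgreementAnalysis, bland_altman, match_cycles,
                               pearson_association, rrmse, summarize_rrmse)


def cycle_frame(t_starts, stride=1.1, side="L"):
    rows = []
    for i, t0 in enumerate(t_starts):
        rows.append({"cycle_id": f"c{i}", "side": side, "t_start": t0,
                     "stride": stride, "stance": 0.62 * stride,
                     "swing": 0.38 * stride, "double_support": 0.13 * stride,
                     "valid": True, "exclusion_reason": "none"})
    return pd.DataFrame(rows)


class TestMatchCycles:
    def test_identical_sets_all_matched(self):
        a = cycle_frame([0.0, 1.1, 2.2])
        paired, dropped = match_cycles(a, a.copy())
        assert len(paired) == 3 and dropped == 0

    def test_small_offset_matched(self):
        a = cycle_frame([0.0, 1.1, 2.2])
        b = cycle_frame([0.05, 1.15, 2.25])
        paired, dropped = match_cycles(a, b)
        assert len(paired) == 3 and dropped == 0

    def test_spurious_cycle_dropped(self):
        a = cycle_frame([0.0, 1.1])
        b = cycle_frame([0.0, 0.55, 1.1])  # mid-stride extra
        paired, dropped = match_cycles(a, b)
        assert len(paired) == 2 and dropped == 1


class TestRrmse:
    def test_worked_example(self):
        assert rrmse([1.0, 1.0], [1.05, 0.95]) == pytest.approx(5.0)

    def test_identity_zero(self):
        assert rrmse([1.2, 1.3], [1.2, 1.3]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            rrmse([], [])
        with pytest.raises(ValueError):
            rrmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rrmse([-1.0, 1.0], [0.0, 0.0])

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        m1 = np.array([1.0, 1.1, 0.9])
        m2 = np.array([1.05, 1.0, 0.95])
        assert rrmse(c * m1, c * m2) == pytest.approx(rrmse(m1, m2), rel=1e-9)

    def test_against_brute_force(self):
        rng = np.random.default_rng(0)
        m1 = rng.uniform(0.9, 1.3, 20)
        m2 = m1 + rng.normal(0, 0.05, 20)
        manual = 100 * np.sqrt(np.sum((m2 - m1) ** 2) / 20) / (np.sum(m1) / 20)
        assert rrmse(m1, m2) == manual


class TestSummarizeRrmse:
    def test_constant_values(self):
        s = summarize_rrmse([10.0] * 6, seed=1)
        assert s["median"] == 10.0 and s["iqr"] == 0.0
        assert s["ci_low"] == 10.0 and s["ci_high"] == 10.0

    def test_right_skew_median_below_mean_ci(self):
        # enough outliers that virtually every bootstrap resample catches
        # one: the mean's CI then sits wholly above the sample median
        s = summarize_rrmse([1.0] * 15 + [20.0] * 5, n_boot=2000, seed=3)
        assert s["median"] == 1.0
        assert s["median"] < s["ci_low"]
        assert s["skewness"] > 1.0

    def test_seeded_ci_reproducible(self):
        a = summarize_rrmse([3.0, 5.0, 9.0, 2.0], seed=7)
        b = summarize_rrmse([3.0, 5.0, 9.0, 2.0], seed=7)
        assert a == b

    def test_too_few_values_flagged(self):
        s = summarize_rrmse([3.0, 5.0])
        assert not s["ci_ok"] and np.isnan(s["ci_low"])


class TestPearson:
    def test_perfect_linear(self):
        out = pearson_association([1, 2, 3, 4], [3, 5, 7, 9])
        assert out["r"] == pytest.approx(1.0)
        assert out["tier"] == "strong"
        out = pearson_association([1, 2, 3], [-1, -2, -3])
        assert out["r"] == pytest.approx(-1.0)

    def test_moderate_tier_exact_r(self):
        # construct x, e orthonormal so that y = r*x + sqrt(1-r^2)*e has
        # exactly the requested correlation with x
        x = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        e = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
        r = 0.45
        y = r * x + np.sqrt(1 - r ** 2) * e
        out = pearson_association(x, y)
        assert out["r"] == pytest.approx(0.45, abs=1e-12)
        assert out["tier"] == "moderate"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_association([1.0, 1.0, 1.0], [1, 2, 3])


class TestBlandAltman:
    def test_identical_series(self):
        out = bland_altman([1.0, 1.1], [1.0, 1.1])
        assert out["bias"] == 0.0
        assert out["loa_low"] == 0.0 == out["loa_high"]
        assert out["pct_within"] == 100.0

    def test_worked_example(self):
        out = bland_altman([1.01, 1.03], [1.00, 1.00])
        assert out["bias"] == pytest.approx(0.02)
        sd = np.std([0.01, 0.03], ddof=1)
        assert out["loa_low"] == pytest.approx(0.02 - 1.96 * sd)
        assert out["loa_high"] == pytest.approx(0.02 + 1.96 * sd)

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(11)
        m2 = np.zeros(1000)
        m1 = rng.normal(0, 0.05, 1000)
        out = bland_altman(m1, m2)
        assert out["pct_within"] == pytest.approx(95.0, abs=2.0)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


def synthetic_paired(n_subjects=6, seed=0):
    """Paired per-cycle frame over a 3x3 factorial with known noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        base = rng.uniform(1.0, 1.3)
        for speed in (1.0, 1.25, 1.5):
            for placement in ("hand", "trouser", "jacket"):
                for k in range(10):
                    stride = base * (1.25 / speed) ** 0.3
                    row = {"subject": f"S{s:02d}", "speed": speed,
                           "placement": placement, "t_start": 1.1 * k,
                           "side": "L"}
                    for p, scale in (("stride", 1.0), ("stance", 0.62),
                                     ("swing", 0.38), ("double_support", 0.13)):
                        m1 = scale * stride
                        row[f"{p}_m1"] = m1
                        row[f"{p}_m2"] = m1 + rng.normal(0, 0.01)
                    rows.append(row)
    return pd.DataFrame(rows)


class TestAgreementAnalysis:
    def test_report_structure(self):
        res = AgreementAnalysis(synthetic_paired()).fit(n_boot=200, seed=0)
        # 4 parameters x 3 speeds x 3 placements
        assert len(res.rrmse_table) == 36
        assert len(res.pearson_table) == 36
        assert len(res.bland_altman_table) == 12  # per parameter x placement
        assert set(res.rrmse_table.columns) >= {"median", "iqr", "ci_low", "ci_high"}

    def test_rerun_identical(self, tmp_path):
        for d in ("a", "b"):
            res = AgreementAnalysis(synthetic_paired()).fit(n_boot=100, seed=5)
            res.save_tables(tmp_path / d)
        for f in ("table1_rrmse.csv", "table2_pearson.csv", "bland_altman.csv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_bland_altman_reconstruction_from_saved_tables(self, tmp_path):
        """Bias/LoA in the saved CSV equal a brute-force recomputation from
        the per-condition values."""
        res = AgreementAnalysis(synthetic_paired()).fit(n_boot=100, seed=0)
        res.save_tables(tmp_path)
        saved = pd.read_csv(tmp_path / "bland_altman.csv")
        pc = res.per_condition_rrmse
        for _, row in saved.iterrows():
            sub = pc[(pc["parameter"] == row["parameter"]) &
                     (pc["placement"] == row["placement"])]
            d = (sub["m1_mean"] - sub["m2_mean"]).to_numpy()
            assert row["bias"] == pytest.approx(d.mean())
            assert row["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_missing_keys_rejected(self):
        with pytest.raises(ValueError):
            AgreementAnalysis(pd.DataFrame({"stride_m1": [1.0]}))

    def test_summary_mentions_all_parameters(self):
        res = AgreementAnalysis(synthetic_paired()).fit(n_boot=100, seed=0)
        text = res.summary()
        for p in ("stride", "stance", "swing", "double_support"):
            assert p in text
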