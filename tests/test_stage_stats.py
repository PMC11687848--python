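"""Gated paired statistics against the shipped arterial blood-gas table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsdive.stage_stats import (
    blood_gas_comparisons,
    descriptive_means,
    dive_minima,
    gated_compare,
    hb_all_pairs,
    paired_t,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from nirsdive.types import DiveEvents


def _points(table, analyte, a, b):
    wide = table.pivot(index="subject", columns="point", values=analyte)
    return wide[a].to_numpy(), wide[b].to_numpy()


class TestShapiroWilk:
    def test_sao2_bottom_contrast(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "C", "F")
        w, _ = shapiro_wilk(x - y)
        assert w == pytest.approx(0.701, abs=5e-4)

    def test_sao2_end_contrast(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "D", "G")
        w, _ = shapiro_wilk(x - y)
        assert w == pytest.approx(0.933, abs=2e-3)

    def test_normal_quantile_sample_is_normal(self):
        from scipy.stats import norm

        sample = norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, p = shapiro_wilk(sample)
        assert w > 0.99

    def test_too_small_sample_refused(self):
        with pytest.raises(ValueError, match="n >= 3"):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestPairedT:
    def test_sao2_end_contrast(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "D", "G")
        t, _, df, _ = paired_t(x, y)
        assert t == pytest.approx(1.687, abs=5e-4)
        assert df == 5

    def test_pao2_deep_dive_contrast(self, blood_gas):
        x, y = _points(blood_gas, "pao2", "F", "G")
        t, _, _, _ = paired_t(x, y)
        assert t == pytest.approx(5.634, abs=5e-4)

    def test_antisymmetry(self, blood_gas):
        x, y = _points(blood_gas, "paco2", "C", "D")
        assert paired_t(x, y)[0] == pytest.approx(-paired_t(y, x)[0])

    def test_identical_samples_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p, _, degenerate = paired_t(x, x)
        assert t == 0.0 and degenerate


class TestWilcoxon:
    def test_sao2_bottom_contrast_v_zero(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "C", "F")
        v, _, _ = wilcoxon_signed_rank(x, y)
        assert v == 0.0

    def test_six_positive_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.zeros(6)
        v, p, method = wilcoxon_signed_rank(x, y)
        assert v == 21.0
        assert p == pytest.approx(0.03125)
        assert method == "exact"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=12))
    def test_sign_flip_symmetry(self, diffs):
        d = np.array(diffs, dtype=float)
        if np.all(d == 0):
            return
        v1, _, _ = wilcoxon_signed_rank(d, np.zeros_like(d))
        v2, _, _ = wilcoxon_signed_rank(np.zeros_like(d), d)
        n_eff = np.count_nonzero(d)
        assert v1 + v2 == pytest.approx(n_eff * (n_eff + 1) / 2)

    def test_all_zero_differences_refused(self):
        x = np.ones(5)
        with pytest.raises(ValueError, match="all differences"):
            wilcoxon_signed_rank(x, x)


class TestGatedCompare:
    def test_nonnormal_dispatches_to_wilcoxon(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "C", "F")
        res = gated_compare(x, y)
        assert res.test_kind == "wilcoxon"
        assert res.statistic == 0.0

    def test_normal_dispatches_to_t(self, blood_gas):
        x, y = _points(blood_gas, "sao2", "D", "G")
        res = gated_compare(x, y)
        assert res.test_kind == "paired_t"

    def test_paco2_deep_contrast_statistic(self, blood_gas):
        x, y = _points(blood_gas, "paco2", "F", "G")
        res = gated_compare(x, y)
        assert res.test_kind == "paired_t"
        assert res.statistic == pytest.approx(3.044, abs=5e-4)


class TestBattery:
    def test_twelve_contrasts(self, blood_gas):
        results = blood_gas_comparisons(blood_gas)
        assert len(results) == 12

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("pao2 C-D", 6.683),
            ("pao2 C-F", -0.900),
            ("sao2 C-D", 4.058),
        ],
    )
    def test_known_statistics(self, blood_gas, label, expected):
        results = {r.label: r for r in blood_gas_comparisons(blood_gas)}
        assert results[label].statistic == pytest.approx(expected, abs=5e-4)

    def test_descriptive_means(self, blood_gas):
        means = descriptive_means(blood_gas).set_index(["analyte", "point"])
        row = means.loc[("sao2", "G")]
        assert row["mean"] == pytest.approx(63.7, abs=0.05)
        assert row["sd"] == pytest.approx(16.3, abs=0.05)


class TestHbAllPairs:
    def _table(self, hb_by_point):
        rows = []
        for point, values in hb_by_point.items():
            for subject, hb in enumerate(values, start=1):
                rows.append(
                    {"subject": subject, "point": point, "pao2": 100.0,
                     "paco2": 35.0, "sao2": 98.0, "hb": hb}
                )
        return pd.DataFrame(rows)

    def test_identical_hb_never_significant(self):
        table = self._table({p: [14.0] * 6 for p in "ABCDFG"})
        results = hb_all_pairs(table)
        assert len(results) == 15  # C(6, 2)
        assert not any(r.significant for r in results)

    def test_injected_shift_detected(self):
        base = [13.1, 14.2, 13.7, 14.9, 13.4, 14.5]
        jitter = [0.03, -0.02, 0.01, -0.03, 0.02, -0.01]  # zero-mean noise
        table = self._table(
            {"A": base, "B": [v + j for v, j in zip(base, jitter)],
             "G": [v + 2.5 for v in base]}
        )
        results = {r.label: r for r in hb_all_pairs(table)}
        assert results["hb A-G"].significant
        assert not results["hb A-B"].significant


class TestDiveMinima:
    def test_v_shaped_trace(self):
        t = np.arange(0, 200, 0.5)
        trace = np.abs(t - 100.0)
        ev = DiveEvents(start_time=50.0, end_time=150.0, depth=42.0)
        assert dive_minima(t, trace, ev) == 0.0

    def test_constant_trace(self):
        t = np.arange(0, 200, 0.5)
        ev = DiveEvents(start_time=50.0, end_time=150.0, depth=42.0)
        assert dive_minima(t, np.full(t.size, 7.7), ev) == 7.7

    def test_fully_masked_refused(self):
        t = np.arange(0, 200, 0.5)
        trace = np.full(t.size, np.nan)
        ev = DiveEvents(start_time=50.0, end_time=150.0, depth=42.0)
        with pytest.raises(ValueError, match="masked"):
            dive_minima(t, trace, ev)

    def test_synthetic_nadir_recovered(self, dive42):
        rec, events, truth = dive42
        from nirsdive.heart_rate import HeartRateExtractor
        from nirsdive.mbll import MBLLTransformer
        from nirsdive.spo2 import Spo2Estimator

        chromo = MBLLTransformer().fit(rec).transform(rec)
        hrx = HeartRateExtractor().fit(chromo)
        hrx.transform(chromo)
        series = Spo2Estimator().fit(chromo).transform(chromo, beats=hrx.beat_indices_)
        recovered = dive_minima(series.time, series.spo2, events, post_extension_s=5.0)
        true_min = dive_minima(truth.time, truth.sao2, events, post_extension_s=5.0)
        assert recovered == pytest.approx(true_min, abs=3.0)
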