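import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import fundusvasc as fv
from fundusvasc.errors import DegenerateDataError, InvalidSpecError
from fundusvasc.io import METRIC_NAMES


def brute_midrank(pooled, v):
    """Independent midrank: 1 + #(u < v) + (#(u == v) - 1)/2."""
    pooled = np.asarray(pooled, float)
    return 1 + np.sum(pooled < v) + (np.sum(pooled == v) - 1) / 2


def enumeration_mw(a, b):
    """Oracle: mean ranks, U (by pairwise counting), exact two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    mr_a = np.mean([brute_midrank(pooled, v) for v in a])
    mr_b = np.mean([brute_midrank(pooled, v) for v in b])
    # U1 = n1*n2 + n1(n1+1)/2 - R1 counts (a, b) pairs with a below b
    u1 = sum((x < y) + 0.5 * (x == y) for x in a for y in b)
    n = len(pooled)
    lo = hi = total = 0
    for idx in itertools.combinations(range(n), len(a)):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        u = sum((x < y) + 0.5 * (x == y) for x in ga for y in gb)
        total += 1
        lo += u <= u1 + 1e-9
        hi += u >= u1 - 1e-9
    p = min(1.0, 2 * min(lo, hi) / total)
    return mr_a, mr_b, u1, p


class TestMannWhitney:
    def test_separated_samples(self):
        res = fv.mann_whitney([1, 2], [3, 4])
        assert res.mean_rank_a == 1.5
        assert res.mean_rank_b == 3.5
        assert res.u == 0.0
        assert res.u1 + res.u2 == res.n1 * res.n2

    def test_identical_samples_symmetric(self):
        res = fv.mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.mean_rank_a == res.mean_rank_b
        assert res.p == 1.0

    def test_exact_p_matches_permutation_oracle(self):
        res = fv.mann_whitney([1, 3], [2, 4])
        mr_a, mr_b, u1, p = enumeration_mw([1, 3], [2, 4])
        assert res.mean_rank_a == pytest.approx(mr_a)
        assert res.mean_rank_b == pytest.approx(mr_b)
        assert res.u1 == pytest.approx(u1)
        assert res.p == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_sample_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
        a = rng.integers(0, 5, n1).astype(float)  # integer data force ties
        b = rng.integers(0, 5, n2).astype(float)
        res = fv.mann_whitney(a, b)
        mr_a, mr_b, u1, p = enumeration_mw(a, b)
        assert res.mean_rank_a == pytest.approx(mr_a)
        assert res.mean_rank_b == pytest.approx(mr_b)
        assert res.u1 == pytest.approx(u1)
        assert res.p == pytest.approx(p)

    def test_exact_matches_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            res = fv.mann_whitney(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_approximation_close_to_exact(self, seed):
        """For 8 <= N <= 12 without ties, normal-approx p is within 0.02."""
        rng = np.random.default_rng(seed + 100)
        n1 = rng.integers(4, 7)
        n2 = rng.integers(4, 7)
        a, b = rng.normal(size=n1), rng.normal(0.5, 1, size=n2)
        res = fv.mann_whitney(a, b)  # exact path (N <= 12)
        p_norm = 2 * norm.sf(abs(res.z))
        assert abs(p_norm - res.p) <= 0.02

    def test_rank_conservation(self):
        res = fv.mann_whitney([1.0, 2.0, 2.0, 7.0], [2.0, 3.0, 9.0])
        n = res.n1 + res.n2
        total = res.n1 * res.mean_rank_a + res.n2 * res.mean_rank_b
        assert total == pytest.approx(n * (n + 1) / 2)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidSpecError):
            fv.mann_whitney([], [1.0])


class TestWilcoxon:
    def test_symmetric_differences(self):
        res = fv.wilcoxon_signed_rank([1, 0], [0, 1])
        assert res.mean_rank_pos == 1.5
        assert res.mean_rank_neg == 1.5
        assert res.z == 0.0

    def test_all_positive_differences(self):
        res = fv.wilcoxon_signed_rank([3, 5, 9], [1, 2, 3])
        assert math.isnan(res.mean_rank_neg)
        assert res.w_neg == 0.0
        assert res.n_pos == 3

    def test_hand_computed_z(self):
        d = np.array([3, -1, 2, 5, -2, 4], float)
        res = fv.wilcoxon_signed_rank(d, np.zeros(6))
        # direct formula evaluation: |d| sorted = 1,2,2,3,4,5 so the two
        # |d|=2 values share midrank 2.5
        ranks = {1: 1.0, 2: 2.5, 3: 4.0, 4: 5.0, 5: 6.0}
        w_pos = ranks[3] + ranks[2] + ranks[5] + ranks[4]  # = 17.5
        m = 6
        mu = m * (m + 1) / 4
        tie = 2**3 - 2  # one tied pair (|d| = 2)
        var = m * (m + 1) * (2 * m + 1) / 24 - tie / 48
        z = (w_pos - mu - 0.5) / math.sqrt(var)
        assert res.w_pos == pytest.approx(w_pos)
        assert res.z == pytest.approx(z)

    def test_zero_differences_dropped(self):
        res = fv.wilcoxon_signed_rank([1, 2, 3, 4], [1, 2, 1, 1])
        assert res.n_zero == 2
        assert res.n_pos == 2
        assert res.n == 4

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            fv.wilcoxon_signed_rank([1, 2], [1, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-20, 20), min_size=3, max_size=15))
    def test_swapping_arguments_negates_z(self, diffs):
        a = np.array(diffs, float)
        b = np.zeros_like(a)
        if np.all(a == 0):
            return
        r1 = fv.wilcoxon_signed_rank(a, b)
        r2 = fv.wilcoxon_signed_rank(b, a)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.w_pos == pytest.approx(r2.w_neg)
        if r1.n_pos and r1.n_neg:
            assert r1.mean_rank_pos == pytest.approx(r2.mean_rank_neg)


class TestSampleSize:
    def test_rare_disease_needs_one_participant(self):
        params = fv.SampleSizeParams(confidence=0.95, p=0.00042, margin=0.05)
        assert fv.required_sample_size(params) == 1

    def test_worst_case_proportion(self):
        params = fv.SampleSizeParams(confidence=0.95, p=0.5, margin=0.05)
        assert fv.required_sample_size(params) == 385

    def test_nonincreasing_in_margin(self):
        sizes = [
            fv.required_sample_size(fv.SampleSizeParams(0.95, 0.3, m))
            for m in (0.01, 0.02, 0.05, 0.1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidSpecError):
            fv.SampleSizeParams(margin=0.0)
        with pytest.raises(InvalidSpecError):
            fv.SampleSizeParams(p=1.0)


def synthetic_table(rng, n_hc=20, n_rrd=15, shift=None):
    """A metrics table drawn directly from distributions (no imaging)."""
    rows = []
    for i in range(n_hc):
        rows.append(dict(image_id=f"hc{i}", group="HC", region="HC-cover",
                         **{m: rng.normal(10, 2) for m in METRIC_NAMES}))
    for i in range(n_rrd):
        for region in ("RRD", "non-RRD"):
            vals = {m: rng.normal(10, 2) for m in METRIC_NAMES}
            if shift and region == "RRD":
                vals = {m: v + shift.get(m, 0.0) for m, v in vals.items()}
            rows.append(dict(image_id=f"rrd{i}", group="RRD", region=region,
                             **vals))
    return pd.DataFrame(rows)


class TestCompareCohort:
    def test_report_shape(self):
        rng = np.random.default_rng(0)
        report = fv.compare_cohort(synthetic_table(rng))
        assert len(report) == len(METRIC_NAMES) * 3
        assert set(report["comparison"]) == {
            "HC vs RRD", "HC vs non-RRD", "RRD vs non-RRD"}

    def test_shifted_metric_detected(self):
        rng = np.random.default_rng(1)
        table = synthetic_table(rng, n_hc=40, n_rrd=30,
                                shift={"caliber_avg": -6.0})
        report = fv.compare_cohort(table).set_index(["metric", "comparison"])
        assert report.loc[("caliber_avg", "HC vs RRD"), "p"] < 0.001
        assert report.loc[("caliber_avg", "RRD vs non-RRD"), "p"] < 0.001
        assert report.loc[("density", "HC vs RRD"), "p"] > 0.001

    def test_null_false_positive_rate_calibrated(self):
        """Under no group effect ~5% of comparisons reject at alpha=0.05."""
        rng = np.random.default_rng(7)
        flags = []
        for _ in range(60):
            report = fv.compare_cohort(synthetic_table(rng))
            flags.extend(report["p"] < 0.05)
        rate = np.mean(flags)
        assert 0.015 <= rate <= 0.10

    def test_missing_regions_rejected(self):
        df = pd.DataFrame([{"image_id": "x", "group": "HC", "region": "whole",
                            **{m: 1.0 for m in METRIC_NAMES}}])
        with pytest.raises(InvalidSpecError):
            fv.compare_cohort(df)

    def test_radar_plot_written(self, tmp_path):
        rng = np.random.default_rng(3)
        out = tmp_path / "radar.png"
        fv.compare_cohort(synthetic_table(rng), radar_path=out)
        assert out.stat().st_size > 0

    def test_bonferroni_column_optional(self):
        rng = np.random.default_rng(4)
        rep = fv.compare_cohort(synthetic_table(rng), bonferroni=True)
        assert (rep["p_bonferroni"] >= rep["p"] - 1e-12).all()
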