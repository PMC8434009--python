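"""ERP summaries and the nonparametric test battery.

The Wilcoxon implementations are checked against brute-force enumeration of
their exact null distributions; BH adjustment against a hand-coded step-up.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from p300bci import (
    ErpWaveform,
    average_target_erp,
    compare_environments,
    describe,
    direction_mean_amplitude,
    fdr_bh,
    find_p300_peak,
    ks_normality,
    pearson_correlation,
    preference_group_accuracy,
    read_fixture_tables,
    summarize_records,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from p300bci.erp_stats import SubjectRecord, round2

from conftest import build_epochset  # noqa: E402


def waveform(trace: np.ndarray, fs: float = 100.0) -> ErpWaveform:
    return ErpWaveform(
        values=np.atleast_2d(trace),
        sampling_rate_hz=fs,
        channel_labels=("Pz",),
        n_epochs_averaged=1,
    )


# ---------------------------------------------------------------------------
# enumeration oracles


def signed_rank_p_by_enumeration(diffs: np.ndarray) -> float:
    d = diffs[diffs != 0]
    ranks = sstats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    n = len(d)
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = 2**n
    lower = sum(s <= w + 1e-9 for s in stats) / total
    upper = sum(s >= w - 1e-9 for s in stats) / total
    return min(1.0, 2 * min(lower, upper))


def rank_sum_p_by_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    combined = np.concatenate([a, b])
    ranks = sstats.rankdata(combined)
    n1 = len(a)
    w = ranks[:n1].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(combined)), n1)
    ]
    total = len(sums)
    lower = sum(s <= w + 1e-9 for s in sums) / total
    upper = sum(s >= w - 1e-9 for s in sums) / total
    return min(1.0, 2 * min(lower, upper))


def bh_stepup_by_hand(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------


class TestWaveformSummaries:
    def test_average_of_identical_epochs_is_that_epoch(self):
        epoch = np.random.default_rng(0).normal(size=(1, 2, 50))
        data = np.tile(epoch, (300, 1, 1))
        ep = build_epochset(data, targets=[True] * 300)
        erp = average_target_erp(ep)
        assert np.allclose(erp.values, epoch[0])
        assert erp.n_epochs_averaged == 300

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(1).normal(size=(1, 2, 30))
        ep = build_epochset(np.concatenate([x, -x]), targets=[True, True])
        assert np.allclose(average_target_erp(ep).values, 0.0)

    def test_empty_group_signaled(self):
        ep = build_epochset(np.zeros((3, 1, 10)), targets=[False] * 3)
        with pytest.raises(ValueError, match="no target"):
            average_target_erp(ep)

    def test_peak_found_at_template_latency(self):
        t = np.arange(100) * 10.0  # ms at 100 Hz
        trace = 10.0 * np.exp(-0.5 * ((t - 400) / 45) ** 2)
        pk = find_p300_peak(waveform(trace))
        assert pk.latency_ms == 400.0
        assert pk.amplitude_uv == pytest.approx(10.0)

    def test_monotone_trace_peaks_at_window_start(self):
        trace = -np.arange(100.0)
        pk = find_p300_peak(waveform(trace), window_ms=(250, 600))
        assert pk.latency_ms == 250.0

    def test_tied_maxima_take_the_earlier(self):
        trace = np.zeros(100)
        trace[35] = trace[45] = 5.0
        assert find_p300_peak(waveform(trace)).latency_ms == 350.0

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            find_p300_peak(waveform(np.zeros(100)), window_ms=(2000, 3000))

    def test_mean_amplitude_constant_trace(self):
        assert direction_mean_amplitude(waveform(np.full(100, 4.0))) == 4.0

    def test_mean_amplitude_linear_ramp_gives_midpoint(self):
        trace = np.arange(100) * 10.0  # value equals time in ms
        assert direction_mean_amplitude(waveform(trace)) == pytest.approx(400.0)

    def test_mean_amplitude_matches_index_range_oracle(self):
        trace = np.random.default_rng(2).normal(size=100)
        expected = trace[30:51].mean()  # samples 30..50 inclusive at 100 Hz
        assert direction_mean_amplitude(waveform(trace)) == pytest.approx(expected)

    def test_mean_parietal_policy_averages_pz_p3_p4(self):
        values = np.stack([np.full(100, v) for v in (1.0, 2.0, 3.0, 4.0, 5.0)])
        erp = ErpWaveform(
            values=values,
            sampling_rate_hz=100.0,
            channel_labels=("Fz", "Pz", "Oz", "P3", "P4"),
            n_epochs_averaged=1,
        )
        assert direction_mean_amplitude(erp, channel_policy="mean-parietal") == (
            pytest.approx((2.0 + 4.0 + 5.0) / 3)
        )


class TestDescribe:
    def test_population_sd_of_1_2_3(self):
        mean, sd = describe([1, 2, 3])
        assert mean == 2.0
        assert sd == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_single_value(self):
        assert describe([7.5]) == (7.5, 0.0)

    def test_empty_signaled(self):
        with pytest.raises(ValueError):
            describe([])

    def test_round2_half_away_from_zero(self):
        assert round2(6.215) == 6.22
        assert round2(-6.215) == -6.22
        assert round2(2.004) == 2.0


class TestKsNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert ks_normality(x).p_value > 0.05

    def test_uniform_sample_fails(self):
        x = np.random.default_rng(0).uniform(size=1000)
        assert ks_normality(x).p_value < 0.05

    def test_statistic_equals_cdf_gap_oracle(self):
        x = np.sort(np.random.default_rng(3).standard_normal(40))
        fitted = sstats.norm(x.mean(), x.std(ddof=1)).cdf(x)
        n = len(x)
        gap = max(
            np.max(np.arange(1, n + 1) / n - fitted),
            np.max(fitted - np.arange(0, n) / n),
        )
        assert ks_normality(x).statistic == pytest.approx(gap)

    def test_degenerate_sample_signaled(self):
        with pytest.raises(ValueError, match="zero variance"):
            ks_normality([2.0, 2.0, 2.0])


class TestSignedRank:
    def test_all_positive_six_differences_exact_p(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5, 6]))
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(2 / 64)

    def test_perfectly_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
        assert res.p_value == 1.0

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 9, 9])
        b = np.array([0.0, 0, 0, 0, 0, 0, 9, 9])
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 / 64)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=-9, max_value=9).filter(lambda v: v != 0),
            min_size=5,
            max_size=12,
        )
    )
    def test_matches_full_sign_enumeration(self, diffs):
        d = np.asarray(diffs, dtype=float)
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(signed_rank_p_by_enumeration(d))

    def test_large_sample_uses_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=40)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        ref = sstats.wilcoxon(d, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2, 3], [1.0, 2, 3]).p_value == 1.0

    def test_fully_separated_small_groups(self):
        res = wilcoxon_rank_sum([1.0, 2, 3], [10.0, 11, 12])
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    def test_matches_full_labeling_enumeration(self, a, b):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value == pytest.approx(rank_sum_p_by_enumeration(a, b))

    def test_large_sample_close_to_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=18), rng.normal(0.8, 1, size=15)
        res = wilcoxon_rank_sum(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestFdrBh:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.04]).tolist() == [0.04]

    def test_hand_worked_triplet(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(fdr_bh([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            p = rng.uniform(size=rng.integers(1, 12))
            assert np.allclose(fdr_bh(p), bh_stepup_by_hand(p))

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=10)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(4)
        res = pearson_correlation(rng.normal(size=500), rng.normal(size=500))
        assert abs(res.statistic) < 0.1

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert pearson_correlation(x, y).statistic == pytest.approx(r)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestSubjectTables:
    def test_preference_group_means_from_fixtures(self):
        groups = preference_group_accuracy(read_fixture_tables())
        assert groups["VR"]["n"] == 7
        assert groups["AR"]["n"] == 10
        assert groups["VR"]["mean_accuracy_vr"] == 93.09
        assert groups["AR"]["mean_accuracy_ar"] == 90.67
        # cross cells, recomputed from the table itself
        assert groups["VR"]["mean_accuracy_ar"] == 85.47
        assert groups["AR"]["mean_accuracy_vr"] == 89.33

    def test_single_group_mean_equals_overall_mean(self):
        records = [
            SubjectRecord(f"S{i}", 50.0 + i, 40.0 + i, False, False, "VR",
                          400.0, 400.0, 5.0, 5.0)
            for i in range(4)
        ]
        groups = preference_group_accuracy(records)
        assert set(groups) == {"VR"}
        assert groups["VR"]["mean_accuracy_vr"] == pytest.approx(51.5)

    def test_environment_comparison_flags_strong_shift(self):
        records = read_fixture_tables()
        shifted = [
            SubjectRecord(
                r.subject_id, r.accuracy_vr, r.accuracy_ar,
                r.sickness_vr, r.sickness_ar, r.preference,
                r.latency_vr, r.latency_vr + 20.0, r.amplitude_vr, r.amplitude_ar,
            )
            for r in records
        ]
        report = compare_environments(shifted)
        # every one of the 17 paired differences is -20: the exact signed-rank
        # test must call this highly significant
        assert report["fields"]["latency"]["signed_rank"]["p"] < 0.05

    def test_identical_field_reported_degenerate(self):
        records = [
            SubjectRecord(f"S{i}", 80.0, 80.0, False, False, "AR",
                          400.0 + i, 410.0 + 2 * i, 5.0 + i, 4.0 + i)
            for i in range(8)
        ]
        report = compare_environments(records)
        assert "degenerate" in report["fields"]["accuracy"]["signed_rank"]

    def test_summary_includes_all_group_statistics(self):
        summary = summarize_records(read_fixture_tables())
        assert summary["n_subjects"] == 17
        assert set(summary["preference_groups"]) == {"VR", "AR"}
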