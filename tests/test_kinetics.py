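from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from irmspread import (PhaseAnnotation, attachment_curve, endpoint_fractions,
                       make_cohort_table, phase_durations, wilcoxon_rank_sum)
from irmspread.simulate import simulate_cohort


def _cohort(times_by_substrate, censored_by_substrate=None):
    censored_by_substrate = censored_by_substrate or {}
    records = []
    for sub, times in times_by_substrate.items():
        cens = censored_by_substrate.get(sub, [False] * len(times))
        for i, (t, c) in enumerate(zip(times, cens)):
            records.append({
                "platelet_id": f"{sub}-{i}", "substrate": sub,
                "attachment_time": t, "censored": c,
                "filopodial_duration": np.nan,
                "lamellipodial_duration": np.nan,
                "endpoint_class": "fully_spread",
            })
    return make_cohort_table(records)


class TestAttachmentCurve:
    def test_forced_counting(self):
        cohort = _cohort({"collagen_iv": [10.0, 30.0]})
        curve = attachment_curve(cohort, "collagen_iv", np.array([5, 10, 30]))
        np.testing.assert_allclose(curve, [0.0, 50.0, 100.0])

    def test_all_censored_zero(self):
        cohort = _cohort({"fibrinogen": [100.0, 100.0]},
                         {"fibrinogen": [True, True]})
        curve = attachment_curve(cohort, "fibrinogen", np.array([50, 200, 500]))
        np.testing.assert_allclose(curve, 0.0)

    def test_scaled_empirical_cdf_properties(self, rng):
        times = rng.exponential(50, 200)
        cohort = _cohort({"s": list(times)})
        grid = np.linspace(1, 400, 80)
        curve = attachment_curve(cohort, "s", grid)
        assert np.all(np.diff(curve) >= 0)
        assert curve.min() >= 0 and curve.max() <= 100

    def test_dkw_band_recovers_generating_cdf(self, rng):
        n = 500
        scale = 60.0
        times = rng.exponential(scale, n)
        cohort = _cohort({"s": list(times)})
        grid = np.linspace(5, 600, 120)
        curve = attachment_curve(cohort, "s", grid) / 100.0
        cdf = 1 - np.exp(-grid / scale)
        eps = np.sqrt(np.log(2 / 0.05) / (2 * n))  # 95% DKW band
        assert np.max(np.abs(curve - cdf)) <= eps

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="no platelets"):
            attachment_curve(_cohort({"s": [1.0]}), "other", np.array([1.0]))


class TestPhaseDurations:
    def test_forced_arithmetic(self):
        ann = PhaseAnnotation("p", 0, filopodia_onset_frame=10,
                              lamellipodia_onset_frame=40, spread_frame=60,
                              endpoint_class="fully_spread")
        df = phase_durations([ann], frame_interval=5.0)
        assert df.loc[0, "filopodial_duration"] == 150.0
        assert df.loc[0, "lamellipodial_duration"] == 100.0

    def test_missing_stage_gives_missing_duration(self):
        ann = PhaseAnnotation("p", 0, filopodia_onset_frame=5,
                              lamellipodia_onset_frame=20,
                              endpoint_class="filopodial")
        df = phase_durations([ann], frame_interval=5.0)
        assert df.loc[0, "filopodial_duration"] == 75.0
        assert np.isnan(df.loc[0, "lamellipodial_duration"])

    def test_batch_matches_per_record_oracle(self, rng):
        anns = []
        for i in range(30):
            f = int(rng.integers(0, 10))
            l = f + int(rng.integers(0, 20))
            s = l + int(rng.integers(0, 30))
            anns.append(PhaseAnnotation(f"p{i}", 0, filopodia_onset_frame=f,
                                        lamellipodia_onset_frame=l,
                                        spread_frame=s,
                                        endpoint_class="fully_spread"))
        df = phase_durations(anns, frame_interval=2.0)
        for i, ann in enumerate(anns):
            assert df.loc[i, "filopodial_duration"] == pytest.approx(
                (ann.lamellipodia_onset_frame - ann.filopodia_onset_frame) * 2.0)


class TestEndpointFractions:
    def _cohort_of(self, classes):
        records = [{
            "platelet_id": f"p{i}", "substrate": "s",
            "attachment_time": np.nan, "censored": False,
            "filopodial_duration": np.nan, "lamellipodial_duration": np.nan,
            "endpoint_class": c} for i, c in enumerate(classes)]
        return make_cohort_table(records)

    def test_forced_counting(self):
        fracs, n = endpoint_fractions(
            self._cohort_of(["filopodial"] * 3 + ["fully_spread"]), "s")
        assert n == 4
        assert fracs == {"no_attach": 0.0, "filopodial": 0.75,
                         "fully_spread": 0.25}

    def test_single_record_unit_vector(self):
        fracs, n = endpoint_fractions(self._cohort_of(["no_attach"]), "s")
        assert n == 1
        assert sorted(fracs.values()) == [0.0, 0.0, 1.0]

    def test_multinomial_counting_oracle(self, rng):
        classes = ["no_attach", "filopodial", "fully_spread"]
        drawn = [classes[i] for i in rng.integers(0, 3, size=200)]
        fracs, n = endpoint_fractions(self._cohort_of(drawn), "s")
        assert n == 200
        assert sum(fracs.values()) == pytest.approx(1.0)
        for c in classes:
            assert fracs[c] == pytest.approx(drawn.count(c) / 200)


def enumeration_oracle(a, b):
    """Independent full-enumeration two-sided p for tie-free samples."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:len(a)].sum()
    n = len(pooled)
    ws = [sum(ranks[list(idx)]) for idx in combinations(range(n), len(a))]
    total = comb(n, len(a))
    le = sum(1 for w in ws if w <= w_obs + 1e-9)
    ge = sum(1 for w in ws if w >= w_obs - 1e-9)
    return min(1.0, 2 * min(le, ge) / total)


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0])
        assert res.method == "exact"
        assert res.p_value == 1.0

    def test_textbook_extreme_split(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)
        assert res.statistic == 3.0

    def test_statistic_is_rank_sum_with_midranks(self):
        res = wilcoxon_rank_sum([1, 1], [1, 2])
        # pooled midranks: 2, 2, 2, 4
        assert res.statistic == 4.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 2), (5, 5)])
    def test_matches_scipy_exact_on_tiefree(self, n1, n2, rng):
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        res = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 4), (3, 3), (4, 4)])
    def test_matches_enumeration_oracle_with_ties(self, n1, n2, rng):
        a = rng.integers(0, 3, size=n1).astype(float)
        b = rng.integers(0, 3, size=n2).astype(float)
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value == pytest.approx(enumeration_oracle(a, b), abs=1e-12)

    def test_exact_approx_agree_at_boundary(self, rng):
        # pooled n = 12 is the last exact size.  The rank-sum lattice steps
        # the two-sided p by up to ~0.09 between adjacent statistics there,
        # so the continuity-corrected normal approximation can only track the
        # doubled tail to about half a lattice step: the worst case over the
        # whole balanced 6+6 lattice is 0.0155, so 0.02 is the sharp bound.
        for _ in range(50):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = wilcoxon_rank_sum(a, b)
            assert exact.method == "exact"
            approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic", use_continuity=True)
            assert abs(exact.p_value - approx.pvalue) <= 0.02

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(1.0, 1.0, size=25)
        res = wilcoxon_rank_sum(a, b)
        res_t = wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert res.p_value == res_t.p_value
        assert res.statistic == res_t.statistic

    def test_large_shift_tiny_p(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "asymptotic"
        assert 0 < res.p_value < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestSimulatedCohort:
    def test_substrate_rate_difference_detected(self):
        cohort = simulate_cohort({"collagen_iv": 100, "fibrinogen": 100},
                                 rng=0)
        a = cohort.loc[cohort.substrate == "collagen_iv", "attachment_time"]
        b = cohort.loc[cohort.substrate == "fibrinogen", "attachment_time"]
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value < 0.015
        # collagen-like attaches faster
        assert a.median() < b.median()

    def test_censoring_at_horizon(self):
        cohort = simulate_cohort({"fibrinogen": 500}, rng=1, horizon=100.0)
        cens = cohort["censored"]
        assert cens.any()
        assert (cohort.loc[cens, "attachment_time"] == 100.0).all()
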