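"""Burden statistic, quartiles, loss/gain null, region and dispersion analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from cnburden import (assign_quartiles, cohort_association_tests, compute_burden,
                      ks_distance, ks_region_association, loss_gain_random_test,
                      multiregion_dispersion, region_carriers,
                      region_frequency_by_group, region_prevalence_within_patient)
from cnburden.burden import exact_2x2_p
from cnburden.calling import SEGMENT_COLUMNS, SegmentProfile
from cnburden.regions import Region

from conftest import make_bins, rng


def hypergeom_two_sided_p(a, b, c, d):
    """Independent oracle: full enumeration of 2x2 tables at fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)
    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def brute_force_ks(x, y):
    """Oracle: sup of |ECDF difference| evaluated at every pooled point."""
    x, y = np.sort(x), np.sort(y)
    pts = np.concatenate([x, y])
    return max(abs(np.searchsorted(x, t, side="right") / len(x)
                   - np.searchsorted(y, t, side="right") / len(y)) for t in pts)


def seg_profile(spans, chrom="1"):
    """Build a SegmentProfile from (n_bins, mean_log2, call) triples."""
    rows, pos = [], 0
    for n, m, call in spans:
        rows.append({"chrom": chrom, "start": pos * 500_000, "end": (pos + n) * 500_000,
                     "first_bin": pos, "last_bin": pos + n - 1, "n_bins": n,
                     "mean_log2": m, "call": call})
        pos += n
    return SegmentProfile(sample_id="s", segments=pd.DataFrame(rows, columns=SEGMENT_COLUMNS))


class TestComputeBurden:
    def test_all_neutral_is_zero(self):
        bins = make_bins({"1": 100})
        rec = compute_burden(seg_profile([(100, 0.0, 0)]), bins)
        assert rec.burden == rec.loss_pct == rec.gain_pct == 0.0

    def test_mode_divergence(self):
        bins = make_bins({"1": 100})
        prof = seg_profile([(10, -0.5, -1), (10, 0.5, 1), (80, 0.0, 0)])
        by_bin = compute_burden(prof, bins, mode="by_bin")
        assert (by_bin.burden, by_bin.loss_pct, by_bin.gain_pct) == (20.0, 10.0, 10.0)
        by_seg = compute_burden(prof, bins, mode="by_segment")
        assert by_seg.burden == pytest.approx(200 / 3)

    def test_sex_chromosome_segments_excluded(self):
        bins = make_bins({"1": 100, "X": 50}, sex=("X",))
        prof = seg_profile([(10, -0.5, -1), (90, 0.0, 0)])
        x_seg = seg_profile([(50, -0.5, -1)], chrom="X").segments
        prof.segments = pd.concat([prof.segments, x_seg], ignore_index=True)
        rec = compute_burden(prof, bins)
        assert rec.burden == 10.0   # X loss does not count

    def test_decomposition_exact_on_cohort(self, grch37_bins, small_cohort):
        from cnburden import call_sample
        for sid in list(small_cohort.counts)[:3]:
            rec = compute_burden(call_sample(small_cohort.counts[sid], grch37_bins,
                                             sample_id=sid), grch37_bins)
            assert rec.loss_pct + rec.gain_pct == pytest.approx(rec.burden, abs=1e-12)


class TestQuartiles:
    def test_eight_distinct_values_two_per_quartile(self):
        labels, bounds = assign_quartiles([1, 2, 3, 4, 5, 6, 7, 8])
        assert list(labels).count("Q1") == 2
        assert sorted(set(labels)) == ["Q1", "Q2", "Q3", "Q4"]
        assert bounds[0] < bounds[1] < bounds[2]

    def test_identical_values_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            labels, _ = assign_quartiles([5.0] * 8)
        assert set(labels) == {"Q1"}

    def test_boundary_values_fall_in_lower_quartile(self):
        b = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        labels, (q25, _, _) = assign_quartiles(b)
        assert labels[np.flatnonzero(b == q25)[0]] == "Q1" if q25 in b else True

    def test_permutation_invariance_and_balance(self):
        r = rng(15)
        b = r.normal(size=101)
        labels, _ = assign_quartiles(b)
        perm = r.permutation(101)
        labels_p, _ = assign_quartiles(b[perm])
        assert (np.asarray(labels)[perm] == np.asarray(labels_p)).all()
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([1, 2, 3])


class TestLossGainTest:
    @staticmethod
    def _df(loss, gain, quartile="Q1"):
        return pd.DataFrame({"quartile": [quartile], "loss_bins": [loss],
                             "gain_bins": [gain]})

    def test_balanced_counts_null_identity(self):
        with pytest.warns(UserWarning):   # other quartiles empty
            out = loss_gain_random_test(self._df(20, 20))
        assert out["odds_ratio"].iloc[0] == 1.0
        assert out["p"].iloc[0] == 1.0

    def test_fisher_method_matches_enumeration_oracle(self):
        with pytest.warns(UserWarning):
            out = loss_gain_random_test(self._df(30, 10), method="fisher")
        assert out["odds_ratio"].iloc[0] == pytest.approx(3.0)
        assert out["p"].iloc[0] == pytest.approx(hypergeom_two_sided_p(30, 10, 20, 20))

    def test_exact_2x2_equals_enumeration_on_random_tables(self):
        r = rng(16)
        for _ in range(60):
            a, b, c, d = (int(x) for x in r.integers(0, 31, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert exact_2x2_p([[a, b], [c, d]]) == pytest.approx(
                hypergeom_two_sided_p(a, b, c, d), abs=1e-9)

    def test_bh_step_up_adjustment(self):
        # quartile p-values (0.01, 0.02, 0.03, 0.04) all adjust to 0.04
        df = pd.DataFrame({"quartile": ["Q1", "Q2", "Q3", "Q4"],
                           "loss_bins": [0, 0, 0, 0], "gain_bins": [0, 0, 0, 0]})
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        # hand step-up: min over j>=i of p_j * m / j
        hand = [min(p * 4 / (j + 1) for j, p in enumerate([0.01, 0.02, 0.03, 0.04])
                    if j >= i) for i in range(4)]
        np.testing.assert_allclose(q, hand)
        np.testing.assert_allclose(q, [0.04] * 4)

    def test_binomial_is_default_and_conservative_null(self):
        r = rng(17)
        rejections = 0
        for _ in range(300):
            total = int(r.integers(150, 400))
            loss = int(r.binomial(total, 0.5))
            with pytest.warns(UserWarning):
                out = loss_gain_random_test(self._df(loss, total - loss))
            rejections += out["p"].iloc[0] <= 0.05
        assert rejections / 300 < 0.09


class TestKS:
    def test_identical_multisets_zero_distance(self):
        assert ks_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_distance_one(self):
        assert ks_distance([4, 5, 6], [1, 2, 3]) == 1.0

    def test_interleaved_half(self):
        assert ks_distance([1, 3], [2, 4]) == 0.5

    def test_matches_brute_force_on_random_samples(self):
        r = rng(18)
        for _ in range(50):
            x = r.normal(size=int(r.integers(2, 30)))
            y = r.normal(0.5, 1.2, size=int(r.integers(2, 30)))
            assert ks_distance(x, y) == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        r = rng(19)
        x, y = r.normal(size=15), r.normal(1, 1, size=20)
        assert ks_distance(np.exp(x), np.exp(y)) == pytest.approx(ks_distance(x, y))

    def test_region_association_table(self):
        burdens = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
        carriers = pd.DataFrame({"r1": [False, False, False, True, True, True],
                                 "rare": [True] + [False] * 5},
                                index=list("abcdef"))
        out = ks_region_association(burdens, carriers, min_freq=0.2)
        assert out["region"].tolist() == ["r1"]     # 'rare' below frequency cut
        assert out["D"].iloc[0] == 1.0


class TestRegions:
    def test_carrier_rule_one_bin_overlap_matching_direction(self, grch37_bins):
        region = Region("test", "8", 23.4, 24.0, -1)
        seg = pd.DataFrame([
            {"sample_id": "s1", "chrom": "8", "start": 0, "end": 0,
             "first_bin": grch37_bins.bin_span("8", 23_900_000, 24_400_000)[0],
             "last_bin": grch37_bins.bin_span("8", 23_900_000, 30_000_000)[1] - 1,
             "n_bins": 9, "mean_log2": -0.5, "call": -1},
            {"sample_id": "s2", "chrom": "8", "start": 0, "end": 0,   # gain, not loss
             "first_bin": grch37_bins.bin_span("8", 23_400_000, 24_000_000)[0],
             "last_bin": grch37_bins.bin_span("8", 23_400_000, 24_000_000)[1] - 1,
             "n_bins": 2, "mean_log2": 0.5, "call": 1},
            {"sample_id": "s3", "chrom": "8", "start": 0, "end": 0,   # elsewhere
             "first_bin": grch37_bins.bin_span("8", 40_000_000, 45_000_000)[0],
             "last_bin": grch37_bins.bin_span("8", 40_000_000, 45_000_000)[1] - 1,
             "n_bins": 10, "mean_log2": -0.5, "call": -1},
        ])
        carriers = region_carriers(seg, grch37_bins, [region])
        assert carriers["test"].tolist() == [True, False, False]

    def test_frequency_by_group_counts(self):
        carriers = pd.DataFrame({"r": [True, True, True, False]},
                                index=["p1", "p2", "p3", "p4"])
        groups = pd.Series(["A", "A", "A", "A"], index=carriers.index)
        freq = region_frequency_by_group(carriers, groups)
        assert freq.loc["A", "r"] == 75.0

    def test_region_absent_everywhere_zero_percent(self):
        carriers = pd.DataFrame({"r": [False] * 4}, index=list("wxyz"))
        groups = pd.Series(["A", "A", "B", "B"], index=carriers.index)
        assert (region_frequency_by_group(carriers, groups)["r"] == 0.0).all()

    def test_quartile_composition_sums_to_carrier_count(self):
        r = rng(20)
        carriers = pd.DataFrame({"r": r.random(40) < 0.4},
                                index=[f"p{i}" for i in range(40)])
        groups = pd.Series(r.choice(["Q1", "Q2", "Q3", "Q4"], size=40),
                           index=carriers.index)
        freq = region_frequency_by_group(carriers, groups)
        counts = (freq["r"] / 100 * groups.value_counts()).round().astype(int)
        assert counts.sum() == carriers["r"].sum()


class TestDispersion:
    def _core_df(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "burden", "is_index", "state"])

    def test_identical_cores_zero_sd(self):
        df = self._core_df([("p1", 10.0, True, "M0N0"), ("p1", 10.0, False, "M0N0"),
                            ("p1", 10.0, False, "M0N0")])
        disp, _ = multiregion_dispersion(df)
        assert disp["burden_sd"].iloc[0] == 0.0

    def test_two_core_sample_sd(self):
        df = self._core_df([("p1", 10.0, True, "M1low"), ("p1", 20.0, False, "M1low")])
        disp, _ = multiregion_dispersion(df)
        assert disp["burden_sd"].iloc[0] == pytest.approx(7.0710678, abs=1e-6)

    def test_singletons_excluded_and_counted(self):
        df = self._core_df([("p1", 10.0, True, "M0N0"),
                            ("p2", 5.0, True, "M1low"), ("p2", 6.0, False, "M1low")])
        disp, summary = multiregion_dispersion(df)
        assert summary["n_excluded_singleton"] == 1
        assert len(disp) == 1

    def test_degenerate_equal_sds_handled(self):
        df = self._core_df([("p1", 10.0, True, "M0N0"), ("p1", 10.0, False, "M0N0"),
                            ("p2", 8.0, True, "M1low"), ("p2", 8.0, False, "M1low")])
        _, summary = multiregion_dispersion(df)
        assert np.isnan(summary["kruskal_p"])


class TestPrevalence:
    def test_prevalence_counts(self):
        carriers = pd.DataFrame({"r": [True, True, True, True, True, True, True, False]},
                                index=[f"c{i}" for i in range(8)])
        patients = pd.Series(["p1"] * 4 + ["p2"] * 4, index=carriers.index)
        out = region_prevalence_within_patient(carriers, patients, ["r"])
        assert out["median_prevalence"].iloc[0] == pytest.approx((100 + 75) / 2)
        assert out["n_patients"].iloc[0] == 2

    def test_patients_without_carrier_core_excluded(self):
        carriers = pd.DataFrame({"r": [False, False, True, True]},
                                index=["c1", "c2", "c3", "c4"])
        patients = pd.Series(["p1", "p1", "p2", "p2"], index=carriers.index)
        out = region_prevalence_within_patient(carriers, patients, ["r"])
        assert out["n_patients"].iloc[0] == 1
        assert out["median_prevalence"].iloc[0] == 100.0


class TestAssociations:
    @staticmethod
    def _index_df(r, n=120, shift=0.0):
        state = r.choice(["M0N0", "M0N1", "M1low", "M1high"], size=n)
        is_m1 = np.char.startswith(state.astype(str), "M1")
        burden = np.abs(r.normal(12, 5, n)) + shift * is_m1
        gain = burden * r.uniform(0, 0.5, n)
        return pd.DataFrame({
            "burden": burden, "loss_pct": burden - gain, "gain_pct": gain,
            "state": state, "grading_group": r.integers(1, 6, n),
            "psa": np.exp(r.normal(3, 1, n)), "age": r.normal(67, 7, n),
            "cellularity": r.uniform(40, 100, n)})

    def test_identical_groups_null_center(self):
        r = rng(21)
        df = self._index_df(r)
        # force identical burden multisets in M0 and M1
        m1 = df["state"].str.startswith("M1")
        vals = df.loc[~m1, "burden"].to_numpy()[:m1.sum()]
        df.loc[m1, "burden"] = np.resize(vals, m1.sum())
        out = cohort_association_tests(df)
        res = out["burden_M0_vs_M1"]
        assert res["median_M0"] == pytest.approx(res["median_M1"], rel=0.2)
        assert res["p"] > 0.05

    def test_shifted_m1_burden_detected(self):
        r = rng(22)
        out = cohort_association_tests(self._index_df(r, n=300, shift=7.0))
        assert out["burden_M0_vs_M1"]["p"] < 0.05
        assert out["burden_M0_vs_M1"]["median_M1"] > out["burden_M0_vs_M1"]["median_M0"]
        assert out["sqrt_burden_regressions"]["is_m1"]["p"] < 0.05

    def test_ranksum_pvalues_uniform_under_null(self):
        from scipy import stats
        r = rng(23)
        pvals = []
        for _ in range(300):
            a, b = r.normal(size=30), r.normal(size=30)
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
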