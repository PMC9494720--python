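"""The M1-M9 selection cascade, region counting, merging, ANOVA filter."""

import numpy as np
import pytest
from scipy import stats

import gaitnirs as g
from gaitnirs.core import ValidationError
from gaitnirs.regions import REGION_MAP, regions_containing
from gaitnirs.selection import FeatureSpec


def random_matrices(rng, n=2):
    return [rng.normal(size=(6, 22)) for _ in range(n)]


class TestSelectionMatrices:
    def test_two_value_toy_cv(self, rng):
        # per-cell values 1 and 3: mean 2, sample sd sqrt(2), CV 0.7071
        sel = g.build_selection_matrices([np.full((6, 22), 1.0), np.full((6, 22), 3.0)])
        np.testing.assert_allclose(sel.M1, 2.0)
        np.testing.assert_allclose(sel.M2, np.sqrt(2) / 2)

    def test_mask_counts_are_66_26_26(self, rng):
        for _ in range(5):
            sel = g.build_selection_matrices(random_matrices(rng, 3))
            assert sel.M3.sum() == 66  # floor(0.5 * 132)
            assert sel.M4.sum() == 26  # floor(0.2 * 132)
            assert sel.M5.sum() == 26

    def test_masks_match_sort_based_oracle(self, rng):
        mats = random_matrices(rng, 3)
        sel = g.build_selection_matrices(mats)
        m1 = np.mean(mats, axis=0).ravel()
        # oracle: 26th largest value is the inclusion threshold; ties by index
        order = sorted(range(132), key=lambda i: (-m1[i], i))
        expected_top = np.zeros(132, bool)
        expected_top[order[:26]] = True
        np.testing.assert_array_equal(sel.M4.ravel(), expected_top)

    def test_combined_masks_are_elementwise_and(self, rng):
        sel = g.build_selection_matrices(random_matrices(rng, 2))
        assert (sel.M6 <= sel.M3).all() and (sel.M6 <= sel.M4).all()
        assert (sel.M7 <= sel.M3).all() and (sel.M7 <= sel.M5).all()
        np.testing.assert_array_equal(sel.M6, sel.M3 & sel.M4)

    def test_zero_mean_cell_gets_infinite_cv(self):
        a = np.ones((6, 22)); a[0, 0] = 1.0
        b = np.ones((6, 22)); b[0, 0] = -1.0  # only this cell has zero mean
        sel = g.build_selection_matrices([a, b])
        assert np.isinf(sel.M2[0, 0])
        assert not sel.M3[0, 0]  # never counted as stable

    def test_identical_matrices_give_zero_cv_everywhere(self, rng):
        m = rng.normal(size=(6, 22))
        sel = g.build_selection_matrices([m, m])
        np.testing.assert_allclose(sel.M2, 0.0)
        assert sel.M3.sum() == 66

    def test_single_matrix_rejected(self, rng):
        with pytest.raises(ValidationError):
            g.build_selection_matrices(random_matrices(rng, 1))


class TestRegionize:
    def test_region_map_has_22_regions_of_3_channels(self):
        assert len(REGION_MAP) == 22
        assert all(len(ch) == 3 for ch in REGION_MAP.values())
        assert REGION_MAP[1] == (1, 3, 6)

    def test_flagged_channels_counted_in_region(self):
        M6 = np.zeros((6, 22), bool)
        M6[0, 0] = M6[0, 2] = True  # ch1 and ch3 in band 1
        M8, M9 = g.regionize(M6, np.zeros_like(M6))
        assert M8[0, 0] == 2  # Re1 = {ch1, ch3, ch6}
        assert M9.sum() == 0

    def test_all_zero_mask_gives_all_zero_counts(self):
        M8, M9 = g.regionize(np.zeros((6, 22), bool), np.zeros((6, 22), bool))
        assert M8.sum() == 0 and M9.sum() == 0

    def test_single_channel_propagates_to_every_containing_region(self):
        M6 = np.zeros((6, 22), bool)
        M6[1, 5] = True  # ch6 in band 2
        M8, _ = g.regionize(M6, np.zeros_like(M6))
        hit_regions = {r for r in REGION_MAP if M8[1, r - 1] == 1}
        assert hit_regions == set(regions_containing(6)) == {1, 2, 3, 9, 10}

    def test_counts_match_membership_scan_oracle(self, rng):
        M6 = rng.random((6, 22)) < 0.3
        M7 = rng.random((6, 22)) < 0.3
        M8, M9 = g.regionize(M6, M7)
        for band in range(6):
            for region, chans in REGION_MAP.items():
                assert M8[band, region - 1] == sum(M6[band, c - 1] for c in chans)
                assert M9[band, region - 1] == sum(M7[band, c - 1] for c in chans)


class TestFrequencySelection:
    def _per_subject(self, flag_counts, band=0, region=0, n=20):
        """n subjects; the first len(flag_counts) have the given counts in one cell."""
        out = []
        for i in range(n):
            M8 = np.zeros((6, 22), int)
            if i < len(flag_counts):
                M8[band, region] = flag_counts[i]
            out.append((M8, np.zeros((6, 22), int)))
        return out

    def test_12_of_20_subjects_selects(self):
        specs = g.cohort_frequency_selection(self._per_subject([1] * 12), "totalHb")
        assert [s.region for s in specs] == [1]
        assert specs[0].polarity == "top" and specs[0].bands == (1,)

    def test_11_of_20_subjects_does_not_select(self):
        assert g.cohort_frequency_selection(self._per_subject([1] * 11), "totalHb") == []

    def test_threshold_recomputed_for_other_cohort_sizes(self):
        # ceil(0.6 * 6) = 4
        assert g.cohort_frequency_selection(self._per_subject([1] * 4, n=6), "totalHb")
        assert not g.cohort_frequency_selection(self._per_subject([1] * 3, n=6), "totalHb")

    def test_key_count_is_mode_with_ties_to_smaller(self):
        specs = g.cohort_frequency_selection(
            self._per_subject([1] * 10 + [2] * 4), "totalHb"
        )
        assert specs[0].key_counts == (1,)
        specs = g.cohort_frequency_selection(
            self._per_subject([1] * 7 + [2] * 7), "totalHb"
        )
        assert specs[0].key_counts == (1,)  # tie -> smaller
        specs = g.cohort_frequency_selection(
            self._per_subject([1] * 7 + [2] * 7), "totalHb", key_count_rule="max"
        )
        assert specs[0].key_counts == (2,)


class TestMerging:
    def _spec(self, region, band, kc=1, polarity="top", kind="totalHb"):
        return FeatureSpec(region, polarity, (band,), (kc,), kind)

    def test_adjacent_bands_merge_with_table_notation(self):
        merged = g.merge_contiguous_bands([self._spec(4, 1), self._spec(4, 2)])
        assert len(merged) == 1
        assert merged[0].bands == (1, 2)
        assert merged[0].notation == "Re4: pd1(1) + pd2(1)"

    def test_merge_never_crosses_the_009_hz_boundary(self):
        merged = g.merge_contiguous_bands([self._spec(5, 3), self._spec(5, 4)])
        assert sorted(m.bands for m in merged) == [(3,), (4,)]

    def test_isolated_spec_unchanged(self):
        spec = self._spec(7, 2)
        assert g.merge_contiguous_bands([spec]) == [spec]

    def test_different_polarities_never_merge(self):
        merged = g.merge_contiguous_bands(
            [self._spec(4, 1, polarity="top"), self._spec(4, 2, polarity="bottom")]
        )
        assert len(merged) == 2

    def test_cross_part_spec_unconstructible(self):
        with pytest.raises(ValidationError):
            FeatureSpec(1, "top", (3, 4), (1, 1), "totalHb")


class TestExtraction:
    def test_top_and_bottom_extraction(self):
        matrix = np.zeros((6, 22))
        cols = [c - 1 for c in REGION_MAP[1]]
        matrix[0, cols] = [0.5, 0.2, -0.1]
        top1 = FeatureSpec(1, "top", (1,), (1,), "totalHb")
        bottom2 = FeatureSpec(1, "bottom", (1,), (2,), "totalHb")
        assert g.extract_feature_value(matrix, top1) == pytest.approx(0.5)
        assert g.extract_feature_value(matrix, bottom2) == pytest.approx(0.05)

    def test_merged_spec_averages_per_band_values(self):
        matrix = np.zeros((6, 22))
        cols = [c - 1 for c in REGION_MAP[1]]
        matrix[0, cols] = [0.5, 0.0, 0.0]
        matrix[1, cols] = [0.3, 0.0, 0.0]
        spec = FeatureSpec(1, "top", (1, 2), (1, 1), "totalHb")
        assert g.extract_feature_value(matrix, spec) == pytest.approx(0.4)

    def test_concat_mode_returns_per_band_values(self):
        matrix = np.random.default_rng(0).normal(size=(6, 22))
        spec = FeatureSpec(1, "top", (1, 2), (1, 1), "totalHb")
        per_band = g.extract_feature_value(matrix, spec, mode="concat")
        assert per_band.shape == (2,)
        assert np.mean(per_band) == pytest.approx(g.extract_feature_value(matrix, spec))


class TestAnovaFilter:
    def test_separated_groups_retained(self):
        values = {"f": {"A": [0, 0.01, 0, 0.01], "B": [1, 1.01, 1, 0.99]}}
        retained, pvals = g.anova_filter(values)
        assert retained == ["f"]
        assert pvals["f"]["A|B"] < 1e-6

    def test_identical_groups_not_retained(self):
        values = {"f": {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}}
        retained, _ = g.anova_filter(values)
        assert retained == []

    def test_degenerate_zero_variance_equal_means_is_p_one(self):
        values = {"f": {"A": [2.0, 2.0], "B": [2.0, 2.0]}}
        retained, pvals = g.anova_filter(values)
        assert retained == [] and pvals["f"]["A|B"] == 1.0

    def test_two_group_f_equals_squared_t_oracle(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        _, pvals = g.anova_filter({"f": {"A": a, "B": b}})
        t, p_t = stats.ttest_ind(a, b)
        # one-way ANOVA on two groups is the squared two-sample t test
        f, p_f = stats.f_oneway(a, b)
        assert f == pytest.approx(t**2)
        assert pvals["f"]["A|B"] == pytest.approx(p_t)
        assert pvals["f"]["A|B"] == pytest.approx(0.3466, abs=1e-4)

    def test_shuffled_labels_pass_at_the_null_rate(self, rng):
        # with exchangeable data the pass rate of the any-pair rule must sit
        # within binomial bounds of the same rate measured on independent
        # null draws
        def pass_rate(n_specs, rng):
            passed = 0
            for _ in range(n_specs):
                vals = {"f": {c: rng.normal(size=6) for c in "ABC"}}
                retained, _ = g.anova_filter(vals)
                passed += bool(retained)
            return passed

        n_ref = 4000
        p_hat = pass_rate(n_ref, rng) / n_ref
        n_obs = 150
        observed = pass_rate(n_obs, rng)
        sd = np.sqrt(n_obs * p_hat * (1 - p_hat))
        assert abs(observed - n_obs * p_hat) < 2.58 * sd + 1

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValidationError):
            g.anova_filter({"f": {"A": [1.0], "B": [1.0, 2.0]}})


class TestCohortSelection:
    def test_injected_effect_region_is_selected(self, effect_cohort, effect_featmats):
        # speed effect: totalHb, channel 15, bands 5-6 -> a retained spec
        # must cover one of the regions containing channel 15 in band 5 or 6
        config, _ = effect_cohort
        result = g.select_features(
            effect_featmats, config.subject_ids[:6], "walking_speed"
        )
        target_regions = set(regions_containing(15))
        assert any(
            s.signal_kind == "totalHb"
            and s.region in target_regions
            and ({5, 6} & set(s.bands))
            for s in result.specs
        )

    def test_selection_uses_only_given_subjects(self, effect_cohort, effect_featmats):
        config, _ = effect_cohort
        r1 = g.select_features(effect_featmats, config.subject_ids[:6], "walking_speed")
        r2 = g.select_features(effect_featmats, config.subject_ids[:6], "walking_speed")
        assert [s.to_dict() for s in r1.specs] == [s.to_dict() for s in r2.specs]
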