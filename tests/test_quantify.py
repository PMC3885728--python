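"""Quantification readouts: caliper volume, percent change, ANOVA, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fmtomo
from fmtomo.phantom import SourceVolume, simulate_study
from fmtomo.quantify import (
    GroupComparison,
    caliper_volume,
    compare_groups,
    first_significant_day,
    longitudinal_report,
    percent_change,
    summarize_recon,
)


class TestCaliperVolume:
    def test_printed_formula(self):
        assert caliper_volume(10, 5) == 125.0

    def test_sphere_like_degenerate_case(self):
        r = 7.37
        assert caliper_volume(r, r) == pytest.approx(0.5 * r ** 3)
        assert caliper_volume(7.37, 7.37) == pytest.approx(200.0, rel=0.01)

    def test_swapped_diameters_rejected(self):
        with pytest.raises(ValueError, match="swapped"):
            caliper_volume(5, 10)

    @given(
        a=st.floats(1.0, 30.0),
        delta=st.floats(0.0, 10.0),
        eps=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_each_argument(self, a, delta, eps):
        b = a  # keep b <= a
        assert caliper_volume(a + delta + eps, b) > caliper_volume(a + delta, b)
        assert caliper_volume(a + eps, min(b + eps, a + eps)) > caliper_volume(a + eps, b)


class TestPercentChange:
    def test_definitional_example(self):
        assert percent_change(100, 65.3) == pytest.approx(34.7)

    def test_published_scale_means(self):
        # day-12 group means 7.8e6 vs 5.6e6 give a 28.2% decrease
        assert percent_change(7.8e6, 5.6e6) == pytest.approx(28.2, abs=0.05)

    def test_identity_gives_zero(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    def test_monotone_in_value(self):
        assert percent_change(10, 4) > percent_change(10, 5)


class TestSummarizeRecon:
    def test_single_voxel_power_and_volume(self):
        y = np.zeros((4, 4, 4))
        y[1, 2, 3] = 2.0
        s = summarize_recon(SourceVolume(voxel_size=0.5, yield_=y))
        assert s.total_power == pytest.approx(0.125 * 2.0)
        assert s.volume_mm3 == pytest.approx(0.125)
        np.testing.assert_allclose(s.centroid_mm, [0.75, 1.25, 1.75])

    def test_recon_equal_to_truth_has_zero_localization_error(self):
        _, truth = fmtomo.make_phantom()
        recon = SourceVolume(voxel_size=truth.voxel_size, yield_=truth.yield_.copy())
        s = summarize_recon(recon, truth=truth)
        assert s.localization_error_mm == pytest.approx(0.0, abs=0.05)

    def test_all_zero_recon_flagged(self):
        s = summarize_recon(SourceVolume(voxel_size=0.5, yield_=np.zeros((3, 3, 3))))
        assert s.total_power == 0.0 and s.volume_mm3 == 0.0
        assert s.centroid_mm is None and s.localization_error_mm is None

    def test_half_maximum_volume_close_to_sphere_for_clean_truth(self):
        _, truth = fmtomo.make_phantom(tumor_radius=2.0)
        recon = SourceVolume(voxel_size=truth.voxel_size, yield_=truth.yield_.copy())
        s = summarize_recon(recon, threshold_frac=0.5)
        sphere = 4.0 / 3.0 * np.pi * 2.0 ** 3
        assert s.volume_mm3 == pytest.approx(sphere, rel=0.3)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            summarize_recon(SourceVolume(voxel_size=0.5, yield_=np.ones((2, 2, 2))),
                            threshold_frac=1.5)


def two_group_frame(vals_a, vals_b, day=0, metric_col="intensity"):
    rows = []
    for i, v in enumerate(vals_a):
        rows.append((f"C{i}", "control", day, v, 8.0, 6.0, 20.0))
    for i, v in enumerate(vals_b):
        rows.append((f"T{i}", "treated", day, v, 8.0, 6.0, 20.0))
    df = pd.DataFrame(rows, columns=["animal_id", "group", "day", "intensity",
                                     "a_mm", "b_mm", "weight_g"])
    return df


class TestCompareGroups:
    def test_hand_computed_anova(self):
        cmp = compare_groups(two_group_frame([1, 2, 3], [4, 5, 6]), "intensity", 0)
        assert cmp.F == pytest.approx(13.5)
        assert cmp.p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_identical_groups_null(self):
        cmp = compare_groups(two_group_frame([1, 2, 3], [1, 2, 3]), "intensity", 0)
        assert cmp.F == pytest.approx(0.0, abs=1e-12)
        assert not cmp.significant

    def test_two_group_anova_equals_squared_t(self, rng):
        a = rng.normal(5, 1, 8)
        b = rng.normal(6, 1, 8)
        cmp = compare_groups(two_group_frame(a, b), "intensity", 0)
        t, p = stats.ttest_ind(a, b)
        assert cmp.F == pytest.approx(t ** 2, rel=1e-10)
        assert cmp.p == pytest.approx(p, rel=1e-10)

    def test_zero_variance_differing_means(self):
        cmp = compare_groups(two_group_frame([2, 2, 2], [3, 3, 3]), "intensity", 0)
        assert cmp.p == 0.0 and cmp.F == np.inf and cmp.significant

    def test_invariance_to_relabeling_and_shift(self, rng):
        a = rng.normal(5, 1, 6)
        b = rng.normal(7, 1, 6)
        p1 = compare_groups(two_group_frame(a, b), "intensity", 0).p
        p2 = compare_groups(two_group_frame(np.random.default_rng(5).permutation(a), b),
                            "intensity", 0).p
        p3 = compare_groups(two_group_frame(a + 100.0, b + 100.0), "intensity", 0).p
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert p1 == pytest.approx(p3, rel=1e-9)

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(two_group_frame([1.0], [2.0]), "intensity", 0)


class TestFirstSignificantDay:
    def _comps(self, sig_by_day):
        return [
            GroupComparison(day=d, metric="intensity", group_means={}, group_sds={},
                            n_per_group={}, F=1.0, p=0.01 if s else 0.5)
            for d, s in sig_by_day.items()
        ]

    def test_persistence_rule_skips_transient_significance(self):
        comps = self._comps({0: False, 4: True, 8: False, 12: True})
        assert first_significant_day(comps) == 12
        assert first_significant_day(comps, persistent=False) == 4

    def test_sustained_divergence_from_day8(self):
        comps = self._comps({0: False, 4: False, 8: True, 12: True})
        assert first_significant_day(comps) == 8

    def test_none_when_never_significant(self):
        assert first_significant_day(self._comps({0: False, 4: False})) is None


class TestLongitudinalReport:
    def test_equal_rates_noise_free_has_no_significant_day(self):
        study = simulate_study(n_per_group=4, growth_rate_treated=0.13,
                               growth_rate_control=0.13,
                               animal_cv=0.0, measurement_cv=0.0, seed=0)
        # identical dynamics; tiny baseline spread is zero so F degenerates to 0
        rep = longitudinal_report(study)
        assert rep["metrics"]["intensity"]["first_significant_day"] is None

    def test_growth_rate_estimates_recover_generator_rates(self):
        study = simulate_study(n_per_group=4, animal_cv=0.0, measurement_cv=0.0, seed=0)
        rep = longitudinal_report(study)
        assert rep["group_mean_growth_rates"]["control"] == pytest.approx(0.13, rel=1e-6)
        assert rep["group_mean_growth_rates"]["treated"] == pytest.approx(0.078, rel=1e-6)

    def test_missing_days_reported_not_interpolated(self):
        study = simulate_study(n_per_group=3, seed=1)
        study = study[study["day"] != 8].reset_index(drop=True)
        rep = longitudinal_report(study, expected_days=(0, 4, 8, 12))
        assert rep["missing_days"] == [8]
        assert 8 not in rep["days"]

    def test_plot_study_writes_figure(self, tmp_path):
        from fmtomo.quantify import plot_study

        study = simulate_study(n_per_group=3, seed=4)
        out = plot_study(study, tmp_path / "study.png")
        assert out.exists() and out.stat().st_size > 0

    def test_strong_separation_detected(self):
        study = simulate_study(n_per_group=12, growth_rate_control=0.4,
                               growth_rate_treated=0.05,
                               animal_cv=0.05, measurement_cv=0.05, seed=2)
        rep = longitudinal_report(study)
        assert rep["metrics"]["intensity"]["first_significant_day"] == 4
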