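"""Histogram densitometry, percentile indices and threshold derivations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmodens.densitometry import (
    DensityHistogram,
    EmptyLungError,
    PercentileProfile,
    cumulative,
    delta_hu_profile,
    derive_hypo_upper_limit,
    derive_normo_lower_limit,
    derive_staging_threshold,
    histogram,
    histogram_percentile,
    percentile_hu,
    percentile_profile,
    select_discriminative_percentiles,
    summarize,
)

from .conftest import lung_ct


def _hist_from_counts(counts, lo=-1000.0, width=10.0, extra_out_of_range=0):
    counts = np.asarray(counts, dtype=np.int64)
    edges = lo + width * np.arange(counts.size + 1)
    return DensityHistogram(
        bin_edges=edges,
        counts=counts,
        total=int(counts.sum()) + extra_out_of_range,
        out_of_range_count=extra_out_of_range,
    )


class TestSummarize:
    def test_direct_arithmetic(self):
        ct, m = lung_ct([-800.0, -600.0, -400.0])
        s = summarize(ct, m)
        assert (s.mean_hu, s.min_hu, s.max_hu) == (-600.0, -800.0, -400.0)

    def test_single_voxel_sd_zero(self):
        ct, m = lung_ct([-500.0])
        assert summarize(ct, m).sd_hu == 0.0

    def test_airways_excluded(self):
        ct, m = lung_ct([-800.0, -600.0, 0.0])
        m.labels[0, 0, 2] = 2  # relabel the dense voxel as airway
        s = summarize(ct, m)
        assert s.mean_hu == pytest.approx(-700.0)
        assert s.volume_mm3 == pytest.approx(2 * 0.05**3)

    def test_empty_lung_errors(self):
        ct, m = lung_ct([-500.0])
        m.labels[:] = 0
        with pytest.raises(EmptyLungError):
            summarize(ct, m)

    def test_phantom_mean_matches_mixture(self, small_healthy_phantom):
        """Measured lung mean HU agrees with the analytic mixture mean."""
        from scipy import stats as sps

        from pulmodens.phantom import HEALTHY_MIXTURE, HEALTHY_SUPPORT

        _, ct, truth = small_healthy_phantom
        lo, hi = HEALTHY_SUPPORT
        expected = sum(
            w * sps.truncnorm.mean((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
            for w, mu, sd in HEALTHY_MIXTURE
        )
        assert summarize(ct, truth.lung_map).mean_hu == pytest.approx(expected, abs=5)


class TestHistogram:
    def test_default_is_100_bins(self):
        ct, m = lung_ct([-500.0])
        assert histogram(ct, m).n_bins == 100

    def test_brute_force_binning(self):
        ct, m = lung_ct([-995.0, -985.0, -5.0])
        h = histogram(ct, m)
        assert h.counts[0] == 1 and h.counts[1] == 1 and h.counts[-1] == 1
        assert h.counts.sum() == 3

    def test_zero_hu_in_final_right_closed_bin(self):
        ct, m = lung_ct([0.0])
        h = histogram(ct, m)
        assert h.counts[-1] == 1 and h.out_of_range_count == 0

    def test_out_of_range_tracked(self):
        ct, m = lung_ct([-500.0, 50.0, -1020.0])
        h = histogram(ct, m)
        assert h.out_of_range_count == 2
        assert h.counts.sum() + h.out_of_range_count == h.total == 3

    def test_non_divisible_range_rejected(self):
        ct, m = lung_ct([-500.0])
        with pytest.raises(ValueError):
            histogram(ct, m, bin_width=7.0)

    @given(st.lists(st.floats(-1100, 150, allow_nan=False), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_conservation_property(self, values):
        ct, m = lung_ct(np.asarray(values, dtype=np.float32))
        h = histogram(ct, m)
        assert h.counts.sum() + h.out_of_range_count == h.total == len(values)


class TestCumulative:
    def test_uniform_counts_linear(self):
        h = _hist_from_counts(np.ones(100, dtype=int))
        np.testing.assert_allclose(cumulative(h), np.arange(1, 101) / 100.0)

    def test_all_mass_in_first_bin(self):
        counts = np.zeros(100, dtype=int)
        counts[0] = 10
        c = cumulative(_hist_from_counts(counts))
        assert c[0] == 1.0 and c[-1] == 1.0

    def test_ends_below_one_with_out_of_range_mass(self):
        h = _hist_from_counts([1, 1], extra_out_of_range=2)
        c = cumulative(h)
        assert np.all(np.diff(c) >= 0)
        assert c[-1] == pytest.approx(0.5)


class TestPercentiles:
    def test_nearest_rank_example(self):
        ct, m = lung_ct([-800.0, -600.0, -400.0, -200.0])
        assert percentile_hu(ct, m, 50) == -600.0

    def test_upper_limit_is_max(self):
        ct, m = lung_ct([-800.0, -600.0, -400.0, -200.0])
        assert percentile_hu(ct, m, 99.999) == -200.0

    def test_constant_lung(self):
        ct, m = lung_ct([-500.0] * 7)
        for p in (10, 40, 70, 90):
            assert percentile_hu(ct, m, p) == -500.0

    @pytest.mark.parametrize("p", [5, 25, 40, 50, 70, 95])
    def test_matches_sort_oracle(self, p):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = rng.uniform(-1000, 100, rng.integers(1, 500))
            ct, m = lung_ct(vals.astype(np.float32))
            srt = np.sort(ct.voxels.ravel())
            oracle = srt[int(np.ceil(p / 100 * srt.size)) - 1]
            assert percentile_hu(ct, m, p) == oracle

    def test_out_of_domain_percentile(self):
        ct, m = lung_ct([-500.0])
        with pytest.raises(ValueError):
            percentile_hu(ct, m, 0)
        with pytest.raises(ValueError):
            percentile_hu(ct, m, 100)

    def test_histogram_percentile_within_bin_width(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-990, -10, 5000).astype(np.float32)
        ct, m = lung_ct(vals)
        h = histogram(ct, m)
        for p in (25, 50, 75):
            assert histogram_percentile(h, p) == pytest.approx(
                percentile_hu(ct, m, p), abs=10.0
            )


def _profiles(offsets):
    """Cohort dict of profiles: subject i shifted by offsets[i]."""
    grid = np.arange(10, 95, 5, dtype=float)
    base = -900.0 + 5.0 * grid
    return {
        f"s{i}": PercentileProfile(percentiles=grid, hu_values=base + off)
        for i, off in enumerate(offsets)
    }


class TestDeltaProfile:
    def test_identical_profiles_zero(self):
        c = _profiles([0.0, 10.0, -5.0])
        d = delta_hu_profile(c, c)
        np.testing.assert_allclose(d.hu_values, 0.0)

    def test_translation_equivariance(self):
        c0 = _profiles([0.0, 10.0])
        c1 = _profiles([50.0, 60.0])  # every subject shifted +50
        d = delta_hu_profile(c0, c1)
        np.testing.assert_allclose(d.hu_values, 50.0)

    def test_antisymmetric_under_timepoint_swap(self):
        c0 = _profiles([0.0, 5.0])
        c1 = _profiles([30.0, 80.0])
        fwd = delta_hu_profile(c0, c1).hu_values
        rev = delta_hu_profile(c1, c0).hu_values
        np.testing.assert_allclose(fwd, -rev)

    def test_unmatched_subjects_error(self):
        c0 = _profiles([0.0])
        c1 = {"other": list(_profiles([0.0]).values())[0]}
        with pytest.raises(ValueError, match="matched"):
            delta_hu_profile(c0, c1)

    def test_profile_from_phantom_is_monotone(self, small_healthy_phantom):
        _, ct, truth = small_healthy_phantom
        prof = percentile_profile(ct, truth.lung_map)
        assert np.all(np.diff(prof.hu_values) >= 0)


class TestDiscriminativePercentiles:
    def test_single_differing_percentile_ranks_first(self):
        grid = np.arange(10, 95, 5, dtype=float)
        a = PercentileProfile(percentiles=grid, hu_values=np.zeros_like(grid))
        b_vals = np.zeros_like(grid)
        b_vals[list(grid).index(70.0)] = 50.0
        b = PercentileProfile.__new__(PercentileProfile)
        b.percentiles, b.hu_values, b.subject_id = grid, b_vals, None
        ranked = select_discriminative_percentiles(a, b)
        assert ranked[0] == (70.0, 50.0)

    def test_ties_break_toward_higher_percentile(self):
        grid = np.arange(10, 95, 5, dtype=float)
        a = PercentileProfile(percentiles=grid, hu_values=np.zeros_like(grid))
        ranked = select_discriminative_percentiles(a, a)
        assert ranked[0][0] == 90.0  # all-zero separation: highest p first
        assert [r[0] for r in ranked] == sorted(grid, reverse=True)

    def test_grid_mismatch_errors(self):
        a = PercentileProfile(percentiles=[10, 20], hu_values=[-800, -700])
        b = PercentileProfile(percentiles=[10, 30], hu_values=[-800, -700])
        with pytest.raises(ValueError):
            select_discriminative_percentiles(a, b)


class TestStagingThreshold:
    def test_stated_rule_arithmetic(self):
        assert derive_staging_threshold(
            [-500, -480, -470], [-400, -410, -390]
        ) == pytest.approx(-440.0)

    def test_two_point_mean_gives_minus_435(self):
        assert derive_staging_threshold([-480], [-390]) == pytest.approx(-435.0)

    def test_overlap_warns_but_returns(self):
        with pytest.warns(UserWarning, match="overlap"):
            t = derive_staging_threshold([-400], [-450])
        assert t == pytest.approx(-425.0)

    def test_invariant_to_order_and_duplication(self):
        a = derive_staging_threshold([-500, -470], [-410, -390])
        b = derive_staging_threshold([-470, -500, -470], [-390, -410, -410])
        assert a == b

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            derive_staging_threshold([], [-400])


class TestCompartmentLimitDerivations:
    def test_tail_mass_lands_on_minus_860(self):
        """0.02% of mass below −860 HU: the rule returns exactly −860."""
        counts = np.zeros(100, dtype=int)
        counts[13] = 2  # bin [-870, -860): 2 of 10000 voxels = 0.02%
        counts[14] = 98  # contiguous support above, as in real lungs
        counts[50] = 9900
        h = _hist_from_counts(counts)
        assert derive_normo_lower_limit([h], tail_fraction=0.0002) == -860.0

    def test_empty_tail_returns_first_occupied_edge(self):
        counts = np.zeros(100, dtype=int)
        counts[10] = 100  # all mass in [-900, -890)
        h = _hist_from_counts(counts)
        assert derive_normo_lower_limit([h]) == -900.0

    def test_tail_fraction_one_returns_upper_bound(self):
        counts = np.ones(100, dtype=int)
        h = _hist_from_counts(counts)
        assert derive_normo_lower_limit([h], tail_fraction=1.0) == 0.0

    def test_cohort_mean_is_over_frequencies_not_pooled(self):
        # subject A: tiny lung, all mass low; subject B: huge lung, higher.
        counts_a = np.zeros(100, dtype=int)
        counts_a[0] = 1  # 100% of subject A below -990
        counts_b = np.zeros(100, dtype=int)
        counts_b[50] = 10_000
        h_a, h_b = _hist_from_counts(counts_a), _hist_from_counts(counts_b)
        # mean frequency below -990 is 50%, far above the 0.02% tail:
        assert derive_normo_lower_limit([h_a, h_b]) == -1000.0

    def test_hypo_upper_limit_scans_counts(self):
        counts = np.zeros(100, dtype=int)
        counts[40] = 5
        counts[87] = 1  # highest occupied bin [-130, -120)
        h = _hist_from_counts(counts)
        assert derive_hypo_upper_limit([h]) == -120.0

    def test_hypo_upper_limit_takes_cohort_max(self):
        c1 = np.zeros(100, dtype=int)
        c1[59] = 3  # up to -400
        c2 = np.zeros(100, dtype=int)
        c2[87] = 1
        assert derive_hypo_upper_limit(
            [_hist_from_counts(c1), _hist_from_counts(c2)]
        ) == -120.0

    def test_empty_histograms_error(self):
        h = _hist_from_counts(np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            derive_hypo_upper_limit([h])
        with pytest.raises(ValueError):
            derive_normo_lower_limit([])
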