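"""Tests for distance maps, stratification and the signed-rank comparison."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vascstrata.pk_fit import PkMaps
from vascstrata.spatial import (compare_groups, compare_groups_rank_sum,
                                compute_distance_map, fraction_within,
                                stratify_by_distance, wilcoxon_signed_rank,
                                StratifiedProfile)


def _pk_from(vv, ps, valid):
    return PkMaps(vv=np.where(valid, vv, np.nan), ps=np.where(valid, ps, np.nan),
                  valid=valid, r_squared=np.full(np.shape(vv), np.nan))


def _brute_force_distance(vessel_mask, spacing):
    """O(N*M) nearest-vessel search used as an independent oracle."""
    coords = np.argwhere(vessel_mask) * np.asarray(spacing)
    out = np.empty(vessel_mask.shape)
    for idx in np.ndindex(vessel_mask.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        out[idx] = np.sqrt(((coords - p) ** 2).sum(axis=1).min())
    return out


# ---------------------------------------------------------------------------
# distance map
# ---------------------------------------------------------------------------

class TestDistanceMap:
    def test_3_4_5_triangle(self):
        vessel = np.zeros((12, 12, 12), dtype=bool)
        vessel[2, 2, 2] = True
        dmap = compute_distance_map(vessel, (100.0, 100.0, 100.0))
        # voxel offset (3, 4, 0) at 100 um spacing: distance 500 um exactly
        assert dmap.d_um[5, 6, 2] == pytest.approx(500.0)
        assert dmap.d_um[2, 2, 2] == 0.0

    def test_anisotropic_spacing(self):
        vessel = np.zeros((8, 8, 8), dtype=bool)
        vessel[0, 0, 0] = True
        dmap = compute_distance_map(vessel, (100.0, 200.0, 50.0))
        assert dmap.d_um[1, 0, 0] == pytest.approx(100.0)
        assert dmap.d_um[0, 1, 0] == pytest.approx(200.0)
        assert dmap.d_um[0, 0, 1] == pytest.approx(50.0)
        assert dmap.d_um[1, 1, 1] == pytest.approx(np.sqrt(100**2 + 200**2 + 50**2))

    def test_matches_brute_force_oracle(self, rng):
        spacing = (93.75, 93.75, 78.125)
        vessel = rng.random((12, 12, 12)) < 0.03
        vessel[4, 4, 4] = True  # guarantee non-empty
        dmap = compute_distance_map(vessel, spacing)
        oracle = _brute_force_distance(vessel, spacing)
        np.testing.assert_allclose(dmap.d_um, oracle, atol=1e-6)

    def test_translation_invariance(self):
        vessel = np.zeros((16, 16, 16), dtype=bool)
        vessel[3:5, 3:5, 3:5] = True
        d1 = compute_distance_map(vessel, (100.0,) * 3).d_um
        d2 = compute_distance_map(np.roll(vessel, 4, axis=0), (100.0,) * 3).d_um
        # interior region far from the wrap boundary is unaffected
        np.testing.assert_allclose(np.roll(d1, 4, axis=0)[6:14], d2[6:14])

    def test_spacing_doubling_doubles_distances(self):
        vessel = np.zeros((10, 10, 10), dtype=bool)
        vessel[5, 5, 5] = True
        d1 = compute_distance_map(vessel, (100.0,) * 3).d_um
        d2 = compute_distance_map(vessel, (200.0,) * 3).d_um
        np.testing.assert_allclose(d2, 2 * d1)

    def test_empty_mask_fails(self):
        with pytest.raises(ValueError, match="empty"):
            compute_distance_map(np.zeros((5, 5, 5), dtype=bool), (100.0,) * 3)

    def test_accepts_segmentation_object(self):
        from vascstrata.vessel_seg import VesselSegmentation
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        seg = VesselSegmentation(mask=mask, n_components=1, threshold_value=0.0)
        dmap = compute_distance_map(seg, (100.0,) * 3)
        assert dmap.d_um[2, 2, 2] == 0.0


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

class TestStratifyByDistance:
    def _setup(self):
        vessel = np.zeros((20, 20, 20), dtype=bool)
        vessel[10, 10, 10] = True
        tumor = np.ones((20, 20, 20), dtype=bool)
        dmap = compute_distance_map(vessel, (100.0,) * 3)
        return vessel, tumor, dmap

    def test_partition_conservation(self):
        _, tumor, dmap = self._setup()
        valid = np.ones_like(tumor)
        pk = _pk_from(np.full(tumor.shape, 0.05), np.full(tumor.shape, 0.002), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=100, max_bin_um=500)
        assert prof.voxel_count.sum() == tumor.sum()

    def test_half_open_bin_assignment(self):
        _, tumor, dmap = self._setup()
        valid = np.ones_like(tumor)
        pk = _pk_from(dmap.d_um.copy(), np.full(tumor.shape, 1.0), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=100, max_bin_um=500)
        # the vessel voxel (d = 0) lands in bin [0, 100); its 6 face
        # neighbours (d = 100) land in bin [100, 200) - boundary excluded
        assert prof.voxel_count[0] == 1
        assert prof.mean_vv[0] == pytest.approx(0.0)
        assert np.all(prof.mean_vv[1] >= 100.0)

    def test_overflow_bin_collects_far_voxels(self):
        _, tumor, dmap = self._setup()
        valid = np.ones_like(tumor)
        pk = _pk_from(np.full(tumor.shape, 0.05), np.full(tumor.shape, 0.002), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=100, max_bin_um=300)
        assert np.isinf(prof.bin_edges_um[-1])
        n_far = int((dmap.d_um >= 300).sum())
        assert prof.voxel_count[-1] == n_far

    def test_invalid_voxels_counted_but_not_averaged(self):
        _, tumor, dmap = self._setup()
        valid = np.zeros_like(tumor)
        valid[10, 10, 10] = True  # only the vessel voxel is valid
        pk = _pk_from(np.full(tumor.shape, 0.3), np.full(tumor.shape, 0.001), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=100, max_bin_um=300)
        assert prof.valid_count[0] == 1 and prof.mean_vv[0] == pytest.approx(0.3)
        assert prof.valid_count[1] == 0 and np.isnan(prof.mean_vv[1])
        assert prof.voxel_count.sum() == tumor.sum()

    def test_tissue_means_exclude_vessel_voxels(self):
        _, tumor, dmap = self._setup()
        valid = np.ones_like(tumor)
        vv = np.full(tumor.shape, 0.05)
        vv[10, 10, 10] = 1.0  # the vessel voxel
        pk = _pk_from(vv, np.full(tumor.shape, 0.002), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=200, max_bin_um=400)
        # bin [0, 200) holds the vessel voxel plus its 26 neighbours (6 faces
        # at 100 um, 12 edges at ~141 um, 8 corners at ~173 um)
        assert prof.valid_count[0] == 27 and prof.valid_tissue_count[0] == 26
        assert prof.mean_vv[0] == pytest.approx((1.0 + 26 * 0.05) / 27)
        assert prof.mean_vv_tissue[0] == pytest.approx(0.05)

    def test_rejects_bad_bin_width(self):
        _, tumor, dmap = self._setup()
        pk = _pk_from(np.zeros(tumor.shape), np.zeros(tumor.shape),
                      np.ones_like(tumor))
        with pytest.raises(ValueError, match="bin_width_um"):
            stratify_by_distance(pk, dmap, tumor, bin_width_um=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000),
           bin_width=st.sampled_from([50.0, 100.0, 250.0]))
    def test_property_partition_conservation(self, seed, bin_width):
        rng = np.random.default_rng(seed)
        vessel = rng.random((14, 14, 14)) < 0.05
        vessel[7, 7, 7] = True
        tumor = rng.random((14, 14, 14)) < 0.6
        dmap = compute_distance_map(vessel, (93.75, 93.75, 78.125))
        valid = rng.random((14, 14, 14)) < 0.5
        pk = _pk_from(rng.random((14, 14, 14)), rng.random((14, 14, 14)), valid)
        prof = stratify_by_distance(pk, dmap, tumor, bin_width_um=bin_width,
                                    max_bin_um=1000)
        assert prof.voxel_count.sum() == tumor.sum()
        assert prof.valid_count.sum() == (tumor & valid).sum()


class TestFractionWithin:
    def test_inclusive_radius(self):
        vessel = np.zeros((10, 10, 10), dtype=bool)
        vessel[0, 0, 0] = True
        tumor = np.zeros((10, 10, 10), dtype=bool)
        tumor[0, 0, 0] = tumor[1, 0, 0] = tumor[2, 0, 0] = True
        dmap = compute_distance_map(vessel, (100.0,) * 3)
        # distances 0, 100, 200; radius 100 is inclusive
        assert fraction_within(dmap, tumor, 100.0) == pytest.approx(2 / 3)
        assert fraction_within(dmap, tumor, 199.0) == pytest.approx(2 / 3)
        assert fraction_within(dmap, tumor, 200.0) == pytest.approx(1.0)

    def test_empty_tumor_fails(self):
        vessel = np.zeros((5, 5, 5), dtype=bool)
        vessel[0, 0, 0] = True
        dmap = compute_distance_map(vessel, (100.0,) * 3)
        with pytest.raises(ValueError, match="tumor mask is empty"):
            fraction_within(dmap, np.zeros((5, 5, 5), dtype=bool), 100.0)


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------

def _brute_force_two_sided_p(diffs):
    """Enumerate all 2^n sign patterns of the ranked |diffs| (independent oracle)."""
    from scipy.stats import rankdata
    x = np.asarray(diffs, dtype=float)
    x = x[x != 0]
    n = x.size
    ranks = rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    ws = np.array([np.sum(np.array(signs) * ranks)
                   for signs in itertools.product([0, 1], repeat=n)])
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestWilcoxonSignedRank:
    def test_n6_all_positive(self):
        w, p, n = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert n == 6 and w == pytest.approx(21.0)
        assert p == pytest.approx(2 / 64)

    def test_n6_all_negative_symmetric(self):
        _, p, _ = wilcoxon_signed_rank([-1.0, -2.0, -3.0, -4.0, -5.0, -6.0])
        assert p == pytest.approx(2 / 64)

    def test_zeros_dropped(self):
        w1, p1, n1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, 0.0, 3.0])
        w2, p2, n2 = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert (w1, p1, n1) == (w2, p2, n2)

    def test_all_zero_degenerate(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == (0.0, 1.0, 0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            wilcoxon_signed_rank([1.0, np.nan])

    def test_matches_brute_force_without_ties(self, rng):
        for n in range(2, 11):
            for _ in range(5):
                d = rng.normal(size=n)
                _, p, _ = wilcoxon_signed_rank(d)
                assert p == pytest.approx(_brute_force_two_sided_p(d), abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        for n in range(3, 10):
            for _ in range(5):
                d = rng.integers(-3, 4, size=n).astype(float)
                if np.all(d == 0):
                    continue
                _, p, _ = wilcoxon_signed_rank(d)
                assert p == pytest.approx(_brute_force_two_sided_p(d), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        from scipy import stats
        for _ in range(50):
            d = rng.normal(size=12)
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue,
                                      abs=1e-12)

    def test_normal_approximation_large_n(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        _, p_norm, n = wilcoxon_signed_rank(d, exact_max_n=25)
        from scipy import stats
        p_ref = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert n == 60
        assert p_norm == pytest.approx(p_ref, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=9))
    def test_property_matches_brute_force(self, diffs):
        d = np.asarray(diffs, dtype=float)
        w, p, n = wilcoxon_signed_rank(d)
        assert 0.0 <= p <= 1.0
        if n > 0:
            assert p == pytest.approx(_brute_force_two_sided_p(d), abs=1e-12)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _profile(mean_vv, mean_ps, edges=None, valid=None):
    mean_vv = np.asarray(mean_vv, dtype=float)
    n = mean_vv.size
    if edges is None:
        edges = np.append(np.arange(n) * 100.0, np.inf)
    valid = np.full(n, 50) if valid is None else np.asarray(valid)
    return StratifiedProfile(bin_edges_um=np.asarray(edges, dtype=float),
                             mean_vv=mean_vv,
                             mean_ps=np.asarray(mean_ps, dtype=float),
                             voxel_count=np.full(n, 100),
                             valid_count=valid,
                             mean_vv_tissue=mean_vv.copy(),
                             mean_ps_tissue=np.asarray(mean_ps, dtype=float).copy(),
                             valid_tissue_count=valid.copy())


class TestCompareGroups:
    def test_consistent_shift_detected(self):
        # 8 bins: seven regular ones with bin_hi <= 700 um plus the overflow
        edges = np.append(np.arange(8) * 100.0, np.inf)
        base_vv = np.linspace(0.2, 0.05, 8)
        base_ps = np.linspace(4e-3, 1e-4, 8)
        a = [_profile(base_vv * 0.7, base_ps * 0.7, edges) for _ in range(3)]
        b = [_profile(base_vv, base_ps, edges) for _ in range(3)]
        out = compare_groups(a, b, zone_max_um=700.0)
        # 7 all-negative differences: exact two-sided p = 2 / 2^7
        for param in ("vv", "ps"):
            assert out[param].p_value == pytest.approx(2 / 128)
            assert out[param].statistic == 0.0
            assert out[param].n_pairs == 7
            assert out[param].method == "exact"

    def test_identical_arms_degenerate(self):
        p = _profile([0.1, 0.2, 0.3], [1e-3, 2e-3, 3e-3])
        out = compare_groups([p, p], [p, p], zone_max_um=300.0)
        assert out["vv"].degenerate and out["vv"].p_value == 1.0
        assert out["vv"].method == "degenerate"

    def test_zone_limits_bins(self):
        edges = np.append(np.arange(10) * 100.0, np.inf)
        vv = np.linspace(0.3, 0.1, 10)
        a = [_profile(vv * 0.5, vv * 1e-2, edges)]
        b = [_profile(vv, vv * 1e-2 * 2, edges)]
        out = compare_groups(a, b, zone_max_um=400.0)
        assert out["vv"].n_pairs == 4

    def test_nan_bins_skipped(self):
        # default edges give bins ending at 100/200/300 um plus the overflow;
        # the NaN bin is dropped, leaving 2 usable pairs within the zone
        vv = np.array([0.1, np.nan, 0.3, 0.4])
        a = [_profile(vv * 0.5, vv * 1e-2)]
        b = [_profile(vv, vv * 2e-2)]
        out = compare_groups(a, b, zone_max_um=400.0)
        assert out["vv"].n_pairs == 2

    def test_too_few_usable_bins_fails(self):
        a = [_profile([0.1, np.nan, np.nan], [1e-3, np.nan, np.nan])]
        b = [_profile([0.2, np.nan, np.nan], [2e-3, np.nan, np.nan])]
        with pytest.raises(ValueError, match="fewer than 2 usable"):
            compare_groups(a, b, zone_max_um=300.0)

    def test_unaligned_bins_fail(self):
        a = [_profile([0.1, 0.2], [1e-3, 2e-3],
                      edges=np.array([0.0, 100.0, np.inf]))]
        b = [_profile([0.1, 0.2], [1e-3, 2e-3],
                      edges=np.array([0.0, 200.0, np.inf]))]
        with pytest.raises(ValueError, match="unaligned"):
            compare_groups(a, b, zone_max_um=300.0)

    def test_empty_group_fails(self):
        p = _profile([0.1, 0.2], [1e-3, 2e-3])
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups([], [p])

    def test_tissue_parameters_supported(self):
        edges = np.append(np.arange(5) * 100.0, np.inf)
        vv = np.linspace(0.2, 0.05, 5)
        a = [_profile(vv * 0.7, vv * 1e-2 * 0.7, edges)]
        b = [_profile(vv, vv * 1e-2, edges)]
        out = compare_groups(a, b, zone_max_um=500.0,
                             parameters=("vv_tissue", "ps_tissue"))
        assert set(out) == {"vv_tissue", "ps_tissue"}
        # 4 all-negative usable bins: exact two-sided p = 2 / 2^4
        assert out["vv_tissue"].p_value == pytest.approx(2 / 16)


class TestCompareGroupsRankSum:
    def test_separated_groups(self):
        edges = np.append(np.arange(5) * 100.0, np.inf)
        vv = np.linspace(0.2, 0.05, 5)
        a = [_profile(vv * s, vv * 1e-2 * s, edges) for s in (0.60, 0.65, 0.70)]
        b = [_profile(vv * s, vv * 1e-2 * s, edges) for s in (0.95, 1.00, 1.05)]
        out = compare_groups_rank_sum(a, b, zone_max_um=500.0)
        # complete separation of 3 vs 3: two-sided Mann-Whitney p = 0.1
        assert out["vv"]["p_value"] == pytest.approx(0.1)
        assert out["vv"]["n_a"] == 3 and out["vv"]["n_b"] == 3
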