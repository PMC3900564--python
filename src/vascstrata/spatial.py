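"""Distance-to-vessel stratification of microvascular parameter maps.

The heterogeneity readout: every tumor voxel is assigned its Euclidean
distance (µm, anisotropic-spacing aware) to the nearest macroscopic vessel
voxel, VV/PS maps are averaged within half-open distance bins, and two
study arms are compared over the near-vessel zone (default within 1 mm,
beyond which macromolecular-agent enhancement is noise-dominated) with a
paired Wilcoxon signed-rank test across distance bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .pk_fit import PkMaps

__all__ = [
    "DistanceMap",
    "StratifiedProfile",
    "GroupComparison",
    "compute_distance_map",
    "stratify_by_distance",
    "fraction_within",
    "wilcoxon_signed_rank",
    "compare_groups",
    "compare_groups_rank_sum",
]


# --------------------------------------------------------------------------
# distance map
# --------------------------------------------------------------------------

@dataclass
class DistanceMap:
    """Per-voxel distance (µm, voxel center to voxel center) to the nearest vessel."""

    d_um: np.ndarray
    spacing_um: np.ndarray


def compute_distance_map(vessel_mask, spacing_um) -> DistanceMap:
    """Exact anisotropic Euclidean distance transform to the vessel set.

    Vessel voxels map to exactly zero.  Fails on an empty vessel mask, for
    which the distance is undefined.
    """
    vessel_mask = np.asarray(getattr(vessel_mask, "mask", vessel_mask), dtype=bool)
    spacing_um = np.asarray(spacing_um, dtype=float)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty; distance map undefined")
    d = ndimage.distance_transform_edt(~vessel_mask, sampling=spacing_um)
    return DistanceMap(d_um=d, spacing_um=spacing_um)


# --------------------------------------------------------------------------
# stratification
# --------------------------------------------------------------------------

@dataclass
class StratifiedProfile:
    """Per-distance-bin means of VV/PS with voxel bookkeeping.

    Bins are half-open [lo, hi); the final bin is the overflow
    [max_bin_um, inf).  ``bin_edges_um`` has length n_bins + 1 with the last
    edge infinite.  Means are over valid voxels only and are NaN for bins
    without any valid voxel; voxel_count partitions the tumor mask exactly.

    The ``*_tissue`` means additionally exclude the vessel voxels themselves
    (distance exactly zero): inside a macrovessel the fitted VV is blood
    volume, not a microvascular parameter, so directional claims about the
    tissue response read off the tissue columns.
    """

    bin_edges_um: np.ndarray
    mean_vv: np.ndarray
    mean_ps: np.ndarray
    voxel_count: np.ndarray
    valid_count: np.ndarray
    mean_vv_tissue: np.ndarray = None
    mean_ps_tissue: np.ndarray = None
    valid_tissue_count: np.ndarray = None

    @property
    def bin_lo_um(self) -> np.ndarray:
        return self.bin_edges_um[:-1]

    @property
    def bin_hi_um(self) -> np.ndarray:
        return self.bin_edges_um[1:]


def stratify_by_distance(pk: PkMaps, dmap: DistanceMap, tumor_mask,
                         bin_width_um: float = 100.0,
                         max_bin_um: float = 2000.0) -> StratifiedProfile:
    """Average VV/PS maps within half-open distance bins.

    Tumor voxels with distance in [k*w, (k+1)*w) go to bin k up to
    ``max_bin_um``; everything beyond lands in one overflow bin, so the bin
    voxel counts always sum exactly to the tumor voxel count.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    if dmap.d_um.shape != tumor_mask.shape or pk.vv.shape != tumor_mask.shape:
        raise ValueError("distance map, parameter maps and tumor mask grids differ")

    n_regular = int(np.ceil(max_bin_um / bin_width_um))
    edges = np.append(np.arange(n_regular + 1) * bin_width_um, np.inf)
    n_bins = n_regular + 1  # + overflow

    d = dmap.d_um[tumor_mask]
    idx = np.minimum((d // bin_width_um).astype(int), n_regular)
    voxel_count = np.bincount(idx, minlength=n_bins)

    valid = pk.valid[tumor_mask]
    vv_t, ps_t = pk.vv[tumor_mask], pk.ps[tumor_mask]

    def bin_means(sel):
        count = np.bincount(idx[sel], minlength=n_bins)
        svv = np.bincount(idx[sel], weights=vv_t[sel], minlength=n_bins)
        sps = np.bincount(idx[sel], weights=ps_t[sel], minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (np.where(count > 0, svv / count, np.nan),
                    np.where(count > 0, sps / count, np.nan), count)

    mean_vv, mean_ps, valid_count = bin_means(valid)
    tissue = valid & (d > 0)  # drop the vessel voxels themselves
    mean_vv_tis, mean_ps_tis, valid_tis = bin_means(tissue)
    return StratifiedProfile(bin_edges_um=edges, mean_vv=mean_vv, mean_ps=mean_ps,
                             voxel_count=voxel_count, valid_count=valid_count,
                             mean_vv_tissue=mean_vv_tis, mean_ps_tissue=mean_ps_tis,
                             valid_tissue_count=valid_tis)


def fraction_within(dmap: DistanceMap, tumor_mask, radius_um: float) -> float:
    """Fraction of tumor voxels within ``radius_um`` of the nearest vessel."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if radius_um < 0:
        raise ValueError("radius_um must be non-negative")
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        raise ValueError("tumor mask is empty")
    return float((dmap.d_um[tumor_mask] <= radius_um).sum() / n_tumor)


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Wilcoxon signed-rank result for one parameter over the near-vessel zone."""

    statistic: float        # W+ = sum of ranks of positive differences
    p_value: float
    n_pairs: int            # non-zero differences entering the test
    zone_max_um: float
    method: str             # 'exact' | 'normal' | 'degenerate'
    degenerate: bool = False


def _exact_signed_rank_sf(ranks2: np.ndarray):
    """Exact null distribution of 2*W+ for given doubled (integer) ranks.

    Dynamic program over subset sums: counts[s] = number of sign patterns
    with 2*W+ = s.  Doubling the ranks makes tied (half-integer) average
    ranks exact integers.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts / counts.sum()


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> tuple[float, float, int]:
    """Two-sided one-sample Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking; ties get average ranks.
    The null distribution is enumerated exactly for n <= ``exact_max_n``
    (ties included, via doubled integer ranks) and approximated by a
    tie-corrected normal with continuity correction otherwise.

    Returns (W+, two-sided p, n) where n counts non-zero differences.
    If every difference is zero the test is degenerate and (0, 1, 0) is
    returned.
    """
    x = np.asarray(differences, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("differences must be finite")
    x = x[x != 0]
    n = x.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _exact_signed_rank_sf(ranks2)
        w2 = int(round(2 * w_plus))
        p_low = pmf[: w2 + 1].sum()
        p_high = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_plus, float(p), n

    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, tie_counts = np.unique(np.abs(x), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    dev = w_plus - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)  # continuity correction
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_plus, p, n


def _zone_bin_means(profiles, attr: str, zone_max_um: float, ref_edges) -> np.ndarray:
    """Stack per-subject bin means restricted to bins entirely within the zone."""
    sel = ref_edges[1:] <= zone_max_um
    rows = []
    for p in profiles:
        if not np.array_equal(p.bin_edges_um, ref_edges):
            raise ValueError("stratified profiles have unaligned bins")
        rows.append(getattr(p, attr)[sel])
    return np.asarray(rows)


def compare_groups(profiles_a, profiles_b, zone_max_um: float = 1000.0,
                   parameters: tuple[str, ...] = ("vv", "ps")) -> dict[str, GroupComparison]:
    """Compare two arms' stratified profiles over the near-vessel zone.

    Bins beyond ``zone_max_um`` are excluded (the far-field signal is
    noise-dominated with a macromolecular agent).  The group-mean profile is
    formed per bin in each arm and the paired signed-rank test is run across
    bins on (mean_a - mean_b), separately for each parameter.
    """
    profiles_a, profiles_b = list(profiles_a), list(profiles_b)
    if not profiles_a or not profiles_b:
        raise ValueError("both groups must be non-empty")
    ref_edges = profiles_a[0].bin_edges_um
    out: dict[str, GroupComparison] = {}
    for param in parameters:
        attr = f"mean_{param}"
        a = _zone_bin_means(profiles_a, attr, zone_max_um, ref_edges)
        b = _zone_bin_means(profiles_b, attr, zone_max_um, ref_edges)
        with warnings.catch_warnings():
            # bins empty in every subject are legitimately all-NaN
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            mean_a = np.nanmean(a, axis=0)
            mean_b = np.nanmean(b, axis=0)
        usable = np.isfinite(mean_a) & np.isfinite(mean_b)
        diffs = mean_a[usable] - mean_b[usable]
        if usable.sum() < 2:
            raise ValueError(
                f"fewer than 2 usable distance bins within {zone_max_um} µm "
                f"for parameter {param!r}")
        if np.all(diffs == 0):
            out[param] = GroupComparison(statistic=0.0, p_value=1.0, n_pairs=0,
                                         zone_max_um=zone_max_um,
                                         method="degenerate", degenerate=True)
            continue
        w, p, n = wilcoxon_signed_rank(diffs)
        out[param] = GroupComparison(statistic=w, p_value=p, n_pairs=n,
                                     zone_max_um=zone_max_um,
                                     method="exact" if n <= 25 else "normal")
    return out


def compare_groups_rank_sum(profiles_a, profiles_b, zone_max_um: float = 1000.0,
                            parameters: tuple[str, ...] = ("vv", "ps")) -> dict[str, dict]:
    """Sensitivity analysis: rank-sum test on per-subject zone means.

    Each subject is reduced to its valid-voxel-weighted mean parameter value
    over bins within the zone, and the two arms are compared with the
    Mann-Whitney U test (the unpaired analogue, since the arms are distinct
    animals).
    """
    def zone_means(profiles, attr):
        ref = profiles[0].bin_edges_um
        sel = ref[1:] <= zone_max_um
        vals = []
        for p in profiles:
            m = getattr(p, attr)[sel]
            w = p.valid_count[sel]
            ok = np.isfinite(m) & (w > 0)
            vals.append(float(np.average(m[ok], weights=w[ok])))
        return np.asarray(vals)

    out = {}
    for param in parameters:
        a = zone_means(list(profiles_a), f"mean_{param}")
        b = zone_means(list(profiles_b), f"mean_{param}")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[param] = {"statistic": float(res.statistic),
                      "p_value": float(res.pvalue),
                      "n_a": a.size, "n_b": b.size,
                      "zone_max_um": zone_max_um}
    return out
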