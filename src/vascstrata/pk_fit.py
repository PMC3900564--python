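"""Voxelwise pharmacokinetic fitting for macromolecular-agent DCE-MRI.

With a long-circulating macromolecular contrast agent the blood-pool
concentration is effectively constant over a ~30 minute scan, so the tissue
concentration is linear in time,

    C_tissue(t) = C_blood * (VV + PS * t),

where VV is the fractional vascular volume of the voxel (dimensionless) and
PS is the permeability-surface-area product expressed as the fraction of the
voxel volume that fills with leaked tracer per minute.  Normalizing the
signal enhancement by the blood enhancement turns the voxel time course into
y(t) = VV + PS*t, so VV and PS are the intercept and slope of an ordinary
least-squares line.  Only voxels with positive intercept and positive slope
are physically meaningful and are retained; the rest are flagged invalid and
carry NaN, never zero, so that downstream averages stay honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DceSeries",
    "EnhancementSeries",
    "PkMaps",
    "compute_enhancement",
    "fit_linear_pk",
    "whole_tumor_summary",
]


@dataclass
class DceSeries:
    """A dynamic contrast-enhanced acquisition: baseline plus post-contrast frames.

    Attributes
    ----------
    pre_frame : (X, Y, Z) float array
        Pre-contrast baseline signal.
    frames : (X, Y, Z, T) float array
        Post-contrast signal frames.
    times_min : (T,) float array
        Frame timestamps in minutes after injection, strictly increasing.
    spacing_um : (3,) float array
        Voxel spacing in micrometres.
    """

    pre_frame: np.ndarray
    frames: np.ndarray
    times_min: np.ndarray
    spacing_um: np.ndarray

    def __post_init__(self) -> None:
        self.pre_frame = np.asarray(self.pre_frame, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.spacing_um = np.asarray(self.spacing_um, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a 4D (x, y, z, t) array")
        if self.pre_frame.shape != self.frames.shape[:3]:
            raise ValueError("pre_frame grid does not match frames grid")
        if self.frames.shape[3] != self.times_min.size:
            raise ValueError("number of frames does not match number of times")
        if self.times_min.size < 2:
            raise ValueError("at least two post-contrast frames are required")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.spacing_um.shape != (3,) or np.any(self.spacing_um <= 0):
            raise ValueError("spacing_um must be three positive extents")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]


@dataclass
class EnhancementSeries:
    """Dimensionless enhancement e = (S(t) - S_pre) / M0 with a blood reference."""

    e: np.ndarray
    e_blood: float
    times_min: np.ndarray
    invalid: np.ndarray = field(default=None)  # voxels where enhancement is undefined

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.invalid is None:
            self.invalid = np.zeros(self.e.shape[:3], dtype=bool)


@dataclass
class PkMaps:
    """Voxelwise VV/PS maps with the positivity-filter validity mask.

    ``vv`` and ``ps`` are NaN outside ``valid``.  ``r_squared`` is a
    goodness-of-fit diagnostic kept wherever a fit was attempted.
    """

    vv: np.ndarray
    ps: np.ndarray
    valid: np.ndarray
    r_squared: np.ndarray


def compute_enhancement(series, m0, blood_ref):
    """Convert a signal series into normalized enhancement.

    Parameters
    ----------
    series : DceSeries
    m0 : (X, Y, Z) array
        Equilibrium-magnetization map; must be positive wherever enhancement
        is needed.  Voxels with m0 <= 0 are flagged invalid, not zeroed.
    blood_ref : float or (X, Y, Z) bool array
        Either the blood enhancement value itself (scalar) or a blood-pool
        region over which the mean first-frame enhancement is taken.

    Returns
    -------
    EnhancementSeries
    """
    m0 = np.asarray(m0, dtype=float)
    if m0.shape != series.grid_shape:
        raise ValueError("m0 grid does not match series grid")

    invalid = ~(m0 > 0)
    invalid |= ~np.isfinite(series.pre_frame)
    invalid |= ~np.all(np.isfinite(series.frames), axis=3)

    with np.errstate(divide="ignore", invalid="ignore"):
        e = (series.frames - series.pre_frame[..., None]) / m0[..., None]
    e[invalid] = np.nan

    if np.isscalar(blood_ref) or np.ndim(blood_ref) == 0:
        e_blood = float(blood_ref)
    else:
        region = np.asarray(blood_ref, dtype=bool)
        if region.shape != series.grid_shape:
            raise ValueError("blood region grid does not match series grid")
        region = region & ~invalid
        if not region.any():
            raise ValueError("blood reference region is empty (or entirely invalid)")
        e_blood = float(np.mean(e[region, 0]))
    return EnhancementSeries(e=e, e_blood=e_blood, times_min=series.times_min,
                             invalid=invalid)


def fit_linear_pk(enh: EnhancementSeries, times_min=None, analysis_mask=None) -> PkMaps:
    """Per-voxel OLS of blood-normalized enhancement against time.

    Fits y(t) = e(t)/e_blood = vv + ps*t independently in every masked voxel
    and applies the positivity filter: a voxel is valid only if vv > 0 and
    ps > 0.  Voxels with fewer than two finite frames, or with no time spread,
    are invalid.

    Parameters
    ----------
    enh : EnhancementSeries
    times_min : (T,) array, optional
        Defaults to the times stored on the enhancement series.
    analysis_mask : (X, Y, Z) bool array, optional
        Restrict fitting to these voxels (e.g. the tumor mask); defaults to
        the full grid.
    """
    if enh.e_blood <= 0 or not np.isfinite(enh.e_blood):
        raise ValueError(
            f"blood enhancement must be positive (got {enh.e_blood!r}); "
            "check the blood calibration"
        )
    t = np.asarray(enh.times_min if times_min is None else times_min, dtype=float)
    shape = enh.e.shape[:3]
    if analysis_mask is None:
        analysis_mask = np.ones(shape, dtype=bool)
    else:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != shape:
            raise ValueError("analysis mask grid does not match enhancement grid")

    y = enh.e[analysis_mask] / enh.e_blood  # (N, T)
    w = np.isfinite(y)

    if w.all():
        # fast path: every masked voxel has a complete time course
        n = np.full(y.shape[0], t.size)
        mean_t = t.mean()
        tc = t - mean_t
        s_tt = np.full(y.shape[0], float(tc @ tc))
        mean_y = y.mean(axis=1)
        slope = (y @ tc) / s_tt
        intercept = mean_y - slope * mean_t
        resid = y - (intercept[:, None] + slope[:, None] * t)
        ss_res = (resid * resid).sum(axis=1)
        ss_tot = ((y - mean_y[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
    else:
        # weighted (0/1) closed-form OLS so voxels with missing frames still fit
        yw = np.where(w, y, 0.0)
        n = w.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sum_t = (w * t).sum(axis=1)
            sum_y = yw.sum(axis=1)
            mean_t = sum_t / n
            mean_y = sum_y / n
            s_tt = (w * (t - mean_t[:, None]) ** 2).sum(axis=1)
            s_ty = (w * (t - mean_t[:, None]) * (yw - mean_y[:, None])).sum(axis=1)
            slope = s_ty / s_tt
            intercept = mean_y - slope * mean_t
            resid = yw - (intercept[:, None] + slope[:, None] * t)
            ss_res = (w * resid**2).sum(axis=1)
            ss_tot = (w * (yw - mean_y[:, None]) ** 2).sum(axis=1)
            r2 = 1.0 - ss_res / ss_tot

    fit_ok = (n >= 2) & (s_tt > 0) & np.isfinite(intercept) & np.isfinite(slope)
    pos = fit_ok & (intercept > 0) & (slope > 0)

    vv = np.full(shape, np.nan)
    ps = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    r_squared = np.full(shape, np.nan)

    vv_flat = np.where(pos, intercept, np.nan)
    ps_flat = np.where(pos, slope, np.nan)
    vv[analysis_mask] = vv_flat
    ps[analysis_mask] = ps_flat
    valid[analysis_mask] = pos
    r_squared[analysis_mask] = np.where(fit_ok, r2, np.nan)
    return PkMaps(vv=vv, ps=ps, valid=valid, r_squared=r_squared)


def whole_tumor_summary(pk: PkMaps, tumor_mask) -> dict:
    """Whole-tumor mean/median VV and PS over valid voxels.

    Provided as the conventional global readout that the distance-stratified
    analysis is contrasted against.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    sel = tumor_mask & pk.valid
    n_valid = int(sel.sum())
    summary = {
        "n_tumor_voxels": int(tumor_mask.sum()),
        "n_valid_voxels": n_valid,
        "no_valid_voxels": n_valid == 0,
    }
    if n_valid:
        summary.update(
            mean_vv=float(np.mean(pk.vv[sel])),
            median_vv=float(np.median(pk.vv[sel])),
            mean_ps=float(np.mean(pk.ps[sel])),
            median_ps=float(np.median(pk.ps[sel])),
        )
    else:
        warnings.warn("no valid voxels in tumor; summary statistics undefined")
        summary.update(mean_vv=np.nan, median_vv=np.nan,
                       mean_ps=np.nan, median_ps=np.nan)
    return summary
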