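# Methods note

This note records the quantitative model behind `vascstrata`, the meaning,
units and defaults of every parameter, what the synthetic phantom does and
does not emulate, the numerical choices made along the way, and the known
limitations — particularly of the statistical readout.

## 1. Pharmacokinetic model

With a macromolecular contrast agent (long intravascular half-life, slow
extravasation), the blood-pool concentration `c_b` is effectively constant
over a ~30 minute dynamic scan. The tracer amount in a tissue voxel is then

```
C(t) = c_b * VV + PS * ∫₀ᵗ c_b dτ  =  c_b * (VV + PS·t)      (constant pool)
```

- `VV` — fractional vascular volume of the voxel, dimensionless, in [0, 1].
- `PS` — permeability–surface-area product expressed as the fraction of the
  voxel volume filling with leaked tracer per minute (1/min).

Signal formation is linearized saturation recovery:

```
S(t) = S_pre + k · M0 · C(t) + ε,   ε ~ N(0, σ²)
```

so the normalized enhancement `e(t) = (S(t) − S_pre)/M0 = k·C(t)`, and with
the blood enhancement `e_blood = k·c_b` the per-voxel series

```
y(t) = e(t)/e_blood = VV + PS·t
```

is a straight line. `fit_linear_pk` runs ordinary least squares per voxel
(closed form; a 0/1-weighted variant covers voxels with missing frames) and
applies the positivity filter: a voxel is **valid** only if the fitted
intercept and slope are both strictly positive. Invalid voxels carry NaN,
never zero, so downstream averages are unbiased by construction.

Assumptions: constant blood pool (an optional linear decay is provided for
sensitivity analyses and defaults off); no back-flux of leaked tracer on the
scan time scale; signal linear in concentration; spatially smooth `M0`.

## 2. The synthetic phantom

Each subject is generated from one integer seed and is fully deterministic.

**Geometry.** An ellipsoidal tumor (default semi-axes 0.8× the half-extent
of the field of view) contains `n_trunks` piecewise-linear, tapering vessel
trunks entering from the surface, each optionally spawning one thinner
branch. Centerlines are rasterized and dilated into tubes; a single radius
multiplier is chosen so the vessel voxels occupy `target_fraction` of the
tumor volume. The multiplier is read off a quantile of (distance ÷ local
radius) over tumor voxels, which makes the achieved fraction monotone in the
multiplier and exact up to voxel ties; if even the admissible extremes miss
the target by more than 30% the generator fails loudly rather than deliver
a tree with the wrong vascular density.

**Ground-truth fields.** For a tissue voxel at distance `d` (µm) from the
nearest vessel voxel:

```
vv(d) = vv_baseline + (vv_peak − vv_baseline) · exp(−d/L)
ps(d) = max(ps_peak · exp(−d/L), ps_floor)
```

Vessel voxels are pure blood: `vv = 1`, `ps = ps_peak`. The decay length
`L` models the diffusion-limited perivascular niche: the profiles level off
within ~2–3 decay lengths of a vessel.

**Treatment preset.** Antiangiogenic therapy in this model dampens the
*microvasculature* while leaving the macroscopic network intact: tissue
`ps` and the tissue vv-excess over baseline are multiplied by
`treatment_scale` (default 0.7); vessel voxels keep `vv = 1`. Control and
treated subjects generated from the same seed therefore share an identical
vessel tree, which makes the macrovascular volume fraction directly
comparable between arms. An optional `treated_tumor_scale` shrinks the
treated tumor ellipsoid; it defaults to 1 precisely to preserve that
tree-identity contract, and shrinking the tumor breaks it (the tree is
regenerated for the smaller ellipsoid).

**Parameters** (defaults, units, rationale):

| Parameter | Default | Unit | Why |
|---|---|---|---|
| `fov_mm` | (12, 12, 10) | mm | small-animal tumor field of view |
| `matrix` | (128, 128, 128) | — | isotropic-count reconstruction grid; studies use 64³ for speed |
| `frame_interval_min` | 6 | min | one 3D frame per ~6 min, 5 frames ≈ 30 min scan |
| `first_frame_time_min` | interval/2 | min | frames timestamped at their temporal midpoint, which is unbiased for a linear uptake; exposed because acquisition conventions differ |
| `noise_sigma` | 0 (phantom), 10 (study) | signal units | σ = 10 with `k·M0·c_b = 1000` puts the vessel-wall VV signal at SNR ≈ 20 and the far-field tissue near SNR ≈ 1, reproducing the noise-dominated tumor core seen in vivo |
| `m0_mean`, `m0_variation` | 1000, 0.2 | signal units, — | smooth ±20% equilibrium-magnetization modulation (coil/tissue variation) |
| `s_pre_frac` | 0.1 | — | pre-contrast signal at 10% of M0 |
| `n_trunks` | 6 | — | a handful of feeding vessels per tumor |
| `target_fraction` | 0.045 | — | macrovascular volume fraction of a few percent |
| `vv_peak`, `vv_baseline` | 0.2, 0.01 | — | perivascular vs avascular-core vascular volume |
| `ps_peak` | 0.004 | 1/min | macromolecular-agent leakage near vessels |
| `decay_length_um` (`L`) | 100 | µm | oxygen/nutrient diffusion scale (100–200 µm) |
| `ps_floor` | 1e-7 | 1/min | numerical conditioning, see §4 |
| `c_blood` | 1.0 | arbitrary | concentration unit; only `k·c_blood` matters |

**What the phantom emulates:** linear macromolecular-agent uptake; a sparse
macrovascular tree inside an otherwise microvascular tumor; steep
distance-dependence of VV/PS with a leveled-off far field; per-voxel
Gaussian signal noise; smooth M0 inhomogeneity; two-arm treatment studies
with per-subject random geometry.

**What it does not emulate:** MR physics beyond the linearized
saturation-recovery contract (no B1/coil maps, no k-space, no motion); no
Rician noise floor (noise is additive Gaussian, a good approximation at the
simulated SNR but optimistic in truly signal-free background); no partial
volume beyond voxelization; no necrosis, hemorrhage, or vessel tortuosity
statistics matched to histology; blood sampled as a known scalar reference
rather than from an imaged artery.

## 3. Segmentation and spatial analysis

**Macrovascular segmentation.** The first post-contrast frame of a
macromolecular-agent scan is effectively an angiogram. Segmentation is
percentile thresholding of enhancement over the tumor ROI (threshold
inclusive, `≥`, for deterministic tie handling), connected-component
labeling (26-connectivity by default, which keeps oblique tubes connected),
and a minimum-cluster-size filter (10 voxels). The `SegmentationParams`
default percentile of 82.5 sits mid-way in the upper 15–20 percentile band
conventionally used on real angiograms, where partial-volume blur spreads
vessel-bright signal over many voxels. Threshold choice is expected to be
adapted per dataset; on the phantom's sharper enhancement distribution the
82.5th percentile sweeps in the bright perivascular shell (~17.5% of the
tumor), so `StudyConfig` adapts the threshold to the 95.5th percentile
(= 100 − 100·0.045), at which the segmented network is the macrovascular
tree itself. The realized `threshold_value` is logged per subject.

**Distance map.** `scipy.ndimage.distance_transform_edt` with the voxel
spacing as anisotropic sampling gives the exact Euclidean
voxel-center-to-voxel-center distance to the nearest vessel voxel. No
half-voxel surface correction is applied; the analytic-cylinder acceptance
test quantifies the resulting discretization error (<1% at 25 µm voxels).

**Stratification.** Tumor voxels are partitioned into half-open distance
bins `[k·w, (k+1)·w)` (default width 100 µm) up to `max_bin_um` (2 mm) plus
one overflow bin, so bin voxel counts always sum exactly to the tumor voxel
count. Bin means of VV/PS are taken over valid voxels only; bins without
valid voxels are NaN, never zero. Each profile also carries *tissue-only*
bin means that exclude the segmented-vessel voxels themselves (`d = 0`):
inside a macrovessel the fitted VV is blood volume, not a microvascular
parameter, so directional claims about the tissue response read off the
tissue columns. The all-voxel means remain the primary columns.

**Group comparison.** Arms are compared over the near-vessel zone (bins
with upper edge ≤ `zone_max_um`, default 1 mm — beyond which the
macromolecular-agent signal is noise-dominated). The per-bin group means
are differenced and tested with a two-sided Wilcoxon signed-rank test
across bins: zero differences dropped, average ranks on ties, the null
distribution enumerated **exactly** for n ≤ 25 (ties handled by doubling
the ranks to integers), tie-corrected normal approximation with continuity
correction beyond. A rank-sum (Mann–Whitney) sensitivity analysis on
per-subject zone means is reported alongside; see §5 for why it is the
statistically sounder readout for a two-arm design.

## 4. Numerical choices

- **`ps_floor = 1e-7` /min.** A pure exponential `ps(d)` falls below the
  resolution of double precision relative to the VV term within a few
  hundred micrometres (`ps·t` contributes less than one ulp of the voxel
  signal), making exact round-trip recovery impossible *in principle* for
  any estimator. The floor — 2.5e-5 of the default peak, physically
  negligible — keeps the field representable so that noiseless fits recover
  the truth to ~1e-12 relative error everywhere.
- **Midpoint frame timestamps.** For a linear uptake, averaging the signal
  over a long 3D acquisition equals sampling it at the temporal midpoint,
  so midpoint timestamps make the fit unbiased; the convention is
  configurable (`first_frame_time_min`).
- **Closed-form OLS.** The fit is a single matrix-vector product per volume
  when all frames are finite (the common case), with a 0/1-weighted
  closed-form fallback per voxel otherwise; no iterative solvers.
- **Quantile-based tube sizing.** The vessel-tree radius multiplier is
  found by a direct quantile lookup (exact, monotone) instead of bisection
  with repeated rasterization.
- **Exact signed-rank.** Exactness is preserved under ties by enumerating
  the null over doubled (integer) ranks with a subset-sum dynamic program.
- **Determinism.** Per-subject seeds derive from the master seed via
  `numpy.random.SeedSequence`; reruns are byte-identical, and
  `vascstrata verify` re-derives every report number from the stage CSVs.

## 5. Limitations

- **The bin-paired signed-rank test is fragile by design.** Its pairs are
  distance bins, not independent sampling units. Two consequences, both
  quantified by the Monte-Carlo acceptance characterization:
  (1) *power*: with the effect confined to ~2–3 decay lengths of the
  vessels, only ~4–5 of the 10 in-zone bins carry signal, while far bins
  contain only the positivity-selection bias (identical in both arms) and
  contribute coin-flip signs — and an exact n = 10 signed-rank needs
  near-unanimity (W⁺ ≤ 8) to reach p < 0.05;
  (2) *calibration*: each subject's segmentation error shifts all of that
  subject's bins coherently, so with 6–7 subjects per arm the ten bin
  differences are positively correlated and the test is anticonservative
  under the null (the implementation itself is exactly calibrated on
  independent differences). The per-subject rank-sum readout, which treats
  animals as the sampling unit, has neither defect and is reported in every
  study as `rank_sum_sensitivity`.
- Gaussian (not Rician) noise slightly flatters low-SNR regions.
- Distances are voxel-center to voxel-center; at coarse spacing the first
  bin beyond the vessel wall may be geometrically empty (e.g. no tissue
  voxel closer than 156 µm on a 64³/12 mm grid).
- The segmentation threshold is a study-level constant; real angiograms
  need per-animal adaptation, which the config exposes but does not
  automate beyond the percentile rule.
- The phantom's vessel tree is a random piecewise-linear caricature; its
  branching statistics are not fit to measured tumor vasculature.
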