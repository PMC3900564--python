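# vascstrata

**Distance-stratified analysis of tumor vascular heterogeneity from DCE-MRI,
with a fully synthetic ground-truth phantom.**

Tumor vasculature is spatially heterogeneous: a sparse network of macroscopic
feeding vessels supplies a microvascular bed whose volume and permeability
fall off steeply with distance from those vessels, on the scale of the
oxygen/nutrient diffusion limit (a few hundred micrometres). Readouts that
average pharmacokinetic parameters over the whole tumor blur this structure
away — and with it, the spatially localized response to antiangiogenic
therapy. `vascstrata` implements the alternative: map every tumor voxel's
distance to the nearest macroscopic vessel and analyze vascular parameters
as a function of that distance.

## The model

With a long-circulating macromolecular contrast agent the blood-pool
concentration is effectively constant over a ~30 minute scan, so the tissue
concentration in each voxel is linear in time:

```
C_tissue(t) = C_blood * (VV + PS * t)
```

where `VV` is the fractional vascular volume (dimensionless) and `PS` the
permeability–surface-area product (fraction of voxel volume per minute).
Normalizing signal enhancement by the blood enhancement turns every voxel's
time course into a straight line whose intercept is `VV` and slope is `PS`;
only voxels with positive intercept *and* positive slope are physically
meaningful and retained.

The pipeline has five stages:

| Module | What it does |
|---|---|
| `vascstrata.phantom` | Synthetic 4D DCE-MRI subject: ellipsoidal tumor, embedded macrovascular tree, distance-decaying ground-truth VV/PS fields, linear-uptake signal model with Gaussian noise |
| `vascstrata.pk_fit` | Enhancement normalization and voxelwise ordinary-least-squares VV/PS maps with the positivity filter |
| `vascstrata.vessel_seg` | Macrovascular segmentation of the first post-contrast frame: percentile threshold, connected components, size filter |
| `vascstrata.spatial` | Anisotropic Euclidean distance-to-vessel map, distance-binned stratification, exact Wilcoxon signed-rank group comparison |
| `vascstrata.pipeline` | Two-arm (control vs treated) study orchestration, provenance capture, report verification; `vascstrata` CLI in `vascstrata.cli` |

## Worked example

A full two-arm study — 7 treated vs 6 control synthetic subjects on 64³
grids, treatment scaling the microvascular fields by 0.7 while leaving the
macrovascular tree untouched — runs in a few seconds:

```python
from vascstrata import StudyConfig, run_study

config = StudyConfig(master_seed=1)
report = run_study(config, out_dir="results")

arms = report["arm_means"]
print(f"macrovascular fraction  control: {arms['control']['macrovascular_fraction']:.4f}")
print(f"macrovascular fraction  treated: {arms['treated']['macrovascular_fraction']:.4f}")
print(f"tumor within 250 um of a vessel: {arms['control']['fraction_within_radius']:.3f}")
for param in ("vv", "ps"):
    c = report["comparison"][param]
    print(f"{param}: signed-rank W+ = {c['statistic']:.1f}, "
          f"p = {c['p_value']:.4f} over {c['n_pairs']} distance bins")
print(f"rank-sum sensitivity (PS, per-subject): "
      f"p = {report['rank_sum_sensitivity']['ps']['p_value']:.4f}")
```

prints

```
macrovascular fraction  control: 0.0450
macrovascular fraction  treated: 0.0450
tumor within 250 um of a vessel: 0.107
vv: signed-rank W+ = 3.0, p = 0.0098 over 10 distance bins
ps: signed-rank W+ = 6.0, p = 0.0273 over 10 distance bins
rank-sum sensitivity (PS, per-subject): p = 0.0012
```

The macrovascular volume fraction is indistinguishable between arms (the
treatment model leaves the feeding vessels intact), while the stratified
microvascular VV and PS are systematically lower in the treated arm across
the near-vessel zone. `results/` now contains `report.json`,
`subjects.csv`, per-subject and per-arm stratified profiles, and a QC plot
of the VV/PS-versus-distance curves.

The same study from the command line:

```bash
vascstrata run --seed 1 --out results/
vascstrata verify --report-dir results/    # re-derives every report number
```

Individual stages are also exposed (`vascstrata phantom`, `pk-fit`,
`vessel-seg`, `strata`); volumes travel as NIfTI, tables as CSV, metadata
as JSON. See `docs/methods.md` for the full model description, parameter
tables and limitations.

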