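# splenotex

Quantitative 3-D texture and volumetry analysis for optical-CT images of
mouse spleen, built around a three-reference-point grey-level co-occurrence
matrix (GLCM), together with a synthetic spleen-phantom generator for
validating the whole pipeline against known ground truth.

## Who this is for

Optical computed tomography (optical CT / OPT) of optically cleared organs
produces isotropic 3-D reconstructions in which haemoglobin absorption maps
splenic microstructure: bright red pulp (RP), dark white-pulp (WP)
follicles, and intermediate marginal zones (MZ) in a dense honeycomb.
Changes in that honeycomb — for example after treatment with a vascular
disrupting agent, which shrinks the spleen and its internal features — can
be quantified by whole-organ volumetry and by texture statistics, without
the sampling bias of 2-D histology. This package provides that analysis
chain end to end for researchers working with such volumes, and a phantom
module for anyone who needs spleen-like test volumes with ground truth.

## The statistic at its core

A classical 2-D GLCM counts ordered grey-level pairs at displacement *d*
and angle *θ*. Per-slice 2-D texture of a 3-D organ is slice-dependent, so
the co-occurrence statistic is extended with a **third reference point**
probing depth. For a volume *I* and displacements Δx = Δz = d·cos θ,
Δy = d·sin θ, the 3-D GLCM counts triples

    i = I(x, y, z),   j = I(x+Δx, y+Δy, z),   k = I(x, y+Δy, z+Δz),

normalised to a probability tensor P(i, j, k). Two Haralick-style features
are derived:

    contrast    = Σ P(i,j,k) · [(i−j)² + (i−k)² + (j−k)²]
    homogeneity = Σ P(i,j,k) / [1 + (i−j)² + (i−k)² + (j−k)²]

swept over *d* and averaged over θ ∈ {0°, 45°, 90°, 135°}. The displacement
at which contrast peaks tracks the characteristic feature size of the
tissue, so cohorts with smaller internal structures peak at smaller *d*.

Around this sit the standard steps: per-ROI preprocessing (linear 8-bit
scaling, histogram equalisation, width-3 median filter), organ volumetry
from keyframe contours every 20 slices interpolated by signed-distance
blending, and an exact one-tailed Mann–Whitney U test suited to n = 3 per
group, where the smallest attainable p is exactly 1/C(6,3) = 0.05.

## Worked example

```python
import splenotex as st

# Full phantom study: 3 vehicle vs 3 treated spleens (treated scaled by
# 0.896 linearly => ~28% volume loss, internal features by a further 0.9)
report = st.run_pipeline(seed=1)

vc = report["volume_comparison"]
pk = report["peak_contrast_displacement"]
print(f"p = {vc['p_value']:.2f}")
print(f"volume ratio (treated/vehicle) = "
      f"{vc['volume_ratio_treated_over_vehicle']:.3f}")
print(f"shrinkage of means = {vc['percent_shrinkage_of_means']:.1f}%")
print(f"peak contrast displacement: vehicle {pk['vehicle_mean_px']:.1f} px, "
      f"treated {pk['treated_mean_px']:.1f} px")
```

prints

```
p = 0.05
volume ratio (treated/vehicle) = 0.718
shrinkage of means = 28.2%
peak contrast displacement: vehicle 13.8 px, treated 12.5 px
```

The p-value 0.05 is the combinatorial floor of the exact test — every
vehicle volume exceeds every treated volume. The measured volume ratio
0.718 recovers the generator's 0.896³ ≈ 0.72 shrinkage, and the treated
cohort's peak-contrast displacement is smaller than the vehicle's,
reflecting its smaller white-pulp follicles.

The 2-D feature simulation (four images of lymph-node discs in marginal-zone
annuli at grey levels 0/128/255 on a red-pulp background) shows the same
mechanics in isolation:

```python
fig = st.feature_simulation_study()
print(fig["peaks"]["i"].displacement, fig["peaks"]["iii"].displacement)
# 45.6 50.8  -> smaller features peak at smaller displacement
```

A command-line interface mirrors the library: `splenotex run`,
`splenotex feature-image`, `splenotex preprocess`, `splenotex texture`,
`splenotex volumetry`, `splenotex simulate-features`.

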