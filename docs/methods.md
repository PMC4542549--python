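# Methods

## The three-reference-point co-occurrence statistic

A 2-D GLCM at displacement *d* and angle *θ* counts ordered pairs
(I(x, y), I(x+Δx, y+Δy)) over all positions where both points are in
bounds. The 3-D extension adds a third reference point in depth: with
Δx = Δz = round(d·cos θ) and Δy = round(d·sin θ), each in-bounds triple

    i = I(x, y, z),  j = I(x+Δx, y+Δy, z),  k = I(x, y+Δy, z+Δz)

increments the count at (i, j, k). Conventions, chosen once and applied
everywhere:

- **Rounding** of the real-valued offsets is half-away-from-zero per
  component, so d = 2 at 45° gives (1, 1, 1). An alternative "chessboard"
  convention (±d on both axes at the diagonal angles) is available via
  `convention="chessboard"`, since the diagonal layout on a pixel grid is
  genuinely ambiguous; the literal rounding is the default.
- **θ = 135°** has negative Δx = Δz; the implementation takes the formula
  at face value and skips out-of-bounds triples.
- **θ = 90°** makes Δx = Δz = 0, so the second and third points coincide
  and the tensor is degenerate (all mass on j = k, contrast exactly twice
  the two-point contrast of the pair marginal). The angle is kept in the
  default four-angle set for fidelity to the four-direction average; the
  degeneracy is noted in debug logs and covered by a structural test.
- **Normalisation** divides raw counts by the number of valid triples.
  This is what makes homogeneity land in (0, 1]; feature functions reject
  unnormalised input.
- **No symmetrisation**: matrices are directional. Angle averaging is the
  only pooling, and matrices are averaged before features are taken.
  Because contrast and homogeneity are linear in P, averaging per-angle
  feature values is algebraically identical; the displacement-sweep code
  exploits this to stream features from the co-occurring value arrays
  without materialising Ng³ tensors (a test pins the equivalence to the
  explicit-matrix route).
- **Boundary policy**: triples partially outside the volume are skipped,
  never padded or wrapped — padding would invent intensities.
- **Grey depth**: the data model is 8-bit (Ng = 256; a 2-D GLCM then has
  2¹⁶ elements). A uniform requantisation v ↦ v·Ng/256 supports smaller
  Ng; the study defaults use Ng = 64, which keeps the statistic dense
  enough to be stable on the phantom ROI sizes.

The peak of a contrast-vs-displacement curve is located by argmax plus the
vertex of the quadratic through the three surrounding samples, giving
fractional displacements; a maximum at either end of the sweep is returned
unrefined and flagged `at_boundary`. A constant curve has no unique peak
and raises.

## Preprocessing

ROI extraction → linear min–max scaling to 8-bit (round-half-up; constant
input maps to zero) → per-ROI histogram equalisation → width-3 median
filter. Equalisation uses the classical mapping
v ↦ round(255·(cdf(v) − cdf_min)/(N − cdf_min)) and is applied per ROI,
preserving intra-sample contrast at the cost of inter-sample comparability
of absolute grey values (recorded in provenance). Equalisation can amplify
noise, which is the median filter's purpose — hence the default order
filter-after-equalisation, with the reverse available as a config switch
since either reading is defensible. The median filter truncates its window
at boundaries rather than padding (no invented intensities) and takes the
lower median for the resulting even-sized windows; it runs in 3-D (3×3×3)
on volumes and 2-D (3×3) on single slices, matching data dimensionality.

## Volumetry

The organ is contoured on keyframe slices every `slice_step` (default 20)
slices, anchored at the first and last slices intersecting the object; the
final partial interval is interpolated over its actual gap. Keyframe
segmentation is Otsu's threshold (computed globally over the volume, after
excluding the bright-artifact tail above the artifact percentile — per-slice
Otsu is ill-posed on near-empty pole slices, and extreme streaks otherwise
dominate the between-class variance), an intensity cap at the per-slice
`artifact_percentile` (default 99.9) emulating manual exclusion of highly
attenuating streaks, largest connected component, hole filling, and a
marching-squares boundary traced on a one-pixel-padded mask so that
border-touching components still yield closed polygons. Externally drawn
keyframe polygons can be supplied as JSON to preserve a manual workflow.

Intermediate slices blend the signed Euclidean distance transforms of the
bracketing keyframe masks linearly in z and threshold at zero — the
standard reproducible choice for contour interpolation. It preserves any
region common to both keyframes, reproduces the keyframes exactly, and for
concentric discs interpolates the radius linearly. Volume is voxel count ×
voxel volume ((26 μm)³ = 1.7576×10⁻⁵ mm³ at the default voxel size).

Known discretisation bias: linear interpolation under-fills where the
cross-section profile is concave, i.e. at the organ poles, so volumes are
slightly underestimated; at the default phantom geometry the deficit is
~2.5% at step 20 and ~0.2% at step 5, and it cancels almost exactly in
between-cohort ratios. A human reviewer's slice-by-slice corrections have
no algorithmic counterpart here; that QC step is a limitation.

## The spleen phantom

The generator emulates reconstructed-volume-space spleens: an ellipsoidal
organ of bright red pulp (blood is the dominant absorber) containing dark
white-pulp nodules wrapped in intermediate marginal-zone shells, bright
vessel tubes, additive Gaussian noise, and occasional bright streak
artifacts crossing the slice plane. Nodules are placed by rejection
sampling with a minimum separation that keeps marginal zones from merging;
placement failure after bounded retries raises, reporting the achieved
count. A treated cohort scales the whole geometry by `cohort_scale`
(default 0.896, i.e. 1 − 0.896³ ≈ 28% volume loss) and the internal
feature sizes by a further `feature_scale` (default 0.9), modelling
marginal-zone contraction. Everything is deterministic given the spec's
seed; cohorts derive per-sample seeds from one base seed via
`numpy.random.SeedSequence`.

Ground truth records the tissue label grid and the exact spleen voxel
count. Artifacts are an intensity corruption: inside the spleen the
underlying tissue label is kept (as with real reconstruction streaks
overlying anatomy) and artifact voxels are tracked in a separate mask;
outside the spleen they carry their own label.

Default study conditions (chosen once, at desk scale): grid 224×96×96
voxels at 26 μm; semi-axes (x, y, z) = (40, 34, 100) voxels so that the
20-slice keyframe step is proportionally comparable to a full-resolution
organ spanning most of a 512-slice scan; 55 nodules of radius 5.5 ± 0.7
voxels with 2.5-voxel marginal zones, giving the dense honeycomb texture
of real spleen; intensities RP 1.0 > MZ 0.55 > WP 0.2 over background
0.05, vessels 1.25; noise σ = 0.04; one streak artifact at intensity 2.5;
n = 3 per cohort. Texture uses a 56×56×48 ROI centred on the spleen (long
axis along z, mirroring how a real ROI is placed inside the organ away
from boundaries), Ng = 64, d = 1..20, four angles.

What the phantom does **not** model: optical physics (scattering,
refractive-index mismatch), clearing-induced differential shrinkage,
projection-space reconstruction and its characteristic noise correlations,
non-ellipsoidal organ shape, and spatial heterogeneity of follicle size.
Passing tests on phantoms therefore demonstrate that the measurement chain
recovers known geometry and group differences of the modelled kind — not
that real tissue contrasts behave identically.

## The 2-D feature simulation

Four images of four disc features each (lymph-node core at grey level 0,
marginal-zone annulus at 128, red-pulp background at 256 clamped to the
8-bit maximum 255, with the clamp recorded in provenance). Within each
feature-size pair the outer radius is fixed and the marginal zone grows
inward at the lymph node's expense, varying the MZ area ratio: small
features (outer 16 px) with 4 px vs 10 px MZ, large features (outer 28 px)
likewise. Disc membership is centre-of-pixel Euclidean distance, boundary
inclusive. The study sweeps 2-D contrast over d = 1..60 and checks two
laws: smaller features peak at smaller displacement, and a thicker
marginal zone (softer RP–WP transition) lowers peak contrast. The exact
radii driving published versions of such simulations are not fixed here;
the defaults are configurable and make both laws hold cleanly.

## Statistics

- **Exact Mann–Whitney U**, one-tailed, by full enumeration of all
  C(nA+nB, nA) assignments of the combined midranks; ties need no separate
  correction. At n = 3 vs 3 the attainable p-values are multiples of 1/20,
  with floor 0.05 at complete separation — an asymptotic approximation is
  meaningless at this size, so totals above 20 are rejected rather than
  approximated.
- **Group curves**: per-displacement group means; a displacement is
  "separated" when the two groups' value ranges are disjoint; maximal runs
  are reported as intervals.
- **Peak statistics**: per-group mean of per-sample peak displacements,
  spread as sample SD by default (SEM by config switch — published
  "±" conventions are often unstated); boundary peaks are included but
  flagged. With two groups and a voxel size, the mean difference is also
  reported in micrometres.
- **Percent change** is reported for both means and medians of the cohort
  volumes, since central-tendency conventions differ between reports.

## Reproducibility

Every pipeline run embeds its resolved config and a hash of it plus the
seed in the report; the CSV/JSON outputs are byte-identical across reruns
with the same config and seed. All problem sizes above were selected as
the package's desk-scale defaults; every one of them is a config field.
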