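# Methods

## Problem and model

Soft-tissue attenuation (diaphragm, breast, lateral chest wall) removes
counts from myocardial perfusion SPECT images in a spatially structured
way, producing apparent perfusion defects. When a CT-based
attenuation-corrected (AC) reconstruction of the same acquisition is
available, the ratio of the non-attenuation-corrected (NAC) image to the
AC image isolates the artifact: wherever no attenuation acted the ratio
is ≈ 1, and attenuated regions fall below 1. `attenquant` quantifies the
artifact from this ratio on a standardized segment grid.

The left ventricle is reduced to an `n_slices × 12` matrix: a fixed
number of contiguous short-axis slices counted from the base (20 at
4 mm voxels for the CZT camera profile, 12 at 6.4 mm for the
conventional profile), each divided into twelve 30° sectors about the
in-plane LV centre. Per-segment counts are normalized by the grand
total over all analyzed segments, so all downstream quantities are
invariant to global count rescaling (acquisition time, administered
activity).

With `r_ij` the per-segment ratio of normalized NAC to normalized AC
counts and `M = {(i,j) : r_ij < τ}` the artifact mask at the per-camera
threshold `τ` (0.90 CZT, 0.85 conventional; strict inequality):

- **Extent** `= |M| / (n_slices · 12)` — the fraction of the grid
  inside the artifact.
- **Localization** — the circular mean (direction of the unit-vector
  resultant) of the sector-centre angles of the segments in `M`, each
  weighted equally; undefined for an empty mask, and flagged degenerate
  when the resultant vanishes (antipodal masks). A depression-weighted
  variant (weights `1 − r_ij`) is available as an option.
- **Depth** `= mean(NAC counts over M) / mean(NAC counts over the k
  highest-count segments)`, `k = round(0.30 · n_segments)` (72 of 240
  CZT, 43 of 144 conventional), ties broken by segment index. Depth is
  the fractional count level surviving inside the artifact — 73% means
  a 27% count reduction. It is computed on the NAC grid by default
  (the artifact is a property of the uncorrected image); an AC-based
  variant exists and returns ≈ 1 on synthetic data, since true AC
  images carry no artifact.

Note the renormalization coupling: because grids are normalized by
their own totals, an artifact that removes counts from the NAC image
raises the ratio of every *unattenuated* segment to `T_AC / T_NAC > 1`
and maps an injected transmission factor `f` to a measured ratio
`f · T_AC / T_NAC`. Delineation is therefore reliable as long as
`f · T_AC / T_NAC < τ < T_AC / T_NAC`, which holds with wide margins
for realistic factors (0.6–0.8) and extents (< 40%).

## Angular convention

0° at the anterior wall, increasing anterior → lateral (90°) → inferior
(180°) → septal (270°); sector `i` covers `[30i, 30(i+1))` (half-open,
no voxel splitting; voxel angle taken at the voxel centre) with its
centre at `30i + 15`. This frame puts the classic inferolateral
attenuation artifact near 150–170° and is configurable
(`AngularConvention(offset_deg=…, sense=…)`) because short-axis display
conventions differ between vendors.

## Synthetic phantom

The generator emulates a physical cardiac phantom insert imaged at the
two camera profiles, not a patient: a uniform cylindrical myocardial
shell (outer radius 32 mm, wall 10 mm, axial span = analyzed span;
optional hemispherical apical cap kept apical to the analyzed slices),
filled at a constant expected count density (default 500 counts/voxel,
giving segment sums of a few thousand counts, typical of summed
clinical slices). The default radius/wall pair is deliberate: the
voxelized annulus splits into exactly equal sector voxel counts at both
4 mm (120 voxels/slice) and 6.4 mm (48 voxels/slice) grids, so every
segment of a noiseless phantom has identical expected counts and
fixture metrics are analytically exact rather than
discretization-polluted.

On this shell:

- **Attenuation artifact** — multiplicative transmission factor
  `f ∈ (0,1)` applied to the NAC volume only, inside non-overlapping
  angular × slice zones. This is a phenomenological stand-in for
  attenuation physics: it reproduces the defining signature (sector
  ratios drop to `f`, exactly, noise off) but models no depth
  dependence, scatter, or reconstruction coupling.
- **True defect** — the same voxel set (greedy nearest-voxel fill to
  the requested volume, realized volume within one voxel of the
  request) scaled by an uptake factor in BOTH volumes, mimicking a
  solid insert. Because NAC and AC lose the same counts, per-segment
  raw-count ratios are unchanged and the pipeline must report identical
  metrics with and without the defect — the computational form of the
  phantom control experiment in which the defect appears identically on
  both cameras while the artifact moves.
- **Poisson noise** — independent draws on NAC and AC voxel
  expectations (emission counting statistics), streams spawned from one
  seed; everything regenerates bit-identically from (config, seed).
  The NAC/AC ratio of Poisson counts is biased at low counts; the
  default count density keeps segment-level relative SD near 1.4%
  (CZT), so delineation margins are ≈ 5σ or better.

Simulated cohorts draw per-acquisition extent and depth percentages
from truncated normals and the artifact centre from a normal; the drawn
extent is realized as one contiguous sector-aligned block (width
`ceil(n_target / n_slices)` sectors over the most basal slices) centred
on the drawn angle, so realized extents differ from draws only by
block-rounding (≲ 0.6 percentage points at the CZT grid). A single
contiguous block matches the single inferior/inferolateral artifact
morphology typical of supine male imaging.

What passing tests on these phantoms do **not** show: robustness to LV
axis tilt, apical thinning, non-uniform uptake, extra-cardiac activity,
reconstruction artifacts, or camera-specific resolution effects. The
generator is a verification harness for the quantification pipeline,
not a physics simulation.

## Numerical and design choices

- **LV centre**: by default one shared in-plane centre per study — the
  count-weighted centroid of the summed analyzed AC stack, reused for
  the NAC volume (paired-geometry contract). A per-slice centroid mode
  exists, but a focal cold defect drags the centroid of the slices it
  touches (~0.3 voxel for a 2.1 cm³ defect) and re-bins boundary
  voxels, perturbing depth by ~2 points; the shared centroid dilutes
  that leverage below the minimum voxel-to-sector-boundary margin
  (1.7° at the 4 mm grid), keeping binning, and hence all metrics,
  exactly defect-invariant. The shared centre assumes an untilted
  short-axis stack, which reformatted clinical data satisfies by
  construction.
- **Slice selection**: the most basal slice is the last one whose count
  sum exceeds 1% of the maximum slice sum (robust to noise-only
  slices); analysis proceeds apically for exactly `n_slices` slices.
- **Thresholding**: strict (`<`), no connectivity filtering by default
  (a wrap-aware largest-component option exists); undefined segments
  (AC = 0) can never join the mask but stay in the extent denominator.
- **Rounding**: percentages round half away from zero (18.75 → 19), to
  integer precision.
- **Degenerate inputs**: empty masks yield extent 0 with localization
  and depth undefined (null in JSON, never 0); antipodal masks flag the
  localization as degenerate; all-zero paired differences give a
  flagged `t = 0, p = 1`.
- **Paired comparisons**: localization differences are signed shortest
  angular differences; extent/depth differences are linear. Two-sided
  p from the t survival function.

## Problem sizes used in validation

The reference phantoms are noiseless single studies (seconds to
generate and quantify). Cohort recovery uses 37 noisy CZT acquisitions
(matching a realistic single-camera arm). The null calibration of the
paired t test uses 1,000 repetitions of 8 acquisition pairs at the
conventional-camera grid, chosen to give a Monte-Carlo SE of ~0.7
percentage points on the rejection rate while completing in well under
a minute.

## Known limitations

- The multiplicative artifact model is generative convenience, not
  physics; its realism is untested here.
- Myocardial membership on real data relies on a configurable radial
  band around the centre rather than model-based segmentation; on
  synthetic shells the default (no band) is exact.
- No 17-segment AHA mapping, perfusion scoring, or inter-camera image
  registration.
- The per-camera thresholds are fixed constants of the camera profile;
  their observer-based derivation is out of scope.
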