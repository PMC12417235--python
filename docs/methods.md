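# Methods

## Model and procedure

The collateral status of a stroke patient is summarized as a vessel-volume
ratio between a region at risk and its mirror image on the healthy
hemisphere. Two region definitions are supported on one scoring contract:

- **ODACS** — the region is the patient-specific occlusion-downstream area,
  approximated by CTP hypoperfusion: voxels with Tmax strictly greater than
  6 s. Using the hypoperfused region sidesteps explicit thrombus
  localization and adapts to anatomical variation, which matters most for
  distal (M2) occlusions where fixed territory atlases are unreliable.
- **MCA-CS** — the region is an MCA-territory mask (any NIfTI mask, mapped
  to the patient grid with a user-supplied affine; no atlas is bundled).

Both scores are the ratio of segmented vessel volume (mL) in the
ipsilateral region to that in the mirrored contralateral region. Ratios may
exceed 1 and are not capped. A zero contralateral volume leaves the ratio
*undefined*: the result is flagged rather than raised, so cohort runs never
abort on one degenerate patient.

### Assumptions

- The CTA vessel segmentation and the Tmax map are on, or have been
  resampled to, a common axis-aligned grid (`assert_same_grid` enforces
  this). Registration *estimation* is out of scope; applying a given affine
  is supported (`resample_to_grid`).
- Volumes are reoriented to canonical RAS+ on load, so the left-right axis
  is always the first array axis and mirroring is well defined. Oblique
  affines are rejected rather than silently approximated.
- The midline is an explicit plane (point + unit normal in mm), supplied as
  a JSON sidecar by whatever extracted it; `default_midplane` (grid-centre
  plane, normal along left-right) is the fallback. Automatic symmetry-based
  midline estimation is not implemented.

## Downstream-area refinement

Perfusion software excludes vessels from its maps, so the thresholded
hypoperfusion mask contains vessel-shaped tunnels, and precisely the voxels
the score must count would fall outside the region. Morphological closing
with a 3D ellipsoidal structuring element — semi-axes (10, 10, 1) voxels in
(x, y, z), inclusive inequality `(dx/a)² + (dy/b)² + (dz/c)² ≤ 1` — fills
those tunnels. Notes on the exact semantics:

- Semi-axes are in voxel units (a config option is the natural place for a
  mm-specified element on differently sampled data). At 5 mm slices the
  element is nearly planar: its only out-of-plane offsets are (0, 0, ±1).
  A consequence visible in tests: a tunnel spanning the *full* z-extent of a
  slab refills only on interior slices, because the outermost slices see
  background through the z-offsets. Lesions are thicker than one slice in
  practice, so carved vessels interior to the lesion are recovered.
- The volume is padded with background by the element extent before
  dilation and cropped after erosion; the image border therefore never
  spuriously closes gaps. Closing is extensive, idempotent, and monotone,
  and is verified voxel-for-voxel against a brute-force set-based oracle.
- Setting `closing_semi_axes: [0, 0, 0]` disables the refinement (the
  element degenerates to the origin voxel). On phantoms with carved vessels
  this demonstrably collapses the measured ratio — the refinement step is
  what makes the score well defined on real CTP output, not a cosmetic
  smoothing.
- No connected-component filtering is applied to the hypoperfusion mask;
  it is used exactly as thresholded.

## Mirroring

Reflections are computed in physical mm space (voxel-centre convention),
so anisotropic voxels are handled correctly, and each reflected point is
assigned to the nearest voxel centre; exact half-voxel ties round toward
the lower index for determinism. For grid-symmetric planes this is an exact
involution and preserves voxel counts; for arbitrary planes, reflections
landing off-grid are dropped and counted in a warning. The region pair
records the lesion side (majority hemisphere), the ipsi/contra overlap
fraction (warned above 5% — midline-straddling lesions), and z-slice
coverage.

## Categorization

The quantitative ratio is mapped to the 4-level Tan scale with relaxed
outer boundaries: CS 0 iff r < 0.05, CS 1 iff 0.05 ≤ r ≤ 0.5, CS 2 iff
0.5 < r ≤ 0.95, CS 3 iff r > 0.95. The relaxations exist because minor
false-positive vessel segmentations would otherwise forbid the extreme
categories entirely. The stated relaxations are strict inequalities on the
open ends but silent about the boundary points themselves; we assign
boundary points to the inner categories, preserving the original scale's
"≤ 50%" inclusivity pattern. Ratios above 1 satisfy r > 0.95 and map to
CS 3. The extended scale refines only the interior: 1a spans [0.05, 0.25],
1b (0.25, 0.5], 2a (0.5, 0.75], 2b (0.75, 0.95]. Dichotomy: good = CS 2–3,
poor = CS 0–1.

## Cohort statistics

- **Weighted kappa** is implemented from the definition
  κ = 1 − Σw·O / Σw·E with quadratic weights w_ij = (i−j)²/(K−1)² and
  chance expectation from the marginals; it is cross-checked in tests
  against an independent pair-by-pair oracle and scikit-learn. The category
  set is fixed by the declared scale (K = 4, or 6 for the extended scale)
  even when categories are unobserved, so weights do not drift across
  subsets. If both raters are constant on the same category κ = 1 by
  convention; a zero expected disagreement with nonzero observed
  disagreement is mathematically impossible (any off-diagonal observation
  makes its expected cell positive), but the code flags it defensively.
- **Wilcoxon signed-rank** (one-sided, ODACS < MCA-CS) drops zero
  differences, uses the exact distribution for ≤ 25 tie-free differences
  and the normal approximation with tie correction otherwise (via
  scipy.stats.wilcoxon); the exact path is verified against full 2ⁿ
  enumeration in tests.
- **Bland–Altman**: differences MCA-CS − ODACS, limits mean ± 1.96·SD with
  sample (n−1) SD.
- **Shift proportion**: patients whose reference (MCA-CS) category is good
  but whose ODACS category is poor, over all defined pairs, reported as
  numerator/denominator.
- Medians/IQRs use linear interpolation between order statistics
  (numpy's default percentile convention). Undefined scores are excluded
  pairwise with counts reported; groups with fewer than two patients have
  inferential statistics set to null. No multiple-testing correction.

## Phantom generator

Phantoms emulate the measurement situation, not brains: a 96×96×18 grid at
1×1×5 mm (5 mm slices match clinical CTP reconstructions), a one-sided
ellipsoidal Tmax lesion (background 2 s, lesion 10 s), capsule
(line-segment tube, radius 1.2 mm) vessels rasterized in physical
coordinates, and a grid-centre midplane. Contralateral anatomy is the exact
voxel mirror of the ipsilateral candidate set; a controlled deficit is
created by selecting/trimming capsules until the in-region voxel count
matches the target ratio, with the last capsule shortened voxel-by-voxel
along its axis. Truth volumes are therefore exact by brute-force counting
(calibration against counts, not analytic capsule volumes, absorbs
rasterization error); the achieved ratio is within ±0.02 of target, limited
only by integer rounding. Target ratios above 1 are realized by thinning
the contralateral side instead.

Additional realism hooks:

- `carve_vessels_from_tmax` resets lesion-interior vessel voxels to
  background Tmax, reproducing the vendor vessel-removal artifact; only the
  closing step can recover these voxels.
- Symmetric background vessels are placed inside the territory but clear of
  the (dilated) downstream region, so the deficit is strictly confined to
  the downstream area and the containment ordering ODACS ≤ MCA-CS holds by
  construction: MCA-CS = (B + rC)/(B + C) ≥ r for r ≤ 1 (B = symmetric
  background volume, C = contralateral in-region volume).
- `render_cta` produces an intensity image (vessel contrast + Gaussian
  noise) for the fallback threshold segmenter, which stands in for a
  trained vessel-segmentation model (out of scope here; the scoring API
  accepts any binary segmentation).

What the phantoms do **not** model: CT noise texture and beam hardening,
vascular tree topology, partial-volume effects at vessel boundaries,
imperfect midline estimation, registration error, and venous contamination.
Passing the phantom suite shows the *pipeline arithmetic* is correct —
thresholding, closing, mirroring, volume ratios, categorization — not that
segmentation or registration of real scans would be accurate.

Synthetic cohorts draw occlusion location with the clinical mix (52%
proximal M1, 32% distal M1, 16% M2) and shrink the lesion for more distal
strata — semi-axes (18,18,22), (15,15,18), (11,11,14) mm — echoing the
clinical hypoperfused-volume gradient at desk scale (lesions of roughly
30/17/7 mL; the small grid keeps the full 50-patient simulation in seconds
on one CPU). Target ratios are uniform on [0.1, 1.1]; two simulated raters
categorize the truth ratio with Gaussian reading noise (SD 0.08 and 0.12).
Because lesion size only scales C, the expected gap MCA-CS − ODACS =
B(1−r)/(B+C) grows as lesions shrink — the distal-occlusion overestimation
effect — and the cohort tests verify this ordering and its Wilcoxon
significance end-to-end.

## Numerical and design choices

- Tmax threshold is strict (`> 6 s`); the value is configurable (e.g. 4 s)
  but 6 s is the conventional hypoperfusion definition.
- Mirroring ties round toward the lower index; interpolation is linear for
  scalars and nearest-neighbour for masks everywhere.
- Mask NIfTIs are written as uint8 0/1 volumes for interoperability.
- Reports embed full provenance (package version, config echo, SHA-256 of
  inputs, midplane, lesion side), making every report reproducible from its
  own metadata.
- Every entry point that uses randomness requires an explicit seed; nothing
  seeds from the clock.

## Known limitations

- No registration or midline *estimation*: inputs must be pre-aligned or
  accompanied by transforms, mirroring the reliance on upstream vendor
  processing.
- Limited CTP z-coverage truncates the downstream area and is not detected
  beyond the reported `coverage_slices`.
- The fallback segmenter is a threshold with component-size cleanup,
  suitable for phantoms only.
- Agreement statistics report point estimates without confidence intervals.
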