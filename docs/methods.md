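# Methods

## Scope and measurement model

The package measures corneal neovascularization (CoNV) as an *area density*:
the fraction of a matched region of interest (ROI) classified as vessel in a
binarized angiogram, expressed as a percentage. Two derived statistics are
built on it:

- **Vessel density percentage** over ROI A: `(∫ V dA / ∫ dA) × 100` with
  V = 1 on vessel pixels, computed as an exact pixel-count ratio (one
  rounding at output only).
- **Vessel growth density** between consecutive follow-ups: the previous
  binary map is registered into the new frame, subtracted
  (`new AND NOT previous`), change components of ≤ 2 px (8-connectivity)
  are discarded as misalignment debris, and the surviving new-vessel pixels
  are divided by the same ROI area. Applied to two repeat scans of one time
  point, the identical computation gives the repeated-scan error floor.

The subtracted-mask procedure and the plain week-to-week density difference
coincide exactly when masks are nested, registration is perfect and no
components are filtered (a property the tests assert). They diverge when
vessels regress or debris is filtered; the subtracted-mask form is the
primary output because it is the quantity the overlay visualization shows,
and the plain difference is reported alongside
(`GrowthMeasurement.plain_difference_percent`). Regression is exposed as a
separate non-negative channel (`regressed_px`, previous-only pixels) rather
than as negative growth, since the one-sided component filter makes a signed
percentage ill-defined.

## Pre-processing

- OCTA en-face scans: 3×3 median filter (radius 1) then Gaussian smoothing
  with σ = 1 px, suppressing speckle and single-row motion lines. ICGA/SLP
  get no smoothing by default (configurable), only background correction.
- All modalities: white top-hat with a disk structuring element, default
  radius 12 px for the 3 mm / 304 px pitch. SLP vessels are dark on a bright
  cornea, so SLP images are complemented first. Border handling is reflect
  (half-sample symmetric) everywhere; the brute-force test oracles pad the
  same way.
- The top-hat defaults to a *plain* grayscale opening. An
  opening-by-reconstruction variant is available
  (`use_reconstruction=True`), but on scenes whose vessel network is
  connected at near-uniform intensity the reconstruction regenerates the
  entire network from any single blob wider than the element and zeroes the
  residual — a failure mode that real, intensity-varying angiograms mask but
  synthetic noiseless scenes expose directly. The element radius must exceed
  the widest expected vessel *cluster* half-width, not just a single vessel:
  with radius 12 the residual preserves vessels up to junction-cluster
  scale, and the noiseless pipeline recovers truth density almost exactly.

## Local-phase enhancement and binarization

The "enhance then automatically threshold" stage is built on the monogenic
signal: log-Gabor band-pass filters at wavelengths {3, 6, 12, 24} px
(bracketing vessel widths of roughly 2–10 px at 9.87 µm/px), with the Riesz
transform supplying the isotropic odd-quadrature pair. The phase-congruency
ratio

```
pc = max(0, Σ_s even_s) / (Σ_s A_s + ε),   A_s = sqrt(even_s² + odd_s²)
```

is high where the local phase is bright-ridge-like regardless of absolute
contrast (the DC bin is zeroed, and pc is a ratio, so the map is invariant
to affine intensity remaps — asserted to 1e-3 in tests). It gates a
quantile-normalized copy of the input (`(x − q01)/(q99.5 − q01)`), giving a
ridge map in [0, 1] whose amplitude is meaningful across bright and dim
image regions alike.

Binarization defaults to Otsu-seeded hysteresis: seeds at the Otsu split of
the gated map, grown through connectivity down to a linking level placed
`low_ratio = 0.6` of the way from the background floor (median of
sub-threshold pixels) to the seed level. The hysteresis linking is what
retains dim small-caliber vessels that are attached to the network while
rejecting isolated dim responses; `low_ratio` trades a dilation bias (too
low) against loss of attenuated vessels (too high), and 0.6 centers the
density error near zero across seeded scenes. Global Otsu and a local
mean + k·σ rule (window 31 px, k = 0.05) are kept as comparison modes. A
constant enhanced image yields an all-background map, not an error — a scan
with no vessels is a legitimate observation.

The exact local-phase construction used by the emulating study is
unpublished; the parameters above are declared package defaults, and the
comparison modes exist so sensitivity to this choice can be reported.

## Registration

Global 2-D transforms (translation; similarity = translation + rotation +
isotropic scale, the default, matching magnification and acquisition-angle
differences; full affine behind a flag) are estimated with SimpleITK:
Mattes mutual information (50 bins) for cross-modality pairs, where
intensity relationships are non-linear, or normalized cross-correlation for
same-modality pairs; dense metric sampling (deterministic); 3-level
pyramid; regular-step gradient descent capped at 300 iterations/level.
A fit reports `converged=False` — never an exception — when either input is
constant or the final score falls below a per-metric floor (0.3 for
correlation, 0.15 for MI); independent noise fields land far below both.
Transforms are 3×3 homogeneous matrices on (x = col, y = row) pixel
coordinates, pixel centers at integer coordinates, mapping the moving frame
into the fixed frame. Intensity images are warped with linear
interpolation, binary maps with nearest neighbor; out-of-field pixels are
excluded from every overlap mask, and the measurement ROI is the
intersection of overlaps minus any manual exclusion mask (iris background
removal is reproduced as a mask-file input, never an interactive step).

## Synthetic scenes

The generator emulates the study conditions the pipeline is meant for:
suture-induced CoNV in the superior quadrant, imaged weekly for 8 weeks on
a 3 × 3 mm field sampled at 304 × 304 (≈ 9.87 µm/px).

- **Geometry**: straight capsule segments (line segment + radius) — the
  simplest geometry with an exact per-pixel membership oracle. Week 1
  sprouts 6 roots from the limbus edge; each later week attaches 14 new
  branches to existing segments at random branching angles (30–70°, the
  in-field side preferred so border clipping does not starve growth).
  Segment length 0.8–1.4 mm; large-vessel radius 20–40 µm; 30% of segments
  are small-caliber (radius 8–18 µm, below the ≈ 2 px ICGA/SLP
  detectability limit motivated by the ~10 µm visibility scale of the
  modality). These defaults yield ≈ 15% density at week 3 rising to ≈ 32%
  at week 8, with ≈ 3.5 percentage points of new density per week — the
  regime in which weekly growth must be distinguished from scan noise.
- **Rendering**: bright vessels on dark background for OCTA/ICGA, dark on
  bright for SLP. Degradations are phenomenological, not physical:
  multiplicative speckle and additive Gaussian noise; 2 single-row motion
  lines (OCTA); 2 bright horizontal iris bands in the lower image half and
  a Gaussian leakage halo whose gain ramps over the first 4 weeks (ICGA);
  low-frequency background texture (SLP); small-caliber contrast attenuated
  by 0.9 for ICGA/SLP (a free simulation parameter — the real
  between-modality contrast deficit is not quantified anywhere). Repeat
  scans reuse the scene with a fresh noise seed plus a 0.5 px sub-pixel
  jitter emulating re-positioning between acquisitions minutes apart.
- All randomness flows through explicitly seeded generators; identical
  seeds give bit-identical trees, masks and renders.

What passing the synthetic battery does **not** show: capsule trees have no
curvature, taper or depth; artifacts are stylized; SLP color texture is
reduced to luminance; and no simulation reproduces biological regression,
scarring or dye dynamics. Recovery results bound algorithmic error, not
agreement with histology.

## Statistics

Bland–Altman analysis uses differences `d_i = a_i − b_i`: sample mean and
SD (n−1), limits of agreement mean ± 1.96 SD (the multiplier is a
parameter), and a t-based 95% CI of the mean difference with n−1 df —
reconstruction of published CIs is consistent with t, not z. Paired
comparison adds Pearson r, a two-sided paired t-test, and a KS normality
check per series with the Lilliefors correction on by default (the normal
parameters are estimated from the sample; the uncorrected one-sample KS
against the fitted normal is available). Degenerate inputs are flagged, not
raised: zero-variance differences give collapsed LoA with a
`degenerate_variance` flag and t-test p = 1; constant series give
`correlation_undefined`. No multiple-testing correction is applied. Monte
Carlo checks (2000 simulations at n = 22) put CI coverage in the nominal
93–97% band; the mean LoA width sits ≈ 1–2% below the closed form, the
expected small-sample bias of the sample SD (c₄(30) ≈ 0.991).

## Problem sizes and numerics

Validation experiments run at the native 304 × 304 scene size: 10 scenes
for density recovery (noiseless and default noise), 10 triplets for the
modality ordering, 20 trials for growth-vs-repeat discrimination and for
registration recovery, 2000/1000 simulations for the statistical
calibration. Internal arithmetic is double precision; density ratios are
exact integer counts divided once; reports round to 2 decimals
(configurable). Filters document reflect padding so independent oracles can
match to 1e-6; component filtering and pixel counts match brute-force
implementations exactly.

## Known limitations

- The registration model is strictly global; deformable motion (breathing,
  corneal curvature across a wide field) is out of scope.
- The local-phase stage assumes vessels are the dominant coherent ridge
  structure; dense pathology (scar ridges) would pass the gate.
- Densities from different devices remain comparable only inside the
  registered, matched ROI; no field-of-view harmonization beyond the
  overlap intersection is attempted.
- ICGA frame selection (dye transit timing) is upstream of this package;
  one operator-selected frame per session is assumed.
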