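# Methods

This note documents the model implemented by `sonoshadow`, the
conventions and numerical choices behind it, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Detection model

The detector is a fixed rule pipeline inside a clinician-drawn ROI;
it contains no learned components and is a pure function of
(pixels, ROI, configuration).

**Intensity scale.** The ROI is min–max normalized and multiplied by
`scale_max` (default 1000), giving *scaled intensity units* (SIU).
The screening thresholds τ_LC = 300 and τ_SR = 100 are expressed in
SIU and applied to this scale directly; a unit-interval normalization
alone would make thresholds of this magnitude unattainable. Because
both screening statistics are intensity *differences*, they are
invariant to constant offsets and scale linearly with intensity — the
thresholds are absolute and therefore meaningful only on this fixed
scale. A constant ROI maps to all zeros.

**Candidate generation.** White top-hat (disk radius 5 px) responds
to bright structures too narrow to contain the disk; stones wider
than ~11 px survive the opening and are *not* enhanced, which bounds
the stone sizes this operating point can detect. Thresholding keeps
pixels strictly above the 99th percentile (linear-interpolation
percentile over all ROI pixels); components under 20 px are removed
(8-connectivity throughout); the regional-maxima gate keeps only
components containing a connected plateau whose outside neighbors are
all strictly lower. Region descriptors follow the moment-equivalent
ellipse convention of standard region-properties implementations
(no sub-pixel moment correction; solidity uses the pixel-center
convex-hull rasterization, so a plus-shaped pentomino has solidity
exactly 1). Mean intensity is measured on the denoised SIU image,
not the top-hat response. Brightness is the integrated intensity
μ·A — the product reading; a quotient would penalize larger stones.
The elongation penalty term is max(0, L_max/L_min − tol) with
tol = 2.0: mildly elliptical stones are not penalized, and setting
tol = 0 recovers a raw-ratio penalty. A degenerate minor axis
(collinear pixels) saturates the term at 10.

**Screening.** The ring for local contrast is the candidate bounding
box expanded by 5 px per side, clipped to the image, box excluded; a
box spanning the whole image has no ring and the candidate is
rejected as not evaluable. Axial profiles start at the first row
below the candidate bounding box and run for up to 30 rows. The
center band is 5 columns around the rounded centroid (rounding half
away from zero); the lateral reference is the union of two 5-column
bands offset ±10 px, falling back to the surviving band if one is
fully outside the image. The drop row is the argmin of the forward
differences of P_C, the rise row the argmax among later differences;
P_Ce is the profile up to and including the drop row and P_Cl the
segment from the next row through the rise row. When the drop sits at
the final row (or the profile never decreases) the transition term is
zero. Thresholds use "≥ passes". Under this reading the transition
term is positive for genuine bright-stone → dark-shadow transitions
and near zero for flat or noise profiles, so the score grows rather
than vanishes for true stones.

**Scoring.** The four features live on incommensurate scales
(brightness ~10³–10⁴ SIU·px, contrasts ~10²–10³ SIU, penalty ~0–1),
so each feature is min–max normalized across the surviving candidates
of the image before the weighted combination; winner selection is
invariant to any common monotone rescaling, so normalization
preserves the ranking intent while making the weights commensurate.
With a single survivor each salience feature is defined as 1 and the
penalty as 0 when its raw value is 0 (and 1 otherwise); the same
convention covers all-equal feature columns. A raw-sum mode is
retained for sensitivity analysis. Ties break by higher shadow-region
score, then shallower centroid, then smaller lateral position.

**Shadow onset and ROI.** The onset is the row after the steepest
decrease of P_C, or the profile start when the profile never
decreases. The posterior shadow ROI spans the winner's column extent
from the onset for up to 30 rows. Known trade-off: the profile starts
below the candidate *bounding box*, so when the thresholded candidate
covers the whole stone the profile begins inside the shadow and the
steepest-drop search degenerates to noise — the onset then lands
somewhere within the shadow column rather than at its top. The
alternative (starting at the centroid row) would sharpen onset
localization for stones but would hand shadow-free bright lines a
large spurious transition term and break the screen's selectivity;
we keep the bounding-box convention and accept coarser onset
estimates.

## Evaluation protocol

Localization error is the perpendicular distance from the predicted
centroid to the expert axis line through the two annotated endpoints
(general form a·x + b·y + c = 0 with a = y_b − y_a, b = x_a − x_b),
reported in pixels and in millimetres at 0.35 mm/px. A prediction
counts as correct when it falls in a capsule around the annotated
segment: perpendicular distance ≤ 0.5·|AB| and longitudinal
projection within the segment extended by 0.25·|AB| beyond each end
(boundaries inclusive). The capsule is our surrogate for the
expert-drawn "suspected stone region": it uses only the two collected
endpoints and scales with stone size; both factors are configurable.

Group summaries report mean ± sample SD (n − 1 denominator) with
t-based 95% CIs (absent for n = 1). Interobserver agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single rater —
for the annotation center coordinates and axis length, with ≥ 0.75
read as good and ≥ 0.90 as excellent.

The ablation runner evaluates four score variants — {B}, {B,C},
{B,C,S}, {B,C,S,P} — where dropping a feature zeroes its weight and
disables its screen (the penalty has no screen). Accuracy is reported
per (variant, confidence group).

**Distance convention.** Accuracy is evaluated with the default gated
pipeline, where a frame whose candidates all fail the screens yields
`no_candidate` (counted incorrect). An abstained frame has no
distance, so centroid-distance statistics are computed in an
*always-predict* localization mode (screens contribute to the
composite score but do not gate), mirroring a cohort in which every
image is known to contain a stone and contributes a localization
error.

## Phantom generator

The phantoms emulate the features the detector consumes — local
brightness, ring contrast, and axial profile structure — not acoustic
physics. A frame is smoothed Rayleigh envelope noise (scale 1,
Gaussian σ = 1.2 px) rescaled to a mean of 300, with an elliptical
stone (multiplicative gain, 1 px soft edge), a posterior shadow
column of the stone's lateral extent, and optional thin bright line
confounders with no posterior attenuation. Shadow grades map to the
three diagnostic-confidence strata:

| grade    | attenuation | length | edge feather | stone gain | stratum |
|----------|------------:|-------:|-------------:|-----------:|---------|
| weak     | 0.20        | 10 px  | 3 px         | 2.4        | 50–60%  |
| moderate | 0.45        | 20 px  | 2 px         | 2.8        | 60–80%  |
| strong   | 0.70        | 40 px  | 1 px         | 3.2        | ≥ 80%   |

The weak grade interrupts its column with two random 2–3-row gaps
(faint, discontinuous shadowing). Stone gain co-varies mildly with
grade (weakly shadowing stones echo somewhat more faintly), but the
dominant difficulty driver is the shadow itself. The dataset
generator randomizes stone position, semi-axes (5–7 × 3.5–5 px),
orientation (±0.35 rad) and gain (±~8%); the optional confounder is a
25 × 3 px horizontal line at 1.15× the stone gain placed laterally
beside the stone — bright enough to win a brightness-only contest,
shadow-free so the shadow screen rejects it. These values are
fixture conventions chosen so that the default SIU thresholds
separate strong shadows from confounders; they are not clinical
measurements. All ground truth (stone mask, centroid, axis endpoints,
shadow mask) is derived analytically from the spec parameters, never
measured from the rendered image.

What passing phantom tests shows: the pipeline's rules interact as
designed — shadows rescue confounder-dominated frames, difficulty
orders weak/moderate/strong, stone-free speckle is rejected. What it
does not show: robustness to fan-beam geometry, depth-dependent gain,
scan-conversion interpolation, anatomical clutter, or scanner
post-processing, none of which the phantoms model.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 30 phantoms
per grade (20 for the strong-recovery check, 50 stone-free frames),
160×160 px frames, and ROIs of roughly 130×110 px — sizes at which
every statistic stabilizes while the full suite runs in well under a
minute per cohort. All randomness flows through explicit integer
seeds (phantom generation only; detection itself is deterministic),
and CLI reruns with identical inputs and configuration produce
byte-identical result files.

## Known limitations

- Thresholds are absolute on the SIU scale; frames whose dynamic
  range is dominated by a single very bright structure compress all
  other contrasts (visible in the confounder experiments).
- The 99th-percentile threshold allocates a fixed pixel budget: very
  large bright structures can crowd smaller stones out of the
  candidate map.
- Shadow-onset estimation is coarse when the candidate box covers the
  whole stone (see above); the shadow ROI is still placed within the
  shadow column but not necessarily at its top.
- Stones wider than the structuring element survive the opening and
  are suppressed by the top-hat; detecting them requires a larger
  `se_radius`.
- Weak, discontinuous shadows frequently fail τ_SR at the default
  operating point; the gated pipeline then abstains, which is scored
  as incorrect in accuracy terms.
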