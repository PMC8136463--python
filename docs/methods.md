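# Methods

`echodim` implements, end to end, the validation methodology for automated
parasternal long-axis (PLAX) left-ventricular measurements: four landmarks
(`sept_ant`, `sept_post`, `pw_endo`, `pw_epi`) define three guideline
dimensions — interventricular septal thickness (IVS), LV internal diameter
(LVID) and posterior-wall thickness (PW) — each the Euclidean mm distance
between its two keypoints after pixel-spacing conversion.  An automated
reader is judged against a consensus of blinded experts, and its keypoint
placement errors are decomposed relative to the consensus measurement lines.
Because clinical image data cannot ship with a package, every stage is
exercised on a synthetic phantom study whose structure mirrors the
multi-reader validation design.

## Synthetic study generator

**What it emulates.** 100 echocardiograms, each contributing one
end-diastolic and one end-systolic frame (both "from the same video"); 13
accredited experts annotating every frame twice, mutually blinded; one AI
reading per frame, i.e. 26 expert evaluations + 1 automated evaluation per
frame.  True dimensions are drawn per study from truncated normals with the
validation-cohort population values — LVIDd 47.0 ± 6.4 mm, LVIDs 37.7 ± 7.3
mm, IVSd 11.7 ± 2.4 mm, PWd 11.0 ± 1.6 mm — resampled until positive and
until LVIDs < LVIDd.  Wall thicknesses are held equal across the two phases
of a study; only the cavity diameter changes (real walls thicken in systole,
but no phase-specific thickness parameters are part of the design).

**Phantom rendering.** Two bright wall bands flanking a dark cavity band
along a per-study measurement axis (default angle uniform in 60–120° from
the image x-axis), plus additive Gaussian speckle (SD 0.05 in [0,1]
intensity units), 256×256 px at 0.5 mm/px.  This is deliberately minimal:
the image exists so that the heatmap codec, cropping and augmentation
operators have consistent visual structure to act on; it makes no attempt at
speckle physics, and nothing in the statistical pipeline reads pixel values.

**Rater noise model.** Every keypoint is displaced in physical mm in the
local frame of its own measurement line (`sept_ant`→IVS line, `sept_post`
and `pw_endo`→LVID line, `pw_epi`→PW line): a *transverse* Gaussian
component along the measurement direction with SD
`transverse_sd_frac × line length`, and a *longitudinal* component
perpendicular to it (along the myocardium) with SD
`longitudinal_sd_frac × line length`.  Readings, raters and keypoints are
independent; missingness is independent per keypoint per reading
(`miss_prob`, default 1 % for experts, 0 for the AI).  A systematic
`bias_mm` lengthens the targeted dimension by exactly that amount (the
line's endpoints move ∓b/2 along the line, anchored at the LVID midline), so
a configured bias propagates to the signed deviation unchanged.

**Defaults as study conditions.** The AI preset is longitudinal 15 %,
transverse 7 % of line length; the expert preset is the pooled observed
per-point component spread of real readers (longitudinal 23 %, transverse
11.5 %), with each expert's two fractions scaled by a per-expert factor
drawn once from U(0.7, 1.3) so that individual experts differ, as real ones
do.  Two consequences of this independent-Gaussian endpoint model are worth
stating because they differ from real readers:

* Component fractions are preserved, but dimension-level mm SDs come out
  larger than real readers achieve for the LVID, because real endpoint
  errors are correlated along the ventricle (both points slide together),
  which cancels in the distance.  The generator makes no attempt to model
  that correlation.
* Noise scales with the *true* line length, so end-systolic measurements
  (shorter cavity) carry slightly *smaller* mm errors; in real data systole
  is harder, not easier.  Phase comparisons on synthetic data therefore test
  the machinery, not the clinical direction of the effect.
* Because a Euclidean distance is convex in its endpoints, longitudinal
  noise inflates measured lengths on average (≈ σ²_long/L per endpoint
  pair).  The noisier expert consensus inflates more than the AI, so the AI
  shows a small negative LVID bias against consensus even with no configured
  bias.  This is a genuine property of distance-based measurement under
  anisotropic keypoint noise, not an artifact of the implementation.

## Heatmap codec and image operators

Keypoint targets are Gaussian heatmaps with intensity exactly 1 at the point
and SD 4 px (broad targets reflect that readers cannot re-select the same
pixel); maps are not renormalized after boundary truncation.  Decoding takes
the peak coordinate only — no sub-pixel refinement — with row-major
first-occurrence tie-breaking for determinism.  A missing keypoint encodes
to an all-zero map, decodes back to missing, and carries loss weight 0.

Inference-time images are centre-cropped to 640×640 with zero padding; the
odd pixel of an asymmetric crop or pad goes to the trailing side, and the
`CropSpec` coordinate map is exactly invertible for surviving points.
Training-time augmentation applies a random affine (rotation ±15°, isotropic
scale 0.9–1.1, translation ±5 % — ranges are package choices), a gamma
change I→I^γ with γ in 0.7–1.4, and rectangular erasure up to 10 % of the
area.  The affine acts identically on image and keypoints; keypoints mapped
out of bounds are flagged invalid, whereas erasure never invalidates a
keypoint (it is a regularizer, not a missingness mechanism).

## Consensus and agreement statistics

Per-reading dimensions are computed in mm; a dimension is missing iff either
keypoint is missing, and values are never clamped.  The reference standard
per frame and dimension is the median across experts of each expert's median
reading (with two readings, their mean; an expert with one missing reading
contributes the other).  At least `min_experts = 3` experts must contribute,
otherwise the reference is missing.  The evaluated expert's own readings are
*included* in the consensus, as in the original design; this flatters each
expert slightly (verified as a property test), and a leave-one-out flag
exists for sensitivity analysis.  A pooled-readings consensus (median over
all 26 readings) is available behind `consensus="pooled"`; the
per-expert-median-first rule is the default because the validation-phase
description reduces each expert to their median opinion first.

For each method (AI and each expert individually) and each stratum
(dimension × phase ∈ {ED, ES, pooled}) the package reports: bias (mean
signed deviation), precision SD (sample SD, n−1), absolute-deviation
quantiles at 50/80/90/95 % (linear interpolation between order statistics,
matching the R type-7 default of the original analysis environment), the
empirical cumulative error curve, and ICC.  The ICC form is ICC(2,1) —
two-way random effects, absolute agreement, single rater — computed from the
two-way ANOVA mean squares of the (method, reference) pairs across frames
with the McGraw–Wong F-based 95 % CI, clipped to [−1, 1]; no specific
variant was mandated, so the standard agreement-with-a-reference choice is
used and flagged in reports.  Exact agreement (zero residual mean square)
returns ICC 1 with undefined (NaN) interval bounds.

SD comparisons use the variance-ratio F test (two-sided p = twice the
smaller tail, as in R's `var.test`); paired absolute errors use the Wilcoxon
signed-rank test (their folded-normal distribution rules out a t test), with
zero differences dropped, an exact null for n ≤ 25 and a
continuity-corrected normal approximation above.  α = 0.05 throughout, with
no multiplicity adjustment.  Strata with n < 2 are marked unavailable rather
than raising.

## Keypoint-error decomposition

Each reading's keypoint deviation from the consensus keypoint location
(coordinate-wise median across experts of per-expert median positions — the
consensus construction for point locations is a package choice, flagged) is
projected onto the consensus measurement line of its own structure,
equivalent to rotating and rescaling the image so the consensus line is
vertical with unit length.  The component along the measurement direction is
*transverse*, the perpendicular one *longitudinal*; both are signed
fractions of line length (reported ×100 as %).  Signs: transverse positive
towards the line's end (posterior) point; longitudinal positive towards the
+90° side (visually counterclockwise from the line direction, with image y
down).  All projections are computed in mm so anisotropic pixels cannot
distort angles; the decomposition satisfies Pythagorean closure to 1e−9
relative tolerance and is invariant under global similarity transforms.
Summaries report component SDs per method/phase/keypoint and per line (the
two LVID keypoints pooled), with F tests for longitudinal vs transverse and
for the posterior vs anterior LVID point.

A mapping of keypoints to lines is needed because `sept_post` belongs to two
structures (it ends the septum and starts the cavity diameter); it is
treated as an LVID keypoint (decomposed — and simulated — against the LVID
line), which is the assignment under which recovering the generator's
longitudinal/transverse fractions from the LVID panel is well-posed.

## Numerical and design choices

* Medians of even counts are the mean of the middle two, everywhere.
* Simulated keypoints are clipped to image bounds (annotators click inside
  the image); with default geometry this is a ≥4 SD event.
* `grouped_train_split` assigns shuffled whole videos greedily to the
  training partition subject to `floor(train_frac · n_frames)`; with
  one-frame videos this reproduces an exact 1515/379 split of 1894 frames at
  80/20.
* One sequential `numpy` Generator drives a whole study, so a (config, seed)
  pair reproduces the dataset byte for byte, including PNGs and CSVs.
* Parameter-recovery checks run the AI against a consensus of zero-noise
  experts so the reference lines equal truth; with noisy experts the
  recovered fractions are structurally inflated by consensus noise
  (≈ √(frac² + σ²_consensus)), a property of the reference rather than of
  the estimator.

## Problem sizes

The default generator reproduces the design scale (100 studies → 200 frames,
13 experts × 2 readings + AI → 5 400 evaluations, 21 600 keypoint rows), and
`scripts/acceptance.py` runs at exactly that scale.  Unit and property tests
use 8–40 frames and 1–5 experts, which is ample for the exact worked
examples and the fixed-seed calibration suites (200-replicate isotropy
calibration, 2 000-replicate F-test type-I check).

## Known limitations

No speckle physics, no cine loops, no pathology, no frame-selection
modelling; expert error correlation between endpoints and across readings is
not modelled (see above); heatmap decoding is integer-pixel (peak only), so
sub-pixel localization error of a hypothetical network is outside scope, as
is the network itself.
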