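# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical conventions, and the design choices behind
`blindval`.

## The blinded validation protocol

The package operationalises a reader study for subjective segmentation.
Given a complete grid of masks (every image segmented by every source),
`design.build_schedule` constructs one presentation per (image, source)
pair plus, per source, a configurable number of covert repeats of
uniformly chosen distinct images.  The whole pool is permuted uniformly
at random; the permutation and all sampling derive from a single integer
seed, so a schedule is reproducible byte for byte.  Each slot receives a
random 128-bit presentation id — sequential ids would leak generation
order, which correlates with source.  The identity map
(presentation id → image, source, replicate) is sealed into a separate
checksummed file; the review stage structurally cannot read it (path
guard in the CLI plus a schema audit of the bundle), and the analysis
stage refuses to run without it.  One schedule serves one validator;
independent validators get independent schedules with independent seeds.

## Statistics

**Dice.** `dice(a, b) = 2|A∩B|/(|A|+|B|)` on boolean rasters of equal
shape and image.  Two empty masks score 1.0: two raters agreeing that
the image contains no target region is perfect agreement.  (Real
dense-tissue studies never hit this case; the convention matters only
for degenerate synthetic inputs.)  Empty-vs-nonempty is 0 by the
formula.

**DSC summaries.** Collections of per-image DSC values are reported as
mean ± sample sd (n−1 denominator) with a Student-t interval,
mean ± t₁₋α/2,n−1 · sd/√n.  The t-interval rather than a normal-z
interval is deliberate: for strata of a few dozen images the difference
is visible at the third decimal, and the t form is what reproduces
published interval bounds computed from printed (mean, sd, n) rows.
Singleton strata carry no interval and are flagged instead of silently
reporting ±0.

**Proportion intervals.** Accuracy and agreement proportions get Wilson
score intervals (via `statsmodels`).  Wilson rather than Wald: at
n = 300 and p ≈ 0.92 the Wald interval is visibly off (its bounds do not
match published three-decimal values where Wilson's do), and Wilson
behaves sensibly at the boundaries.

**Repeat (intra-observer) metrics.** The covert repeats yield a k×k
confusion matrix — rows the first evaluation, columns the second — and a
2×2 binary collapse (agree = the scheme's agree subset, default
{correct}).  From the 2×2 matrix, with the first evaluation as reference
and agree as positive class: accuracy = (TP+TN)/n with Wilson CI;
precision = TP/(TP+FP); recall = TP/(TP+FN); balanced accuracy =
(recall + specificity)/2; F1 = harmonic mean of precision and recall;
Cohen's kappa = (p_o − p_e)/(1 − p_e) with p_e from the full marginals.
This orientation (replicate 1 = reference) is the one that uniquely
reproduces both published metric rows recovered by the integer-search
oracle in `tests/test_acceptance.py`.  When p_e = 1 (all mass in one
marginal cell) kappa is undefined and reported as `None`, never as 0.
Kappa on the k×k matrix uses the same chance-corrected formula with full
marginals.

**The first-pass / repeat split.** Agreement percentages, stratified
DSC, and order effects use only replicate-1 responses; the repeats feed
only the intra-observer analysis.  This is what makes each source's
denominator equal the image count (e.g. 3 × 500 = 1500 first-pass items
and 300 repeat pairs in the reference design).

**Order of appearance.** For each image, the replicate-1 presentations
of its sources are ranked 1..S by schedule position: rank r means the
source's mask was the r-th version of that image the validator saw.
Covert repeats are excluded from ranking by default — ranks are then
exactly {1..S} per image with no ties.  A duplicate-inclusive variant
(`order_ranks(..., include_duplicates=True)`) lets repeats occupy rank
slots; how repeated presentations should rank is genuinely ambiguous in
a blinded design, so both conventions are available and the exclusive
one is the default.

**Sessions.** Responses are ordered by answer time; a new session starts
when an item was shown more than `gap_threshold` seconds (default 3600)
after the previous answer.  The rule is strictly-greater: a gap of
exactly one hour does not split.  Session duration runs from first
shown to last answered, which for a single-item session is that item's
own display span — this keeps throughput (items/hour) finite and
meaningful for one-image sessions.

No multiple-testing correction is applied anywhere: the outputs are
descriptive agreement figures, not hypothesis tests.

## Synthetic cohort model

`simulate.gen_masks` draws, per image, a base region — an ellipse with
random centre, axes, rotation, and a low-order sinusoidal boundary
wobble — and, per source, a perturbed copy (centre/axes/phase jittered
by the source's perturbation magnitude in pixels, with axes floored at
2 px so jitter cannot annihilate the region).  Expected pairwise DSC
decreases monotonically in the perturbation.  The defaults (500 images,
96×96 rasters, sources L1/L2/model with perturbations 4/4/6 px, 100
covert repeats per source) were fixed once so that the cohort matches
the reference study's structure and its typical pairwise DSC band
(≈ 0.70–0.79).  Seeding is hierarchical (master seed → per-image →
per-(image, source) streams), so growing `n_images` leaves earlier
images unchanged.

`simulate.simulate_validator` draws one latent judgment per
(image, source): agree with probability
clip(base_agree[source] + rank_offset[rank], 0, 1), where rank is the
order of appearance; a disagree draw also fixes its category from the
configured split (default 0.5/0.4/0.1 over
oversegmented/undersegmented/incorrect).  Each *evaluation* of the item
then flips the binary judgment independently with probability ε
(default 0.04), re-drawing the category on the flipped side.  Two
evaluations of a repeated item therefore disagree with probability
2ε(1−ε) — ≈ 7.7% at the default, matching the observed repeat
discordance rates (7.67% and 8.67%) of the two reference validation
rounds.  Timestamps follow a session plan (item counts and gap lengths);
the default plan splits the run into 28 sessions with the final two
holding one item each, mirroring the reference study's session
structure, with per-item dwell times drawn from a gamma distribution
around 45 s.

**What the generator does not model.**  The validator's labels are
drawn from per-source probabilities and are *independent of the actual
mask overlap*: the synthetic concordance-stratified DSC therefore does
not reproduce the real-data pattern where same-label images have higher
DSC, and passing pipeline tests on synthetic data says nothing about
that coupling in real studies.  Masks are smooth convex-ish blobs, not
anatomy; there is no image-difficulty structure, no device/year
covariates, and no drift in the validator's criterion over time.  The
generator validates the machinery (cardinalities, partitions, metric
arithmetic, parameter recovery), not the psychology.

## Numerical conventions

* Internal computation at full double precision; headline tables are
  conventionally read at 3 decimals.  Report CSVs are written at 6
  decimals so regeneration from identical inputs is byte-identical.
* Published interval bounds recomputed from *rounded* printed means/sds
  can disagree with a full-precision recomputation by ±0.001; the
  implementation always recomputes from raw values and does not chase
  such bounds.
* One published accuracy interval (second validation round, 274/300) is
  inconsistent with every standard binomial interval for that count
  (Wilson gives ≈ 0.876–0.940) and appears to duplicate the first
  round's row; the package reports the recomputed Wilson interval.
* Raster binarization: any strictly positive pixel value is foreground;
  multi-channel rasters count a pixel as foreground if any channel is
  positive.
* Timestamps are stored timezone-aware and normalised to UTC, so the
  one-hour session rule is unambiguous across offsets.
* `closest_mean_dsc` (mean over images of the larger of two per-image
  DSC values) dominates both componentwise means; it is the right
  summary for "how close is the model to the *nearer* expert".

## Problem sizes

The test suite and the acceptance script run the full reference-scale
synthetic study (500 images × 3 sources + 300 repeats, 96×96 rasters)
plus larger label-only simulations where precision demands it (5,000
repeat pairs for the ε-recovery check; 20 × 3,000 images for
order-effect sign recovery).  Label-only runs skip mask rasterisation
entirely (`simulate_study(..., with_masks=False)`), which keeps the
whole suite under a minute on one CPU.

## Known limitations

* The review loop ships with a stdin driver and a programmatic driver
  interface; a browser front-end must honour the same contract (strict
  schedule order, two timestamps, no provenance) but is not included.
* Label-definition drift — the phenomenon where a validator's use of
  `incorrect` vs `oversegmented` changes over a round — can be measured
  (order effects, per-session agreement) but not prevented by software;
  clearer instructions to the validator are the actual fix.
* Binary masks only: no probabilistic or multi-class segmentation, no
  boundary metrics (Hausdorff), no DICOM I/O.
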