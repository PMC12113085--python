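# blindval

Blinded reader-study design and inter-/intra-observer reliability
analysis for image segmentation masks.

## The problem

When segmentation is subjective — dense-tissue delineation on
mammograms is the motivating case — there is no clean ground truth:
expert annotators disagree with each other (inter-observer variability)
and with themselves over time (intra-observer variability).  Comparing a
model's masks against any single expert therefore conflates model error
with human inconsistency.

`blindval` implements a blinded validation protocol for this setting.
All masks for a set of images — from human annotators and/or automatic
models — are pooled, shuffled into a random order, and stripped of any
indication of origin.  A random subset per source is covertly included a
*second* time.  An independent validator reviews the anonymized stream
one mask at a time, labelling each as `correct`, `oversegmented`,
`undersegmented`, or `incorrect` (the scheme is configurable).  Because
the validator is blind to sources, agreement rates are unbiased across
human and machine; because of the covert repeats, the validator's own
consistency is measurable.

## What it computes

With masks `A`, `B` of the same image, spatial agreement is the Dice
similarity coefficient

    DSC = 2|A∩B| / (|A| + |B|)  ∈ [0, 1].

Per-image DSC collections are summarised as mean ± sd with a Student-t
interval (t with n−1 df) on the mean.  From the validator's responses
the package derives:

* **Agreement by source** — per source, the label counts and the percent
  of first-pass presentations judged acceptable (labels collapse to
  agree/disagree through the scheme).
* **Concordance-stratified DSC** — for each source pair, per-image DSC
  split by whether the validator gave both sources the same binary
  judgment.
* **Intra-observer reliability** — the covert repeats yield k×k and 2×2
  confusion matrices (rows = first evaluation, columns = second), from
  which: accuracy (observed agreement) with a **Wilson score interval**,
  **Cohen's kappa** κ = (p_o − p_e)/(1 − p_e), balanced accuracy, F1,
  precision and recall (first evaluation as reference, positive class =
  agree).
* **Order-of-appearance effects** — agreement as a function of whether a
  source's mask was the 1st, 2nd, … version of its image the validator
  saw.
* **Session analytics** — review sessions are maximal runs with no break
  longer than one hour; each gets duration, throughput, and agreement.

A synthetic-cohort module generates the whole experiment end to end —
masks with controllable pairwise DSC, a schedule with covert repeats,
and a stochastic validator with configurable agreement probabilities,
repeat-flip rate ε (binary repeat discordance 2ε(1−ε)), per-rank order
bias, and a session plan — so every pipeline stage is testable without
any real images.

## Worked example

```python
from blindval import (CohortConfig, DEFAULT_SCHEME, ValidatorBehavior,
                      agreement_by_source, build_schedule,
                      confusion_from_repeats, detect_sessions, dice,
                      gen_masks, rater_metrics, simulate_validator,
                      stratified_dsc)

cfg = CohortConfig(n_images=40, seed=7, duplicates={"L1": 8, "L2": 8, "model": 8})
catalog = gen_masks(cfg)                                  # 40 x 3 masks
plan, prov = build_schedule(catalog, cfg.duplicates, seed=7)
log = simulate_validator(plan, prov, ValidatorBehavior(seed=7))

print(len(plan))                                          # 144 presentations
print(agreement_by_source(log, prov, DEFAULT_SCHEME)[["total", "percent_agree"]])
rep = confusion_from_repeats(log, prov, DEFAULT_SCHEME)
m = rater_metrics(rep.overall_binary)
print(f"accuracy={m.accuracy:.3f} ({m.acc_ci_low:.3f}, {m.acc_ci_high:.3f}) "
      f"kappa={m.kappa:.3f}")
```

prints

```
144
           total  percent_agree
source_id
L1            40           77.5
L2            40           85.0
model         40           90.0
accuracy=0.917 (0.742, 0.977) kappa=0.455
```

144 presentations = 40 images × 3 sources + 24 covert repeats.  The
percent-agree column counts first-pass `correct` labels per source (the
repeats are excluded, so each denominator is 40).  The 24 repeats give
the 2×2 matrix behind the accuracy (fraction of repeats judged the same
way twice, with its Wilson 95% interval) and kappa (the same agreement
corrected for chance — low here because with only 24 mostly-agree
repeats, chance agreement is high).

## Command line

```
blindval design   --manifest manifest.csv --duplicates L1=100,L2=100,model=100 \
                  --seed 7 --out plan/
blindval review   --plan plan/bundle --out responses.csv
blindval simulate --config cohort.yaml --seed 7 --out study/
blindval analyze  --responses responses.csv --provenance plan/provenance.json \
                  --manifest manifest.csv --plan plan/bundle --out report/
blindval report   --tables report/ --plots
```

`design` copies each mask into the bundle under an opaque 128-bit
presentation id and seals the identity map into a separate
`provenance.json`; `review` refuses to see that file (the blinding
guard), and `analyze` refuses to run without it.  The report directory
holds deterministic CSV tables (agreement, stratified DSC, confusion
matrices, rater metrics, order effects, sessions).

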