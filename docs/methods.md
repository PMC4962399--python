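# Methods

## The assay and its analysis problem

`platescreen` analyses single-well phenotypic screens of the kind run with
transgenic zebrafish stress reporters: 96-well plates, one embryo per well,
a fluorescent readout per well, 12 positive-control wells (a reference
inhibitor such as riluzole, expected to cut the signal roughly in half),
12 negative vehicle (DMSO) wells and 48 test compounds per plate, each
compound measured once per screen replicate. With no within-plate
replication, per-compound variance cannot be estimated, so classical
two-group statistics do not apply well. The package implements the
replicate-free SSMD* ("B value") approach: score each well against its own
plate's test-compound population.

## Per-well score (SSMD*)

For well *i* with reading *X<sub>i</sub>* on a plate whose reference wells
(by default all ok test wells of that plate) have median *m* and median
absolute deviation MAD:

    score_i = (X_i − m) / (√2 · 1.4826 · MAD)

Assumptions and choices:

* **Most compounds are inert.** The plate's own test wells stand in for
  negative references; the median and MAD are insensitive to the minority of
  genuine hits. Robust location/scale is essential here — a mean/SD
  reference would be dragged by the very hits being sought.
* **1.4826·MAD** estimates the SD under approximate normality of the bulk.
* **√2** accounts for the variance of a *difference* between one well and
  the reference population. The constant is configurable
  (`AnalysisConfig.denominator_factor`) because conventions differ between
  published variants; √2 is the default.
* The scored well is included in its own reference by default (a median is
  insensitive to one well of ~48). A leave-one-out policy (`test_loo`) and a
  policy adding negative controls (`test_and_negative`) are available.
* A plate whose reference readings are identical (scale 0) or whose ok
  test-well count falls below `min_reference_size` (default 8) is a scoring
  error, surfaced per plate rather than silently skipped.

An important and easily-missed consequence of self-normalisation: an inert
well drawn from the same distribution as its reference has a null score SD
of 1/√2 ≈ 0.707 *regardless of the assay's noise level* (the score is
scale-free). A −0.5 cutoff therefore sits only ~0.7 null-SD from zero, and
per-well false-positive rates at that cutoff are intrinsically high unless
the reference population is wider than the truly-inert noise (see
"specificity" below).

## Control-group statistics

* `ssmd_controls`: median of all pairwise positive−negative differences
  divided by their sample (n−1) SD. Wells are unpaired, so all n·m pairwise
  differences are used. Inhibitory positives give negative values.
* `percent_reduction`: 100·(1 − mean(treated)/mean(control)); a
  median-based variant is available. Negative values indicate activation.
* `comparison_metrics`: S/B, S/N, Z-score separation and
  Z′ = 1 − 3(sd₊+sd₋)/|mean₊−mean₋|, provided only for side-by-side
  comparison with SSMD; degenerate denominators yield an undefined flag,
  not an error.

## Hit calling and concordance

Thresholds (configurable; strict inequalities): score < −0.5 → inhibitor,
< −1.0 → strong inhibitor, > +1.0 → activator, else inactive. Status
dominates score: dead wells are toxic, defective/excluded wells excluded,
before any score is consulted.

A compound is a final hit only when both screen replicates agree:
same class, with (strong_inhibitor, inhibitor) resolving to inhibitor —
concordant at the −0.5 level, discordant at −1.0. Toxic in either replicate
→ final toxic with a rescreen-at-lower-dose flag (1 and 0.1 μM manifest via
`toxic_rescreen_list`). Excluded in one replicate only → not_replicated
(unconfirmable), excluded in both → excluded. Activator calls carry an
informational autofluorescence-suspect flag (auto-fluorescent or toxic
compounds can inflate reporter signal); no correction is attempted.

The hit summary reports counts and percentages of compounds screened for
the four rows of interest: below −0.5, below −1.0, above +1.0, caused
death. Percentages are kept at full precision; rounding is display-only.

## Quality control

Per plate and threshold *t*: a positive control scoring < *t* is a true
positive, otherwise a false negative; a negative control scoring ≥ *t* is a
true negative, otherwise a false positive; then

    sensitivity = 100·TP/(TP+FN),   specificity = 100·TN/(TN+FP).

Screen-level QC reports mean ± SD of both metrics across plates, per
replicate and per threshold (SD across plates, 0 for a single plate).
Tightening the cutoff from −0.5 to −1.0 is monotone: sensitivity cannot
rise, specificity cannot fall. `control_variability` reports within-plate
CV of raw control readings and between-plate CV of plate control means
(sample SD), with a per-day breakdown when day labels exist. Plate
pass/fail is advisory: fail when no positive control shows activity or the
reference was degenerate; no data are deleted.

## Dose response

`dose_summary` reports per-dose n/mean/SD/percent-reduction versus vehicle
and a trend test: Spearman rank correlation between dose and per-well
reading (negative = dose-dependent reduction) with a one-sided, lower-tail
permutation p-value, estimator (b+1)/(B+1), B = 1000 by default, seeded.
Permutation rather than asymptotic inference because per-dose n is small
(12 wells). No IC50/Hill fit is attempted: the claim under test is monotone
dose-dependent reduction, not potency.

## Synthetic data

### Stochastic generator (`simulate_screen`)

Per ok well: `exp(N(log_mean, log_sd)) × effect × plate_effect × day_effect`.
Defaults and what they emulate:

| parameter | default | rationale |
|---|---|---|
| baseline | 1000 a.u., CV 15 % | positive right-skewed fluorescence; log-normal; CV chosen so a 50 % control effect is clearly separated yet noisy at n = 1 |
| positive_control_effect | 0.5 | the reference inhibitor's ≈50 % signal reduction |
| plate/day effect log-SD | 0.05 each | modest multiplicative batch shifts shared by all wells of a plate/day; exercises the score's plate-wise invariance |
| background_exclusion_rate | 0.02 | dead/defective embryos unrelated to compound toxicity |
| toxic_death_probability | 1.0 | planted-toxicity mode: toxic compounds kill |
| inert_effect_log_sd | 0.0 | optional compound-level heterogeneity shared across replicates |

One embryo per well; compound effects (and heterogeneity draws) are shared
across replicates, everything else is drawn independently per replicate.
All randomness flows from one seed.

`inert_effect_log_sd` matters for QC realism: with it at 0, the test-well
reference scale equals the control noise, the control null score SD is
pinned at 1/√2 and specificity at −0.5 plateaus near 76 % however low the
noise. Real screens show compound-to-compound variability that widens the
test-well reference beyond vehicle noise; setting the heterogeneity above
the well CV lets specificity approach 100 %, which is how the
high-effect/low-noise QC scenario (well CV 2 %, heterogeneity 0.15) is
constructed.

### Deterministic planted-truth screen (`simulate_planted_screen`)

Purpose: verify the decision logic — thresholds, concordance, summary
arithmetic — against *exact* planted counts end to end. Because the null
score SD is fixed at 1/√2 (above), no i.i.d.-noise screen can guarantee,
e.g., that exactly 38 of 2000 compounds fall below −0.5 in both replicates
while 1800 inert compounds never do; the expected number of concordant
false positives alone would be ~100. This generator therefore plants in
score space:

* Inert test wells form a sign-count-balanced "comb": a tight cluster just
  below the plate median plus a spread cluster on the positive side. The
  asymmetry exploits the asymmetric decision bands (−0.5 lower, +1.0 upper):
  the comb's realised scores stay strictly inside (−0.5, +1.0) for every
  count composition, which a symmetric distribution cannot achieve (the MAD
  of any distribution pins half its mass at |score| ≥ 0.477).
* Planted compounds are placed by fixed-point iteration so their realised
  score against the plate's own median/MAD equals a jittered target at the
  centre of the intended band (inhibitor −0.72, strong −1.55, activator
  +1.40); positive controls at −2.2, negative controls inside the inactive
  band. Toxic compounds emit dead wells in both replicates.
* Readings are emitted as `plate_level × (1 + 0.08 × deviation)` with a
  log-normal plate effect, so the data still look like fluorescence and
  still exercise the plate-wise invariance.

Plates carry the standard 12+12+48 layout; compounds are spread evenly
across `ceil(n/48)` plates (2000 compounds → 42 plates — the screen's
compound count, not its plate count, is authoritative). Both replicates
share the plate map; jitter, comb assignment and batch levels are drawn
independently per replicate.

What passing tests on this generator do and do not show: they verify the
pipeline's decision logic exactly; they say nothing about detection power
under realistic noise, which is what the stochastic generator's recovery
and QC properties probe (and where recall is genuinely partial near the
detection boundary).

### Dose series (`simulate_dose_response`)

Planted factor interpolates log-linearly in dose between 1.0 (vehicle) and
the top-dose effect: `factor(d) = 1 − (1−top)·log1p(d)/log1p(d_max)`;
log-normal noise per well; `top_effect = 1` gives a flat null series.

## Numerical choices and degenerate inputs

* Median/MAD via numpy; even-length medians average the middle pair.
* Strict `<`/`>` at thresholds; a control exactly at the cutoff is not a hit.
* Scale 0 (identical reference readings) and undersized references are hard
  per-plate errors; Z′/S/N with zero denominators are undefined flags.
* Affine invariance of scores holds to floating-point rounding (~1e−12
  relative; wells at the median are subject to catastrophic cancellation,
  hence an absolute floor of ~1e−14 in tests).
* Permutation p-values use the add-one estimator, so p ∈ (0, 1] and the
  null distribution is approximately uniform at resolution 1/(B+1).

## Problem sizes

Test-suite and verification runs use desk-scale screens: 2–8 plates for
stochastic properties, the full 2000-compound/42-plate planted screen for
hit-table verification (~1 s), 50 seeded repeats for effect recovery and
200 seeded runs × 400 permutations for null calibration.

## Known limitations

* No spatial (row/column/edge) normalisation — the model has no within-plate
  position effects, and none are simulated.
* No UMVUE/replicated-design SSMD estimators; the screen design is
  single-well by construction.
* The real assay's between-fish CV is not publicly known; all noise defaults
  are simulator parameters, not claims about the biology.
* Autofluorescence is flagged, never corrected.
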