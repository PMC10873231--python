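# Methods

`bmtriage` implements the post-detection analysis of a voxel-wise
brain-metastasis (BM) detection study: given a ground-truth segmentation
and a detector's segmentation for each patient, it quantifies detection
performance lesion by lesion, triages each patient into a treatment
suggestion from the count and volume of their lesions, and measures the
concordance of those suggestions with actual clinical decisions. A
calibrated synthetic-cohort generator replaces the scanner data and
trained network, so the entire pipeline is exercised end to end by code.

## Lesions and volumetry

A *lesion* is a connected foreground component of a 3D label mask.
Connectivity defaults to 26 neighbours (the usual 3D clinical
convention; 6 and 18 are available — published lesion counts rarely
state the convention used, so it is configuration, not a constant).
Physical volume is voxel count × voxel volume, with spacing taken from
the NIfTI header; nothing beyond spacing in the affine is used, because
the two masks being compared always live on the same co-registered grid.
A lesion's *diameter* is the equivalent spherical diameter
d = (6V/π)^(1/3), the inverse of the sphere-volume formula
V = (4/3)πr³. This makes the two expressions of the follow-up
criterion — "diameter ≤ 5 mm" and "volume ≤ 65 mm³" — coincide by
construction, since (4/3)π(2.5 mm)³ = 65.45 mm³. Maximum-extent
(RECIST-style) diameters are out of scope.

Lesion ordering is deterministic (descending volume, ties broken by
lexicographic centroid) so tables and reports are reproducible byte for
byte.

## Detection evaluation

A predicted lesion is a candidate match for a ground-truth lesion when
they share at least one voxel. Candidates are resolved **one-to-one**,
greedily by descending overlap-voxel count (ties: smaller predicted id,
then smaller ground-truth id). This is the default because it uses a
single true-positive count in both the sensitivity and PPV numerators,
which is how pooled results are normally reported. The literal
any-overlap reading is available as a mode in which one prediction may
account for several ground-truth lesions (sensitivity then counts
detected ground-truth lesions; PPV counts non-false-positive
predictions).

A prediction that overlaps only already-matched ground-truth lesions is
*absorbed*: it is part of an existing detection, so it is neither a true
nor a false positive. Consequently TP + absorbed + FP = n_pred, and
TP + FN = n_gt. Predictions overlapping nothing are false positives;
the false-positive rate is reported per patient (FP ÷ number of
patients), with patients who have no lesions still counting in the
denominator.

The FROC curve fixes the match labels once (matching is
threshold-independent) and sweeps the detector confidence: at each
distinct confidence value, detections below it are discarded and
sensitivity and FP/patient are re-counted. Both coordinates are
non-decreasing as the threshold falls; this is asserted at construction.

Undefined ratios (zero denominators) are reported as NaN, never as 0.

## Triage

With n the lesion count and V the total volume in mm³:

* **group A** (follow-up): n ≤ 2 and V ≤ 65 mm³;
* **group B** (limited disease; surgery/SRS): not A, n ≤ 10 and
  V ≤ 15,000 mm³ (15 mL);
* **group C** (extensive disease; WBRT/systemic therapy): otherwise.

The branches are exhaustive and disjoint over (n, V) and monotone: more
lesions or more volume never lowers the group. Boundary values belong to
the smaller group (n = 2, V = 65 → A; n = 10, V = 15,000 → B). A patient
with zero detected lesions is group A — follow-up is the only coherent
suggestion when nothing requiring treatment was found.

Whether the 65 mm³ cap applies to the *total* volume or to *each* lesion
is genuinely ambiguous in guideline phrasings ("≤ 2 lesions with
diameter ≤ 5 mm" reads per-lesion; "total volume > 65 mm³ or count ≥ 3"
defines B as the complement of a total-volume A). Total-volume mode is
the default, because only it makes the three groups an exact partition;
the strict per-lesion mode (largest lesion ≤ 65 mm³) is available via
`TriageConfig(volume_mode="per_lesion")`. All four thresholds live in
`TriageConfig` and are never inlined at call sites.

Reference groups come from the treatment actually given: follow-up → A,
surgery/SRS → B, WBRT/chemotherapy → C. The **targeted-agent override**
addresses EGFR/ALK-mutant NSCLC: for such patients without
lesion-related symptoms, upfront targeted chemotherapy replaces local
therapy as first-line treatment, so a patient triaged B whose actual
treatment was chemotherapy is re-classified as concordant when computing
the modified accuracy. Risk dichotomization maps A → low risk, B/C →
high risk.

## Agreement statistics

*ICC.* Counts and total volumes from the two sources are compared with
the single-measures two-way mixed consistency coefficient ICC(3,1):
(MS_R − MS_E)/(MS_R + (k−1)MS_E) from the two-way ANOVA without
interaction, k = 2 raters. The consistency form ignores a fixed additive
shift between raters (a detector that always reads 7 units high still
scores 1.0). The 95% CI uses the Shrout–Fleiss F construction. Both the
coefficient and CI are implemented from the ANOVA sums of squares; tests
verify exact agreement with an independent library implementation on
random data. A residual sum of squares below 1e−12 of the total is
snapped to zero to keep exact-duplicate inputs at ICC = 1.0 despite
floating-point cancellation. Fewer than 3 subjects or zero total
variance is an error, not a silent 0.

*Weighted kappa.* Ordinal concordance between triage groups uses Cohen's
kappa with linear disagreement weights |i−j|/(k−1) by default (the
scheme is configurable — linear, quadratic, unweighted — and named in
the report, since published values often omit it). Chance agreement
comes from the margin products. A table with all mass in one category is
reported as kappa 1.0 (agreement is trivially perfect).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the
emulated cohort's characteristics, fixed up front:

* **Cohort size** 112 patients.
* **Lesion counts**: zero-truncated negative binomial with truncated
  mean 8.5 and SD 12.22 lesions/patient (the SD ≫ mean requires
  over-dispersion, which rules out a Poisson law). The two untruncated
  parameters are solved numerically from the truncated moments. For
  parameter sets the family cannot reach (SD too small), the law falls
  back to a zero-truncated Poisson matched on the mean, and a mean of 1
  degenerates to exactly one lesion per patient.
* **Lesion volumes**: lognormal, solved in closed form from two
  constraints — 72.6% of lesions below 65 mm³, and a mean per-patient
  total volume of 1814.5 mm³, i.e. a per-lesion mean of 1814.5/8.5 =
  213.5 mm³ under independence of counts and volumes. (Reading
  1814.5 mm³ as a *per-lesion* mean instead would force σ ≈ 3.25 and put
  most of the distribution's mass in centimetre-scale lesions that never
  occur clinically; the per-patient reading gives σ ≈ 2.26 and realistic
  tails.) The solution is the positive root of
  σ²/2 − zσ − ln(mean/65) = 0 with z = Φ⁻¹(0.726).
* **Detector**: each true lesion is detected with probability
  expit(s·(lnV − ln m50)) — a logistic miss curve in log-volume, since
  small lesions are the ones detectors miss. The slope is fixed at
  s = 1.5 per log-unit and the midpoint m50 solved by Gauss–Hermite
  quadrature + bisection so the *expected* lesion-wise sensitivity
  equals 876/952 ≈ 92.0%. False positives arrive per patient as
  Poisson(160/112 ≈ 1.43) with small lognormal volumes (median 30 mm³,
  σ = 1 — vessel-like mimics). Detected volumes carry multiplicative
  lognormal noise (σ = 0.2 on the log scale); confidences are
  Beta(6, 2) for true and Beta(2, 5) for false detections.
* **Clinical decisions**: each patient's treatment is drawn from their
  ground-truth triage group's treatment set with probability 1 − ε, else
  from an adjacent group's set. The default ε = 0.11 follows from
  composing the two observed concordances (detector-vs-clinic ≈ 0.768
  and detector-vs-ground-truth ≈ 0.866 imply clinic-vs-ground-truth
  ≈ 0.768/0.866 ≈ 0.89 under rough independence). Within-group treatment
  weights mirror the cohort's treatment mix (group B: SRS 56:1 surgery;
  group C: chemotherapy 21:11 WBRT). A fraction 5/60 of concordant
  group-B patients (or an exact number, for controlled experiments) is
  flagged EGFR/ALK-mutant, asymptomatic, and switched to upfront
  chemotherapy — the patients the targeted-agent override recovers.

Everything is a pure function of (params, seed); per-patient substreams
are keyed by (seed, stream, patient index), so extending a cohort
preserves its early patients.

Optionally the generator renders masks: lesions become digital spheres
(voxels whose centers lie within the equivalent radius) placed without
overlap inside an ellipsoidal brain mask; simulated detections are
rendered centered on their source lesion so the ≥ 1-voxel overlap rule
binds, and false positives are placed off all true lesions. Placement
failure (too many/large lesions for the grid) raises an error naming the
patient. Table mode (no masks) instead records each detection's source
lesion id, and matching uses that provenance — the two routes agree and
are cross-checked in tests.

**What the generator does not emulate**: lesion shapes beyond spheres,
image intensities or MRI physics, spatial clustering of metastases,
cystic/necrotic volume underestimation, and any correlation between
lesion size and clinical decision beyond what the triage rules induce.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis*, not the performance of any real detector on real
patients.

## Problem sizes and numerical choices

Generator calibration checks run at 500–1000 patients, where binomial
error on a 92% sensitivity is ≈ 0.4 points (tolerance ±2) and Poisson
error on 1.43 FP/patient is ≈ 0.05 (tolerance ±0.3). The full-pipeline
demonstration uses the study's cohort size of 112. Matching and
labeling oracles (brute-force flood fill, exhaustive assignment
enumeration) run on 12³ grids and ≤ 4-lesion graphs, where exhaustive
verification is feasible. Root-finding uses scipy (`brentq` on bracketed
monotone functions; multi-start `root` for the count-law moments with
residual tolerance 1e−6); quadrature uses 96 Gauss–Hermite nodes.
Percentages are rounded to one decimal for display only; reports retain
full precision.

## Known limitations

* Pooled sensitivity/PPV weight every lesion equally; per-patient
  stratification (e.g. by lesion count) is not implemented.
* The ICC confidence interval assumes the ANOVA normality conditions,
  which heavy-tailed volume totals violate; the coefficient itself is
  reported regardless, as is conventional.
* The any-overlap matching mode can report more true-positive pairs than
  predictions; its PPV convention (non-FP predictions) is documented but
  not the only possible one.
* Mask rendering is geometric, not anatomical; it exists to exercise the
  voxel-overlap code path, not to look like MRI.
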