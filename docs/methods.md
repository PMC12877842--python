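# Methods

## Study design encoded by the package

The pipeline implements a retrospective case-control comparison of
diagnosis histories between patients with recurrent pregnancy loss (RPL)
and live-birth controls, as it would be run against an OMOP-style EHR
extract at two medical centers, with three analysis layers (main
association, age-stratified, utilization sensitivity) plus subgroup
(severe RPL, ≥10-year EHR), cross-center concordance, and next-pregnancy
analyses.

### Phenotyping

A patient enters the RPL group through any of three criteria: (a) an
explicit RPL-diagnosis concept; (b) a pregnancy-loss record dated strictly
after a history-of-loss record; (c) at least two distinct loss events.
Distinct events come from a greedy left-to-right scan of the sorted loss
dates: a record opens a new event iff it falls ≥90 days (inclusive) after
the *start* of the previous accepted event. The 90-day rule separates
repeat coding of one loss from genuinely separate losses. The index date is
the minimum over qualifying dates — for criterion (c) the second event's
date, a configurable choice since "the date the criterion is met" is the
only defensible reading we found. The same event-anchored scan defines the
severe-RPL subgroup (≥3 events, index = third event), unifying the two-loss
and three-loss rules.

Controls require any uncomplicated live-birth concept and no
loss/preterm/molar/extrauterine record anywhere in their history; their
index is the earliest live birth. A history-of-loss code alone does not
exclude a control (it is not an outcome record).

The exclusion cascade runs in a fixed order so report arms are comparable:
age at index outside [15, 44] (365.25-day years, the standard epidemiologic
convention); neither female nor any incident-pregnancy evidence (loss and
birth concepts count as evidence, so this arm in practice removes only
patients qualifying through an RPL-diagnosis code alone); record span ≥100
years (a data-quality guard); and no ICD diagnosis inside the study window.

### Diagnosis window and aggregation

The window runs from the unbounded past through index + 365 days,
inclusive at both the index and the +365 endpoint ("one year after" is not
defined to the day anywhere authoritative; 365 is documented and
configurable). ICD-9/10 codes are matched against the crosswalk
dot-insensitively, mapped codes union into Phecode presence indicators
(any-occurrence, no minimum count), and unmapped codes are tallied in a
coverage report rather than silently dropped. Candidates are the Phecodes
carried by at least one cohort member.

### Association model

Crude associations are closed-form 2×2 odds ratios with Wald log-scale
intervals (Haldane-Anscombe 0.5 correction on zero cells, flagged
non-converged). Adjusted associations are additive logistic models with a
cubic B-spline smooth of age, categorical race and ethnicity (largest
category as reference; "Unknown" kept as an explicit level), optionally the
in-window visit count, and the binary diagnosis term. Defaults: df = 4 for
the smooth, unpenalized; `ModelSpec(penalized=True)` switches to a
penalized smooth (statsmodels GLMGam), with GCV-style penalty selection
available. df = 4 captures the post-35 acceleration in loss risk while
keeping the fit portable and fast; with the smooth replaced by a linear
term the fit reduces exactly to plain logistic regression, which the test
suite asserts against an independent maximum-likelihood fit at 1e-6.

CIs use z = 1.96. Separation and divergence (|log OR| > 15 or SE > 50) are
flagged non-converged with the direction preserved from the diverging sign;
no Firth-style penalty is applied by default so that extreme but real
contrasts (e.g. outcome-defining codes) remain interpretable. In sweep
contexts, rank-deficient base designs (rare category levels in small
strata) drop the linearly dependent dummy columns identified by pivoted QR;
direct calls raise and name the collinear columns.

Benjamini-Hochberg adjustment is applied within each analysis family over
all finite p-values (non-converged fits pass through as NaN). Significance
classification: positive if adjusted p < 0.05 and OR > 1, negative if
OR < 1, else null.

### Redaction

Any result where one of the four displayed cells (carriers/non-carriers per
group) is below 10 is flagged and exported only as directional bounds
(">1"/"<1", "<0.05"/">=0.05"), mirroring small-cell disclosure-control
practice for clinical data. Redaction changes display only, never the
classification; `format_for_export` masks the numeric fields in written
tables.

### Comparative analyses

Age strata split at 35 at index; sweeps are restricted to candidates
carried in both strata, and per-diagnosis coefficients are compared with
two-sided z-tests, BH-adjusted. Utilization sensitivity re-fits every
model with the raw in-window visit count added; per-diagnosis percent
change is `100·(OR_with − OR_without)/OR_without` (negative = attenuation
toward the null — the formula is stated here because prose descriptions of
"percent difference" are ambiguous), and the summary median is taken over
the union of significant diagnoses from the two fits, excluding
non-converged pairs. Cross-center concordance classes every shared
candidate (validated positive/negative, discordant, single-center-only,
neither — a partition, asserted in tests) and computes Spearman over the
both-significant set; a ≥10-patients-in-either-group-at-both-centers filter
marks plot-eligible rows. Spearman on ORs equals Spearman on log ORs by
rank invariance.

### Embedding and next pregnancy

The UMAP layer embeds binary non-pregnancy diagnosis profiles (the module
refuses matrices still containing "pregnancy complications" columns, since
those indicate rather than precede the outcome) with common defaults
(n_neighbors = 15, min_dist = 0.1, Euclidean, random initialization for
robustness to degenerate inputs), all recorded in output metadata, and
compares each coordinate dimension between groups with two-sided Wilcoxon
rank-sum tests. The next-pregnancy analysis takes each case's earliest
birth-or-loss ≥30 days after index (same-day ties → loss, flagged
ambiguous), counts a diagnosis as present only strictly before the outcome
date (avoiding conditioning on outcome-day coding), and reuses the adjusted
model, BH, and redaction machinery verbatim.

## Synthetic data: what it emulates and what it does not

The generator plants marginal structure rather than simulating pregnancy
biology: case status first, then records consistent with it. It emulates
the features the pipeline's correctness depends on — two centers whose
case/control visit gap differs (near-equal vs ~2.2×, negative-binomial
counts with dispersion 1.2 since real visit counts are overdispersed), a
case age distribution tilted above the control distribution by a
configurable mean shift (default +3 years) with a quadratic post-35
acceleration, Table-1-like race/ethnicity mixes, per-diagnosis baseline
prevalences with planted conditional odds ratios spanning 0.14–9.5,
optional log-linear visit-count links to diagnosis presence, duplicate loss
records inside 90 days, history-of-loss qualifiers, post-index pregnancy
outcomes, and exclusion-triggering records. It does **not** model
gestational age, pregnancy episodes, code frequency realism, within-patient
diagnosis correlation, or care-seeking dynamics — so passing tests
demonstrate that the *pipeline* recovers planted parameters and controls
error rates under the stated sampling model, not that any clinical claim
generalizes.

The planted panel's effect sizes deliberately bracket the ranges seen in
real menstrual/infertility/pregnancy-complication associations so that
sweeps produce a realistic mix of strong positives, strong negatives,
nulls, and small-cell redactions.

## Numerical and scale choices

- All randomness flows from a single root seed through
  `numpy.random.SeedSequence` spawns (children kept below 2³¹).
- IRLS logistic fits (statsmodels GLM, up to 100 iterations); Wald
  inference throughout; no profile likelihood.
- The demo and acceptance runs use two centers of 1,200 RPL + 3,600
  controls over the ~33-diagnosis default panel — large enough that planted
  ORs are recovered with tight intervals and small enough for quick
  iteration; calibration experiments use 200 replicates (OR recovery at
  n = 10,000; null FDP at n = 2,000 with prevalence ≥ 0.05, a floor chosen
  so Wald p-values are well calibrated) and 300–400 replicates for z-test
  calibration.
- UMAP runs on at most `embed_max_patients` (default 2,000) patients,
  subsampled deterministically, since embedding dominates runtime beyond
  that without changing the rank-sum conclusions.

## Known limitations

- Wald intervals and p-values are first-order asymptotics; below ~30
  carriers per cell they become anti-conservative (hence the redaction
  threshold and the prevalence floor in calibration experiments).
- The next-pregnancy analysis finds births from the same flat tables
  (no external delivery-warehouse linkage) and ignores terminations and
  other outcomes.
- The penalized-smooth path estimates the diagnosis coefficient's SE
  conditional on the selected penalty.
- Concordance requires identical Phecode vocabularies across centers; no
  cross-vocabulary reconciliation is attempted.
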