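# Methods

## Model of the data

A cohort is a patients × antigens matrix of LIPS titers in light units
(LU), with group labels (SLE vs healthy control), demographics, binary
clinical-manifestation flags for patients (CNS, musculoskeletal,
mucocutaneous, nephritis, serositis, hematological, SACQ, quiescent) and
anti-dsDNA status. Titers are strictly positive luminometer counts and
every subject has a value for every panel antigen.

### Cutoffs and Z-scores

The seropositivity cutoff for an antigen is the healthy-control
`mean + 3·SD`, with the sample SD (denominator n−1) because control groups
are small (15–18 subjects). "Seropositive" means strictly above the
cutoff; a titer exactly at the cutoff is negative. The Z-score is
`(titer − cutoff) / control SD`, so the cutoff maps to 0 and the control
mean to −3; no clipping is applied in the data structure (the heatmap
clips negatives to 0 for display only, because the color scale encodes SDs
*above* the cutoff).

A second cutoff policy serves the diagnostic tables: an exhaustive scan of
all midpoints between adjacent distinct pooled titers (plus ±∞) maximizing
Youden's J = sensitivity + specificity − 100. The two policies are kept as
separate, explicitly named outputs because nothing guarantees they
coincide; ties in J are broken toward higher specificity, then toward the
higher cutoff, reflecting the high-specificity emphasis of serologic
diagnosis. Display percentages are rounded half away from zero to integer
percent; unrounded values are retained.

### Relative-ratio clustering

Seronegativity is screened first: a patient with no seropositive call on
any of the six core antigens is labeled SERONEGATIVE and never
ratio-assigned (such patients are reported as a separate remainder, not as
cluster members). Otherwise `RR = Σ(Sm-D3, RNP-A, RNP-70k) / Σ(Ro52, Ro60,
La)` on **raw titer sums** — Z-scores exist only for the heatmap — with
`RR ≥ 1 → Sm/RNP` and `RR < 1 → Ro/La`. A zero Ro/La denominator (possible
only for synthetic input; real LU are positive) is treated as RR = +∞,
hence Sm/RNP, consistent with the ≥ rule. A patient is "pure" when all of
its core seropositive calls fall inside a single trio.

### Association tests

* Fisher's exact test, two-sided by the minimum-likelihood convention
  (sum of hypergeometric point masses ≤ the observed one, with relative
  tie tolerance 1e−7). The statistic is the sample odds ratio; a table
  with an empty margin carries no information and p is defined as 1 with a
  warning. scipy's `fisher_exact` implements exactly this convention and
  stands behind the module function; the test suite checks it against an
  independent exhaustive enumeration.
* Mann–Whitney U with midrank ties: exact by enumeration of all label
  assignments for combined n ≤ 20, otherwise the tie- and
  continuity-corrected normal approximation.
* Geometric-mean-titer comparisons use a pooled two-sample t-test on log10
  titers; GMT = 10^(mean log10 titer).
* Spearman correlation with midranks; exact permutation p for n ≤ 10,
  t-approximation beyond.
* The cluster screen emits raw p-values as the headline output (matching
  the source analysis, which applied no multiplicity correction) and
  Benjamini–Hochberg adjusted values as a clearly labeled extra column.

### Reconstructing printed tables

The reference cohorts are available only as printed percentages with group
sizes. `counts_from_percent` inverts the rounding (half away from zero)
and verifies that the reconstructed integer re-rounds to the printed
percent; when no integer does, reconstruction is refused with the closest
candidates listed rather than guessed. The four headline 2×2 tables
(serositis × cluster; anti-IFN-α × SACQ; anti-Sm × anti-IFN-ω; anti-IFN-α
× anti-IFN-ω) reconstruct exactly and reproduce the published p-values
(0.0022, 0.024, 0.0079, 0.0041) to two significant figures.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults calibrated to the printed summaries of the 129-patient
validation cohort:

* **Control titers** are log-normal per antigen. The choice is a modeling
  decision, not an observed fact: printed SLE means exceed control means
  10–200-fold and some printed 95% CIs dip below zero under a normal
  model, so a heavy-right-tailed, strictly positive family is the natural
  fit. Location/scale reproduce the printed control arithmetic means, with
  SD back-computed from the CI half-width read as `1.96·SD/√n` at the
  printed control n of 15.
* **Latent classes**: each SLE patient draws SM_RNP / RO_LA / SERONEGATIVE
  with probabilities 0.47/0.51/0.02. Given the class, each antigen is
  seropositive with a class-specific probability; own-trio reactivity is
  set near saturation (0.85–1.0) and the cross-trio rate then solves the
  printed marginal sensitivity under the class mix. Seropositive titers
  are the control log-normal shifted up by a class- and antigen-specific
  log10 offset: the own-trio shift is sized from the printed whole-cohort
  SLE mean titers and the cross-trio shift sits one decade lower (cross
  reactivity is real but weaker). The shift is parameterized per antigen ×
  class rather than per antigen alone, because a single shift cannot
  express the own-vs-cross asymmetry the clustering relies on.
* **Seronegative class**: its six core titers are control draws truncated
  below the generating mean+3SD cutoff, so the contract "seronegative
  patients are never core-seropositive" holds surely rather than merely
  with high probability (an untruncated log-normal tail would cross the
  cutoff for ~0.1–2% of draws).
* **Clinical flags** are Bernoulli with class-specific rates taken from
  the printed per-cluster percentages, conditionally independent given the
  class (only marginal per-cluster rates are printed). The seronegative
  class, for which nothing is printed (2/129 patients), uses the mean of
  the two cluster rates.
* **Demographics**: sex at the printed 13:1 female:male ratio; age groups
  (<20 / 20–40 / >40 at 0.18/0.59/0.23) implied by the printed 31 ± 12.1
  years at diagnosis under a normal model; anti-dsDNA at the printed
  58%. Ethnicity proportions are not printed; C/AA/A = 0.55/0.40/0.05 is a
  plausible US lupus-cohort mix and affects no headline quantity.
* **Mixture assay**: mixture LU = sum of the six core titers × log-normal
  noise with unit mean and CV 0.2. The additive model is motivated by the
  near-unity rank correlation of the real mixture against the plain sum;
  any interference term would be unobservable from the published data.
  CV 0.2 is a generic assay-noise level that keeps the rank correlation in
  the observed ≥0.95 range.
* **Reproducibility**: one root seed; every subject gets an independent
  child stream (`SeedSequence.spawn`), so cohorts are bit-reproducible and
  independent of generation order. The latent truth is written to a
  separate file, never into the analysis input.

## What the simulations do and do not show

Passing tests demonstrate that the pipeline is internally correct (exact
tests match enumeration oracles; invariants like "control mean ↦ Z = −3"
hold identically) and that, under the calibrated generative model, the RR
rule recovers the latent serotype classes with ≥95% accuracy and the
cohort-level summaries land near the published ones. They do not show that
real sera follow a log-normal, that clinical flags are conditionally
independent given serotype, or that the published sensitivities arose from
either cutoff policy specifically — the source analysis does not state
which policy produced its tables, so both are reported. Plate effects,
inter-assay drift, serum-dilution kinetics (including the extra dilutions
real Ro60 assays require) and longitudinal sampling are all out of scope.

## Numerical choices and problem sizes

* Exact-test tolerances: hypergeometric tie comparison at relative 1e−7;
  permutation/enumeration comparisons at ≥ threshold − 1e−9.
* Degenerate inputs: <2 controls or zero control variance refuse to
  calibrate; all-identical titers refuse ROC optimization; constant series
  refuse correlation.
* Monte-Carlo checks run at n = 1,000–10,000 with fixed seeds and 99%
  binomial (or 3–4 SD) acceptance bands — large enough for the bands to be
  meaningful, small enough that the full suite runs in well under five
  minutes on one CPU. The label-recovery check uses n = 1,000 SLE
  patients; control-calibration checks use 10,000 control draws.
* The exact-power oracle for the serositis screen enumerates the Fisher
  decision over the binomial serositis count conditional on cluster sizes;
  at the study conditions (13% vs 0%, clusters of ~61/66) the detection
  threshold is 5 events and power at α = 0.05 is ≈0.91.

## Known limitations

* The odds ratio reported with Fisher's test is the unconditional sample
  OR (∞ with a zero cell), not the conditional MLE.
* `counts_from_percent` returns the consistency-checked nearest integer;
  when several integers re-round to the same printed percent (e.g. a 36%
  flag in a cohort of 129: 46 or 47) it deterministically picks the one
  closest to pct·n/100 rather than propagating an interval.
* The ROC scan is O(distinct titers) per antigen, which is exact but not
  intended for mega-cohorts.
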