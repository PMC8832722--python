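# Methods

`mirsign` implements an end-to-end analysis pipeline for a circulating
microRNA (miRNA) diagnostic signature for esophageal squamous cell carcinoma
(ESCC): in-silico candidate discovery in tissue expression data, serum qPCR
quantification, logistic risk scoring, diagnostic performance evaluation,
miRNA-target network enrichment, and a screening cost-effectiveness model.
This note documents the statistical models, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Discovery phase

Each tissue dataset is a log2-scale miRNA x sample matrix with tumor/normal
labels, consumed already normalized. A miRNA is a candidate when it passes
three criteria:

1. **Differential expression** — log2 fold change (tumor mean − normal mean)
   > 0.5 and Benjamini–Hochberg adjusted p < 0.05. The per-miRNA test is a
   two-sided Welch t-test on log2 values; Welch rather than pooled-variance
   because tumor and normal groups routinely differ in spread. Rows with zero
   variance in both groups receive p = 1 by convention and are flagged.
2. **Discrimination** — tie-corrected Mann–Whitney AUC > 0.7, oriented
   tumor-high. The AUC is computed from mid-ranks, so it equals the
   probability that a random tumor sample exceeds a random normal sample with
   half credit for ties.
3. **Abundance** — mean expression over all samples above the median mean
   expression of the miRNAs passing criterion 1. The reference median is
   deliberately computed over the differentially expressed pool only, so the
   criterion selects the abundant half of the biologically interesting
   miRNAs rather than of the whole array.

The final panel is the set intersection of the per-dataset candidate lists,
ordered by the first dataset's ranking. Panel quality is evaluated two ways:
stratified 2-fold cross-validation of a multivariate logistic model, repeated
(default 100 times) with one pooled held-out AUC per repeat, and a frozen
train-on-one/apply-to-all transfer evaluation in which the linear predictor
fitted on one dataset is applied unchanged to the others.

**Logistic fitting.** All logistic fits are plain maximum likelihood. Two-fold
splits of a strongly discriminative panel are frequently linearly separable,
where the MLE diverges; on detected divergence (non-convergence or a
coefficient beyond 1e3) the fit is re-run with a tiny ridge penalty
(lambda = 1e-6, intercept unpenalized) and flagged in provenance. The penalty
is small enough to leave non-separable fits essentially unchanged while
keeping separable ones finite.

## qPCR quantification

Relative expression uses the standard 2^-ΔΔCt method. Per sample,
ΔCt(target) = Ct(target) − mean(Ct of the reference targets); multiple
references (e.g. miR-16 + miR-423) are combined as the arithmetic mean of
their Cts, which is the geometric mean on the linear abundance scale — the
conventional multi-reference rule. The calibrator is the mean ΔCt of the
control group (configurable to a named sample), so the geometric mean of
control fold changes is exactly 1 for every target. A spike-in scheme
(cel-miR-39) is selectable per cohort as an alternative reference set.

Undetermined wells default to imputation at the cycle ceiling (40), so a
systematically undetected target fails the detection filter rather than
silently inflating its expression; `drop_sample` and `drop_target` policies
are available. The detection filter excludes a target iff its mean Ct across
all samples exceeds the detection limit (default 35 cycles), matching the
practice of discarding serum targets that amplify too late to quantify.

## Risk signature

The risk score is logit(P) = b0 + Σ b_j x_j over the 8-miRNA panel, fitted
by maximum likelihood on a training cohort. Covariates enter on the log2
fold-change scale (−ΔΔCt) by default: fold changes are strictly positive and
right-skewed, and the log scale is both numerically stable and symmetric in
up/down regulation. Every model records its covariate scale and scoring
refuses mismatched input, because a formula fitted on one scale is
meaningless on the other.

The packaged registry ships one frozen published formula
(`beijing1-prospective`) with its printed coefficients and intercept
(−3.196), stored verbatim and never refitted. Several of its weights are
negative although the corresponding serum miRNAs are upregulated in cases;
the formula is reproduced as printed rather than "corrected", since the signs
of a jointly fitted logistic model are not individually interpretable.
The registry also accepts user-supplied frozen models as JSON with a
bit-exact export/import round trip.

The classification cutoff maximizes Youden's J = sensitivity + specificity −
1 over thresholds at the observed score values, with the rule score ≥
threshold ⇒ high risk; ties in J break toward the smaller threshold
(maximal sensitivity), and a score exactly at the cutoff is called high risk.
Cutoffs carry an explicit probability/logit scale tag.

## Performance evaluation

AUCs are tie-corrected Mann–Whitney estimates; the ROC curve is a full
threshold sweep (no interpolation), and the AUC equals the trapezoidal area
under the returned curve to numerical precision. Confidence intervals are
percentile intervals from stratified bootstrap replicates (default 2000;
cases and controls resampled independently), with no bias correction —
percentile is the variant that matches a plain stratified bootstrap
description. AUC comparisons use DeLong's method via structural components
(placement values), with the paired covariance subtracted when both score
sets come from the same samples and independent variances summed otherwise;
paired is appropriate for signature-vs-marker on the same patients, unpaired
for cross-cohort comparisons.

Subgroup evaluation restricts cases to a stage subset (e.g. stage I) while
keeping all controls. Group comparisons of risk scores against healthy
controls use one-sided Welch t-tests (alternative: group mean greater),
reported raw with no multiplicity adjustment but one p-value per group.
Marker comparisons fit univariate and joint multivariate logistic models
with Wald odds-ratio CIs; near-collinear or duplicated predictors trigger a
warning, and singular designs fall back to ridge point estimates without
Wald inference. Cross-cancer specificity applies a frozen formula, never a
refit, to each cohort and compares AUCs against the designated reference
cohort with unpaired DeLong tests.

## Target network and enrichment

Edges are validated miRNA→gene interactions filtered to panel miRNAs whose
target genes are strongly differentially expressed (|log2FC| > 2,
BH-adjusted p < 0.01 by default). Enrichment is a one-sided upper-tail
hypergeometric test per gene set (over-representation only), with the
universe defaulting to all genes in the DE table — the most defensible
choice when no background is stated — and sets intersected with the universe
and size-filtered (default 5–500) before testing; BH correction runs across
all tested sets.

## Cost-effectiveness model

A deterministic cohort decision tree over a finite horizon (default 3
years), not a Markov model: the clinical narrative is branch logic, not
recurring cycles. The screening arm tests the compliant fraction; positives
receive confirmatory endoscopy+biopsy treated as a gold standard; true
positives are treated at an early-shifted stage distribution. Test-negatives
(including false negatives) live under usual care, as does the entire
non-compliant fraction and the comparator arm: a background fraction
(default 10%) receives surveillance endoscopy, which detects asymptomatic
cancers at the early-shifted distribution, and the remaining cancers present
symptomatically at the late distribution with a diagnostic endoscopy at
presentation. Applying the same usual-care model to every untested subgroup
keeps the two arms exactly symmetric when the test does nothing.

Stages I–III incur a one-time treatment cost, accrue stage utility for two
years, and are then cured; a stage-specific fraction relapses at the end of
year 2 into the stage-IV pathway (palliative cost, stage-IV utility for one
year, then death), while non-relapsers accrue full healthy utility for the
remaining horizon (full-year accrual, no half-cycle correction). Stage IV is
palliative-only with death after one year. Costs and QALYs can be discounted
annually (default 0). The ICER is Δcost/ΔQALY, reported only in the genuine
tradeoff quadrants; otherwise a dominance status (`screening-dominates`,
`screening-dominated`, `equivalent`) is returned. One-way sensitivity
analysis re-runs the model at each bound of user-supplied parameter ranges.

The packaged default parameters (cohort 100 000, prevalence 1%, compliance
45%, background endoscopy 10%, CNY-labelled costs) are illustrative values
for a high-risk screening population, not published estimates; published
base-case inputs can be supplied as JSON to reproduce a published ICER.

## Synthetic-data generator

The generator plants known ground truth so every downstream claim is
checkable:

* **Tissue**: value = per-miRNA baseline + tumor effect + N(0, noise_sd) on
  the log2 scale. Defaults: 60 tumor / 60 normal, 300 miRNAs, noise 1.0, a
  shared 18-miRNA planted panel at log2FC 2.0 and high baseline. Each
  dataset additionally plants dataset-specific distractors: high-abundance
  decoys that pass every per-dataset criterion but vanish at the three-way
  overlap, and low-abundance differentially expressed miRNAs that populate
  the lower half of the DE abundance distribution (they must outnumber the
  high tier so the abundance median falls below the planted panel).
* **Serum**: Ct = target mean − case shift × stage fraction + N(0, ct_sd),
  default shift 1.0 cycle and ct_sd 1.5, chosen so the trained 8-miRNA
  signature lands in the high-0.8s/low-0.9s AUC range typical of serum
  panels. Stage fractions grade the effect (I 0.7 → IV 1.15); high-grade
  intraepithelial neoplasia carries 0.8 of the case shift while low-grade
  neoplasia and esophagitis carry none, reproducing the qualitative
  premalignant pattern. Censored targets draw from a band above the
  detection limit. Conventional serum markers are calibrated to a target AUC
  with the equal-variance binormal model (case mean √2·Φ⁻¹(AUC)), then
  exponentiated to resemble concentrations (rank statistics unchanged).
  Serum Ct levels use conventional qPCR ranges (references ~21 cycles,
  targets ~30) rather than study-derived distributions, which are not
  published.
* **Seeding**: one master seed; each stage derives a child seed by hashing
  (stage-name, master), giving reproducibility with stage independence.
  Fixture bundles are byte-identical per seed.

What the generator does **not** emulate: batch effects, platform/probe
models, amplification-efficiency differences, correlated miRNA co-regulation,
exosomal vs free compartments, or covariate shift between cohorts. Passing
tests therefore demonstrate correctness of the statistical machinery on data
satisfying the model assumptions, not robustness to the messiness of real
cohort data.

## Numerical choices and edge cases

* BH adjustment is the standard step-up procedure (monotone, clipped at 1).
  Note it is not idempotent as a map on p-values: re-adjusting adjusted
  values inflates them further (e.g. (0.25, 1.0) → (0.5, 1.0) → (1.0, 1.0)).
* Zero-variance expression rows: p = 1, flagged, never dropped silently.
* AUC below 0.5 raises an orientation warning rather than silent flipping.
* Degenerate Youden inputs (all scores equal) return J = 0 with a warning.
* Empty confusion-matrix margins report NaN rates with an explicit flag.
* Decision-tree branch weights are exact expectations (no microsimulation),
  so cohort conservation and linearity hold to machine precision.
* Problem sizes in the test suite (e.g. 60/60 tissue samples, 100 CV
  repeats, 400 coverage replicates at 1000 bootstrap draws) were chosen as
  the smallest designs at which the planted effects are estimated with
  comfortable Monte-Carlo margins.

## Command-line interface

`mirsign` exposes the phases as subcommands (`simulate`, `quantify`,
`train`, `score`, `cea`, `validate-config`, `all`). `all` executes the whole
synthetic study from a YAML config and writes a manifest with a SHA-256
checksum per artifact; identical config + seed reproduce identical checksums.
Exit codes: 0 success, 2 config validation failure, 1 runtime failure.

## Known limitations

* Published per-cohort AUCs depend on patient-level data that are not
  public; the package reproduces the methodology and its printed formula,
  not cohort-specific numbers.
* The covariate preprocessing behind the frozen published coefficients is
  not recoverable; the frozen model is tagged linear-foldchange and applied
  on whatever scale the caller's provenance declares.
* The retrospective-cohort coefficients are not packaged (unavailable);
  users can register their own frozen models from JSON.
* The decision model has no probabilistic sensitivity analysis and no
  lifetime horizon; the one-way analysis covers deterministic ranges only.
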