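# Methods

This note documents the models, rules and numerical choices behind
sigbench, and what the synthetic experiments do and do not establish.

## Signature models

All six engines consume a `SignatureDefinition` — gene list, weights or
centroids, grouped gene sets, reference genes, cutoff scheme, minimum
coverage — loaded from JSON. The set shipped with the package is
**synthetic**: structurally faithful to the research versions of the six
clinical signature families, but with generated gene symbols,
weights and centroids rather than the published coefficients
(reproducing commercial assay coefficients is a non-goal). Real
definitions in the same schema can be dropped in without code changes.

*Grade index (weighted sum).* Raw score s_i = Σ_g w_g x_gi over the
signature genes present. Within each dataset the score is affinely mapped
so that the mean of grade-1 samples is −1 and of grade-3 samples +1; calls
are GG1 (score < 0) / GG3 (≥ 0). Where histologic grade is missing it is
first imputed: a midpoint is calibrated between the mean raw scores of
observed grade-1 and grade-3 samples in the dataset, and missing-grade
samples become grade 1 or 3 by which side their raw score falls. This
midpoint rule is this package's own minimal design for expression-based
grade assignment — deterministic, calibrated per dataset, targeting the
low/high axis the grade index needs. Datasets with no observed grade-1 or
grade-3 samples fall back to a midpoint pooled over all kept datasets;
with no observed anchors anywhere the operation fails loudly rather than
guessing.

*70-gene (centroid correlation).* Pearson correlation between a sample's
expression and a good-prognosis centroid over the intersection of
available genes; Low risk above a threshold (default 0.4, stored in the
definition), High otherwise. Fewer than 3 overlapping genes is an error.

*Recurrence score (grouped composite).* Per sample: each gene is
normalised by subtracting the mean of the reference genes; each named
group (proliferation, HER2, ER, invasion, single genes) is averaged and
floored from below where a floor is configured; the unscaled score is the
weighted sum of group scores; an affine map stored in the definition
rescales to the 0–100 range, clamped at both ends. Cutoff schemes encode
the printed boundary semantics explicitly per threshold: the original
scheme places 18 and 31 inside Intermediate; the TAILORx printing leaves
10 and 26 unassigned and is resolved as Low ≤ 10 < Intermediate ≤ 25 <
High. A missing non-reference gene is an error by design — such datasets
must be excluded upstream by the coverage rule.

*Cell-cycle score (mean).* Mean expression of available signature genes.
Cutoffs are externally supplied (mirroring thresholds derived on an
external cohort) or, when the scheme is named `derive`, computed as
cohort tertiles: thresholds at the ⌈n/3⌉-th and ⌈2n/3⌉-th order
statistics, scores at a threshold falling in the lower bin.

*Intrinsic subtyping (nearest centroid).* Spearman rank correlation of a
sample against each of five subtype centroids over shared genes; the call
is the arg-max, with exact ties broken deterministically by a fixed
subtype order (Basal-like, Her2-enriched, Luminal A, Luminal B,
Normal-like — ties are measure-zero in practice). The five correlations
are retained for the risk-of-recurrence composite. All-constant sample
vectors are an error (the rank correlation is undefined).

*Risk of recurrence, proliferation-weighted.* score = Σ_k c_k ρ_k +
c_p · mean(proliferation genes), with coefficients from the definition
and the proliferation mean taken from the centered matrix; categorised by
the definition's three-level cutoffs.

Missing-gene policy everywhere: drop absent genes and score over the
remainder (weighted sums keep their remaining weights; correlations use
the intersection), recording coverage per call. This tolerates the
90–100% per-platform coverage regime the compendium structure implies
without modifying any engine.

## Preprocessing

Probes are collapsed to genes by averaging (missing probe values omitted
from the mean); unmapped probes are dropped. Hard coverage rules: a
dataset fails the 70-gene signature when strictly less than 75% of its
genes are present, and fails the recurrence score when *any*
non-reference gene is absent; other signatures report coverage without a
hard rule. Failing datasets are excluded wholesale and their samples
tallied in the CONSORT cascade.

Centroid-engine scoring (70-gene, subtyping, risk-of-recurrence) uses
ER-balanced median centering: per dataset, the predominant ER group is
subsampled without replacement down to the minority size; the per-gene
median of each balanced set is computed over 100 subsamples (configurable)
and the reference is the **mean** of those medians — the aggregation
across subsamples is a design choice here (mean is the lower-variance
combiner; median-of-medians differs negligibly at 100 subsamples).
Unknown-ER samples are centered but never contribute to the reference.
Datasets with only one ER group fall back to the plain per-gene median
with a logged warning. With exactly balanced groups the procedure
collapses to the plain median with zero Monte-Carlo variance. The
weighted-sum, mean and reference-normalised engines score uncentered
expression: the grade index and recurrence score carry their own internal
normalisations (grade anchoring; reference genes), and applying the
ER-balancing only to centroid engines keeps each engine's native scale.

## Cohort assembly

The CONSORT cascade keeps patients aged ≥ 70.0, then drops unknown ER,
then missing survival, then samples from coverage-excluded datasets —
counting each sample at the first rule it violates, and asserting
n_input − Σ excluded = n_output on every run. Endpoints: recurrence-free
survival where recorded, distant-metastasis-free survival as substitute,
harmonised and administratively censored at a 10-year horizon
(idempotent). Subgroups: ER+/LN+ and ER+/LN− (requiring known nodal
status, hence disjoint), ER+/LN−/HER2− (requiring explicitly negative
HER2), and a younger postmenopausal comparator applying an inclusive
55 ≤ age ≤ 65 window to the pre-age-filter population under the same
ER/survival/coverage rules. Tumour size is dichotomised at 2 cm for
modelling.

## Survival statistics

Cox models maximise the partial likelihood with the Efron ties
approximation (via lifelines, Newton precision tightened to 1e−9 so
coefficients agree with brute-force maximisation to < 1e−4). Adjustment
sets: ER status, nodal status, grade, size (< 2 vs ≥ 2 cm) and hormonal
therapy for the full cohort; size, grade and hormonal therapy in
subgroups. Chemotherapy is never adjusted for (too few treated patients
in the target population). Unknown levels of adjustment covariates are
retained as explicit categories rather than dropping samples; empty and
duplicate design columns are removed to keep the design full-rank. The
signature never appears in an adjustment set.

Univariable prognostic capacity is summarised by LR = 2(ℓ̂ − ℓ̂₀) with a
χ² test on (levels − 1) degrees of freedom, and by the c-index of the
fitted linear predictor (0.5 for a constant score by convention). Added
capacity beyond the clinico-pathological model is ΔLR = LR_full −
LR_reduced, with both nested models fitted on identical samples (a row
mismatch is an error, never a silent drop). Stratification differences
between age groups use the χ² test of independence without continuity
correction; expected cells below 1 set a warning flag on the result.
Median follow-up uses the reverse Kaplan–Meier estimator (plain median
available as an option). All p-values are two-sided at α = 0.05 with no
multiplicity correction; these conventions are recorded in the report's
provenance block.

Sparse subtype levels can separate completely in small subgroups; the
benchmark pipeline retries such fits with a light L2 ridge (0.01) and
logs that the fit was stabilised. Direct `fit_cox` calls raise a
diagnostic error instead.

## Synthetic compendium

The generator emulates the structure the analysis assumes, not any real
platform's chemistry. Per sample, a latent intrinsic subtype (proportions
0.55/0.25/0.08/0.07/0.05 across Luminal A/Luminal B/Her2-enriched/
Basal-like/Normal-like) drives the subtyping genes (centroid pattern ×
separation, default 3 noise-SD) and ER status (luminal fidelity 0.95, the
non-luminal rate solved so the ER+ marginal hits 0.873); a latent
three-level risk group — dependent on subtype, so subtype calls are also
prognostic — shifts the grade-index, 70-gene, recurrence-score-
proliferation and cell-cycle genes by ±1.5 SD per step and sets the
log hazard (0 / 0.35 / 0.7 by default, i.e. HR 2 for High vs Low).
Histologic grade is drawn conditional on risk to match a ≈ 11/44/37%
grade distribution. Expression sits on per-gene baselines ~N(7, 1)
(recurrence-score and reference genes share one baseline so the stored
0–100 map stays meaningful), with N(0, 1) sample noise, 1–3 probes per
gene with 0.25-SD probe noise, and a handful of unmapped probes.

Platform dropout is class-specific: 9% of 70-gene genes, 4% of
cell-cycle genes, 2% of background genes, none for the protected classes
— reproducing the ~91/96/100% coverage profile of a mixed-platform
compendium. Coverage failures are *planted*: by default the first dataset
receives 30% 70-gene dropout and the second loses one recurrence-score
non-reference gene, so the exclusion rules have known right answers.

Clinical marginals follow the target cohort: missingness 22.5% (PR),
26.9% (HER2), 7.3% (nodal), 7.5% (grade), 6.4% (size), 4.4% (ER); 24% of
samples lack survival altogether; treatment probabilities 3.9/55.3/1.8/
30.4/8.6% (chemo/hormonal/both/untreated/unknown); 54.6% node-negative
among known. Ages are a mixture: a 15% older stratum over integer years
70–96 with a short ramp to a mode at 75 and geometric decay (rate 0.82)
above it, the remainder uniform over 35–69 (fractional year offsets added
uniformly), giving both the ≥ 70 analysis population and the 55–65
comparator. Survival is exponential under proportional hazards
(baseline 0.04 events/year at Low risk) with independent uniform
administrative censoring on [0, 12.4] years — chosen so the reverse-KM
median follow-up lands near 6.2 years — and 30% of surviving records
carry the distant-metastasis endpoint label.

Randomness: every stream derives from `SeedSequence(master_seed,
spawn_key=k)` with fixed k per component (global gene parameters; one key
per dataset; clinical; survival), so generation is a pure function of
(config, seed) and adding a dataset never perturbs existing ones.

What the generator does **not** emulate: real probe chemistry, batch and
normalisation history, gene–gene correlation beyond the planted modules,
non-proportional hazards, or informative censoring. Passing tests
therefore demonstrate the *machinery* — rule fidelity, estimator
correctness, calibration, determinism — not clinical performance of any
signature on real tumours.

## Problem sizes and numerics

The default configuration (39 datasets, ~9.4k samples, 1500 genes) runs
the full benchmark in about a minute; the analysis drivers use it. The
test suite and the reproduction script use a reduced compendium (6
datasets, 120–260 samples each, 400 genes, older fraction raised to 0.55)
that preserves every structural feature including the planted coverage
failures, plus experiment sizes of n = 2000 (hazard-ratio recovery, 200
replicates for CI coverage), n = 300 × 500 replicates (ΔLR null
calibration), n = 1000 × 60 (ΔLR power) and n = 500 (subtype recovery) —
sizes at which the Monte-Carlo error is small relative to each check's
tolerance while the whole suite stays fast on one CPU.

Numerical conventions: grade-anchor scaling requires distinct grade-1/3
means (else a degenerate-scaling error); tertile derivation requires
distinct thresholds; correlations need ≥ 3 shared genes; recurrence
scores clamp to [0, 100]; nearest-centroid ties break by fixed subtype
order; CONSORT arithmetic is asserted, not assumed. Reports embed the
package version, master seed and a config hash; re-running from the same
seed reproduces every output byte-for-byte.

## Known limitations

The synthetic signature definitions share no coefficients with the
commercial assays, so absolute score distributions (e.g. the fraction of
recurrence scores below 18) reflect the generator's planted effect sizes,
not any clinical population. Frailty/comorbidity adjustment, treatment-
predictive analyses, competing-risks modelling and proportional-hazards
diagnostics are out of scope. The 55–65 comparator shares the generator's
effect sizes with the older stratum, so age-dependent biology — the
scientific question such a comparison probes on real data — is absent by
construction unless configured.
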