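# sigbench

Benchmarking the prognostic value of breast-cancer gene-expression
signatures in older patients.

Multigene signatures (a genomic grade index, the 70-gene good-prognosis
profile, the 21-gene recurrence score, a cell-cycle score, 50-gene
intrinsic subtyping and its risk-of-recurrence/proliferation composite)
guide treatment decisions in early breast cancer, but they were developed
and validated almost entirely in patients younger than 70. This package
implements the full analysis needed to ask whether such signatures carry
independent prognostic information in an older (≥ 70 years) population
assembled from many public expression datasets: research versions of the
six signature scoring algorithms, the preprocessing and cohort-assembly
rules such a multi-study compendium requires, and the survival statistics
used to benchmark signatures against routine clinico-pathological markers.

Because the real compendium is a large external download, the package
ships a first-class synthetic-data generator that reproduces the
compendium's statistical structure — dozens of datasets on heterogeneous
platforms with platform-specific gene dropout, strong ER+ skew, ~50%
node-negative disease, missingness in routine pathology, and
right-censored recurrence outcomes — with complete per-sample ground truth
(latent subtype, risk group, and hazard), so every stage is testable
end to end.

## What it computes

**Scoring engines** (`sigbench.signatures`), each tolerant of missing
platform genes and reporting per-call coverage:

- *Grade index*: weighted sum over signature genes, affinely rescaled per
  dataset so observed grade-1 tumours average −1 and grade-3 tumours +1;
  dichotomised GG1/GG3 at 0. Missing histologic grade is imputed from the
  raw score via a calibrated grade-1/grade-3 midpoint.
- *70-gene*: Pearson correlation r to a good-prognosis centroid; low risk
  when r > 0.4.
- *Recurrence score*: reference-gene-normalised grouped composite with
  group floors, rescaled to 0–100 and clamped; categorised under the
  original (Low < 18 ≤ Intermediate ≤ 31 < High) or TAILORx
  (Low ≤ 10 < Intermediate ≤ 25 < High) scheme.
- *Cell-cycle score*: mean expression of cell-cycle genes with external or
  cohort-tertile cutoffs.
- *Intrinsic subtyping*: Spearman nearest-centroid classification into
  five subtypes on ER-balanced median-centered expression (the centering
  reference is the mean of per-gene medians over 100 Monte-Carlo
  subsamples that equalise ER+/ER− proportions).
- *Risk of recurrence (proliferation)*: Σ_k c_k ρ_k + c_p · mean
  proliferation-gene expression, over the five subtype correlations ρ_k.

**Cohort assembly** (`sigbench.cohort`): an ordered CONSORT cascade
(age ≥ 70 → known ER → available survival → signature gene coverage) whose
arithmetic is asserted on every run; harmonisation of recurrence-free and
distant-metastasis-free endpoints into one RFS metric censored at 10
years; ER/LN/HER2 subgroups plus a 55–65-year-old comparator window.

**Survival statistics** (`sigbench.survival`), built on lifelines:
Kaplan–Meier curves with k-group log-rank tests; multivariable Cox
proportional-hazards models (Efron ties) with hazard ratios HR = e^β and
95% CIs against stated reference levels, keeping unknown covariate levels
as explicit categories; univariable likelihood-ratio statistics
LR = 2(ℓ̂ − ℓ̂₀) and the concordance index as single-number measures of
prognostic capacity; the added value of a signature beyond the
clinico-pathological adjustment as ΔLR = LR_full − LR_reduced, tested
against χ²(levels − 1); χ² comparison of risk stratification between age
groups; and reverse Kaplan–Meier median follow-up.

## Worked example

```python
from sigbench import RunConfig, run_benchmark
from sigbench.simulate import small_config

report = run_benchmark(
    RunConfig(simulate=small_config(), seed=1, outdir="results/demo")
)
print(report.consort.to_text())
print(f"median follow-up: {report.median_followup_years:.2f} y")
print(report.delta_lr_rows.query("subgroup == 'All'")
      [["signature_id", "delta", "df", "p"]].round(3).to_string(index=False))
```

prints

```
Assessed for eligibility: n = 1168
  excluded — age under 70: n = 501
  excluded — missing ER status: n = 28
  excluded — missing survival information: n = 151
  excluded — insufficient signature gene coverage: n = 161
Analysis cohort: n = 327
median follow-up: 6.41 y
signature_id  delta  df     p
         ggi  5.892   1 0.015
         g70  7.889   1 0.005
          rs  4.399   2 0.111
         ccs  9.894   2 0.007
       pam50  1.396   4 0.845
        rorp  1.172   2 0.557
```

The CONSORT block shows the exclusion cascade on the simulated compendium
(two of six datasets are planted coverage failures and their samples fall
out at the coverage step). The ΔLR table quantifies how much
log-likelihood each signature adds to a Cox model already containing the
clinico-pathological covariates: here the grade-index, 70-gene and
cell-cycle signatures add significant information at this (deliberately
small) sample size, while the subtype-based calls do not.

The `analysis/` directory chains the same steps at full compendium scale
(39 datasets, ~9.5k samples) as numbered drivers — simulate, coverage +
CONSORT, signature distribution, survival benchmark, age-stratification
contrast, validation experiments — each writing small summary tables under
`results/`.

A `sigbench` command-line tool exposes the stages
(`sigbench simulate | score | benchmark | consort`); see `sigbench --help`.

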