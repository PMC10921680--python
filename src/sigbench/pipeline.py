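"""End-to-end orchestration: bundle I/O, scoring, assembly, benchmarking.

A *compendium directory* is the on-disk exchange format (plain text only):

    compendium/
      clinical.csv              one row per sample, documented header
      truth.tsv                 ground-truth table (synthetic data only)
      signatures.json           signature definition set
      config.json               generator config, master seed, content hash
      <dataset_id>/expression.tsv   probes × samples, first column probe_id
      <dataset_id>/annotation.tsv   probe_id → gene symbol

`run_benchmark` executes preprocessing → coverage exclusion → CONSORT
cohort assembly → per-dataset signature scoring (ER-balanced centering for
centroid engines) → survival benchmarking per subgroup, and writes the
report tables (risk calls, Cox summaries, univariable LR/c-index, ΔLR,
log-rank, stratification χ², KM curves, CONSORT tally) with a provenance
block so that a re-run from the same seed reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CLINICAL_COLUMNS,
    CohortFilterReport,
    apply_consort_filters,
    harmonize_endpoints,
    stratify_subgroups,
    validate_clinical,
)
from .definitions import (
    RS_CUTOFF_SCHEMES,
    SignatureDefinition,
    load_signature_set,
    save_signature_set,
)
from .preprocessing import (
    BalancingConfig,
    CoverageReport,
    GeneMatrix,
    ProbeMatrix,
    collapse_probes,
    compute_coverage,
    center_by_reference,
    er_balanced_reference,
    exclude_datasets,
)
from .signatures import (
    GradeVector,
    calls_to_frame,
    classify_pam50,
    impute_tumour_grade,
    raw_ggi_scores,
    score_ccs,
    score_ggi,
    score_rorp,
    score_70gene,
    score_recurrence_score,
)
from .simulate import Compendium, SimulationConfig, generate_compendium
from .survival import (
    ALL_PATIENTS_ADJUSTMENT,
    SUBGROUP_ADJUSTMENT,
    CoxConvergenceError,
    compare_stratification,
    delta_lr,
    encode_covariates,
    encode_signature,
    fit_cox,
    km_logrank,
    median_followup,
    univariable_summary,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Bundle I/O


def write_compendium(comp: Compendium, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp.clinical.to_csv(outdir / "clinical.csv", index=False, float_format=FLOAT_FMT)
    comp.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    save_signature_set(comp.definitions, outdir / "signatures.json")
    cfg_dict = dataclasses.asdict(comp.config)
    payload = {
        "config": cfg_dict,
        "seed": comp.seed,
        "config_hash": config_hash(cfg_dict, comp.seed),
    }
    (outdir / "config.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    for ds, pm in comp.probe_matrices.items():
        d = outdir / ds
        d.mkdir(exist_ok=True)
        pm.values.to_csv(d / "expression.tsv", sep="\t", float_format=FLOAT_FMT)
        ann = pm.annotation.rename("gene_symbol").rename_axis("probe_id")
        ann.to_csv(d / "annotation.tsv", sep="\t")
    return outdir


def config_hash(cfg_dict: dict, seed: int) -> str:
    blob = json.dumps({"config": cfg_dict, "seed": seed}, sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_dataset_bundle(ds_dir: str | Path, clinical: pd.DataFrame) -> ProbeMatrix:
    """Load and validate one dataset's expression + annotation files.

    Enforces sample agreement with the clinical table: every expression
    column must be a known sample of this dataset.
    """
    ds_dir = Path(ds_dir)
    ds = ds_dir.name
    expr_path = ds_dir / "expression.tsv"
    ann_path = ds_dir / "annotation.tsv"
    for p in (expr_path, ann_path):
        if not p.exists():
            raise FileNotFoundError(f"{ds}: missing {p.name}")
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    ann = pd.read_csv(ann_path, sep="\t", index_col=0)["gene_symbol"]
    known = set(clinical.loc[clinical["dataset_id"] == ds, "sample_id"])
    extra = [s for s in values.columns if s not in known]
    if extra:
        raise ValueError(
            f"{ds}: expression samples absent from clinical table: {extra[:5]}"
        )
    return ProbeMatrix(dataset_id=ds, values=values, annotation=ann)


def load_compendium_dir(path: str | Path) -> tuple[dict[str, ProbeMatrix], pd.DataFrame, list[SignatureDefinition]]:
    path = Path(path)
    clinical = pd.read_csv(path / "clinical.csv")
    validate_clinical(clinical)
    defs = load_signature_set(path / "signatures.json")
    pms = {}
    for ds_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        pms[ds_dir.name] = load_dataset_bundle(ds_dir, clinical)
    if not pms:
        raise FileNotFoundError(f"{path}: no dataset directories found")
    return pms, clinical, defs


# ---------------------------------------------------------------------------
# Scoring


@dataclass
class ScoringResult:
    calls: pd.DataFrame  # sample_id, dataset_id, signature_id, score, category, coverage
    coverage_reports: list[CoverageReport]
    kept_datasets: list[str]
    excluded_datasets: dict[str, list[str]]

    def calls_for(self, signature_id: str) -> pd.DataFrame:
        return self.calls[self.calls["signature_id"] == signature_id]

    def category_series(self, signature_id: str) -> pd.Series:
        sub = self.calls_for(signature_id)
        return sub.set_index("sample_id")["category"]


def score_compendium(
    probe_matrices: dict[str, ProbeMatrix],
    clinical: pd.DataFrame,
    defs: list[SignatureDefinition],
    rs_scheme: str = "original",
    balancing: BalancingConfig | None = None,
) -> ScoringResult:
    """Score every dataset with all six signatures.

    Datasets failing the hard coverage rules are excluded before scoring.
    Centroid engines (70-gene, intrinsic subtyping, risk-of-recurrence)
    score ER-balanced median-centered expression; the weighted-sum, mean
    and reference-normalised composites score the uncollapsed-scale gene
    matrix directly.  Grade imputation for the grade index falls back to a
    pooled-cohort midpoint in datasets without observed grade-1/3 samples.
    """
    balancing = balancing or BalancingConfig()
    by_id = {d.id: d for d in defs}
    scheme = RS_CUTOFF_SCHEMES[rs_scheme]
    clin = clinical.set_index("sample_id")

    gms: dict[str, GeneMatrix] = {}
    reports = []
    for ds in sorted(probe_matrices):
        gm = collapse_probes(probe_matrices[ds])
        gm.er_status = clin.loc[gm.samples, "er"].where(
            clin.loc[gm.samples, "er"].isin(["pos", "neg"]), "unknown"
        )
        gm.__post_init__()
        gms[ds] = gm
        reports.append(compute_coverage(gm, defs))
    kept, excluded = exclude_datasets(reports)
    for ds, reasons in excluded.items():
        log.info("excluding dataset %s: %s", ds, "; ".join(reasons))
    if not kept:
        raise ValueError(
            "all datasets excluded by the coverage rules: "
            + "; ".join(f"{ds} ({'; '.join(r)})" for ds, r in excluded.items())
        )

    # Pooled grade-imputation midpoint over kept datasets.
    pooled_raw, pooled_grade = [], []
    for ds in kept:
        raw = raw_ggi_scores(gms[ds], by_id["ggi"])
        grades = pd.to_numeric(clin.loc[raw.index, "grade"], errors="coerce")
        pooled_raw.append(raw)
        pooled_grade.append(grades)
    pooled_raw = pd.concat(pooled_raw)
    pooled_grade = pd.concat(pooled_grade)
    m1 = pooled_raw[pooled_grade == 1].mean()
    m3 = pooled_raw[pooled_grade == 3].mean()
    pooled_midpoint = (m1 + m3) / 2.0 if np.isfinite(m1) and np.isfinite(m3) else None

    frames = []
    for idx, ds in enumerate(sorted(kept)):
        gm = gms[ds]
        ref = er_balanced_reference(
            gm, BalancingConfig(balancing.n_subsamples, balancing.seed + idx)
        )
        centered = center_by_reference(gm, ref)

        grades = GradeVector.observed(pd.to_numeric(clin.loc[gm.samples, "grade"], errors="coerce"))
        grades = impute_tumour_grade(gm, grades, by_id["ggi"], pooled_midpoint)
        calls = {
            "ggi": score_ggi(gm, by_id["ggi"], grades),
            "g70": score_70gene(centered, by_id["g70"]),
            "rs": score_recurrence_score(gm, by_id["rs"], scheme),
            "ccs": score_ccs(gm, by_id["ccs"]),
        }
        pam = classify_pam50(centered, by_id["pam50"])
        calls["pam50"] = pam
        calls["rorp"] = score_rorp(pam, centered, by_id["rorp"])
        for sig_calls in calls.values():
            frames.append(calls_to_frame(sig_calls, dataset_id=ds))
    calls_df = pd.concat(frames, ignore_index=True)
    return ScoringResult(calls_df, reports, kept, excluded)


# ---------------------------------------------------------------------------
# Benchmark


@dataclass
class RunConfig:
    """One benchmark run: input, signature set, scheme, seed, output."""

    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    signatures_path: str | None = None
    rs_scheme: str = "original"
    subgroups: tuple[str, ...] = ("All", "ER+/LN+", "ER+/LN-", "ER+/LN-/HER2-", "55-65 ER+/LN-")
    seed: int = 0
    outdir: str = "results/benchmark"

    def __post_init__(self):
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate / input_dir must be set")


@dataclass
class BenchmarkReport:
    consort: CohortFilterReport
    coverage: pd.DataFrame
    calls: pd.DataFrame
    cox_rows: pd.DataFrame
    univariable: pd.DataFrame
    delta_lr_rows: pd.DataFrame
    logrank: pd.DataFrame
    stratification: pd.DataFrame
    km_curves: pd.DataFrame
    median_followup_years: float
    provenance: dict


def _benchmark_subgroup(
    name: str,
    ids: pd.Index,
    cohortish: pd.DataFrame,
    outcomes: pd.DataFrame,
    scoring: ScoringResult,
    defs: list[SignatureDefinition],
) -> tuple[list[dict], list[dict], list[dict], list[dict], list[pd.DataFrame]]:
    adj_set = ALL_PATIENTS_ADJUSTMENT if name == "All" else SUBGROUP_ADJUSTMENT
    sub_clin = cohortish[cohortish["sample_id"].isin(ids)]
    sub_out = outcomes.loc[outcomes.index.intersection(sub_clin["sample_id"])]
    sub_clin = sub_clin[sub_clin["sample_id"].isin(sub_out.index)].set_index("sample_id")
    sub_out = sub_out.loc[sub_clin.index]
    adjustment = encode_covariates(sub_clin, adj_set)

    cox_rows, uni_rows, dlr_rows, lr_rows, km_frames = [], [], [], [], []
    for d in defs:
        cats = scoring.category_series(d.id).reindex(sub_out.index)
        if cats.isna().any():
            missing = cats.index[cats.isna()]
            raise ValueError(f"{d.id}: no risk call for samples {list(missing[:5])}")
        ref = d.reference_label
        try:
            km = km_logrank(cats, sub_out)
            lr_rows.append(
                {
                    "signature_id": d.id, "subgroup": name,
                    "statistic": km.statistic, "df": km.df, "p": km.p,
                }
            )
            for cat, curve in km.curves.items():
                c = curve.copy()
                c.insert(0, "category", cat)
                c.insert(0, "subgroup", name)
                c.insert(0, "signature_id", d.id)
                km_frames.append(c)
        except ValueError as e:
            log.warning("%s/%s: log-rank skipped (%s)", d.id, name, e)

        sig = encode_signature(cats, ref, d.id)
        design = pd.concat([adjustment, sig], axis=1)
        # Sparse subtype levels occasionally separate completely in small
        # subgroups; a light ridge stabilises those fits (and is flagged).
        try:
            fit = fit_cox(sub_out, design)
        except CoxConvergenceError as e:
            log.warning("%s/%s: ridge-stabilised multivariable fit (%s)", d.id, name, e)
            fit = fit_cox(sub_out, design, penalizer=0.01)
        counts = cats.value_counts()
        for cat in [ref] + [c for c in sorted(counts.index) if c != ref]:
            term = f"{d.id}[{cat}]"
            row = {
                "signature_id": d.id, "subgroup": name, "category": cat,
                "n": int(counts.get(cat, 0)),
                "pct": round(100.0 * counts.get(cat, 0) / len(cats), 1),
            }
            if cat == ref or term not in fit.coefs.index:
                row.update({"HR": 1.0 if cat == ref else np.nan,
                            "HR_lower95": np.nan, "HR_upper95": np.nan, "p": np.nan})
            else:
                row.update(
                    {
                        "HR": fit.hr[term], "HR_lower95": fit.hr_lower[term],
                        "HR_upper95": fit.hr_upper[term], "p": fit.p[term],
                    }
                )
            cox_rows.append(row)

        try:
            uni = univariable_summary(sub_out, cats, ref, d.id)
        except CoxConvergenceError as e:
            log.warning("%s/%s: ridge-stabilised univariable fit (%s)", d.id, name, e)
            uni = univariable_summary(sub_out, cats, ref, d.id, penalizer=0.01)
        uni["subgroup"] = name
        uni_rows.append(uni)

        try:
            dlr = delta_lr(sub_out, adjustment, sig, d.id, name)
        except CoxConvergenceError as e:
            log.warning("%s/%s: ridge-stabilised nested fits (%s)", d.id, name, e)
            dlr = delta_lr(sub_out, adjustment, sig, d.id, name, penalizer=0.01)
        dlr_rows.append(dataclasses.asdict(dlr))
    return cox_rows, uni_rows, dlr_rows, lr_rows, km_frames


def run_benchmark(cfg: RunConfig) -> BenchmarkReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        comp = generate_compendium(cfg.simulate, cfg.seed)
        probe_matrices, clinical, defs = comp.probe_matrices, comp.clinical, comp.definitions
        sim_cfg_dict = dataclasses.asdict(cfg.simulate)
    else:
        probe_matrices, clinical, defs = load_compendium_dir(cfg.input_dir)
        sim_cfg_dict = None
    if cfg.signatures_path is not None:
        defs = load_signature_set(cfg.signatures_path)

    scoring = score_compendium(
        probe_matrices, clinical, defs, rs_scheme=cfg.rs_scheme,
        balancing=BalancingConfig(seed=cfg.seed),
    )
    cohort, consort = apply_consort_filters(clinical, scoring.kept_datasets)
    outcomes = harmonize_endpoints(cohort)
    groups = stratify_subgroups(cohort, clinical, scoring.kept_datasets)

    cox_rows, uni_rows, dlr_rows, lr_rows, km_frames = [], [], [], [], []
    for name in cfg.subgroups:
        ids = groups[name]
        if name == "55-65 ER+/LN-":
            young_clin = clinical[clinical["sample_id"].isin(ids)]
            young_out = harmonize_endpoints(young_clin)
            res = _benchmark_subgroup(name, ids, young_clin, young_out, scoring, defs)
        else:
            res = _benchmark_subgroup(name, ids, cohort, outcomes, scoring, defs)
        for acc, part in zip((cox_rows, uni_rows, dlr_rows, lr_rows, km_frames), res):
            acc.extend(part)

    strat_rows = []
    if "ER+/LN-" in groups and "55-65 ER+/LN-" in groups:
        for d in defs:
            cats = scoring.category_series(d.id)
            old = cats.reindex(groups["ER+/LN-"]).dropna()
            young = cats.reindex(groups["55-65 ER+/LN-"]).dropna()
            try:
                sc = compare_stratification(old, young, d.id)
                strat_rows.append(
                    {
                        "signature_id": d.id, "chi2": sc.chi2, "df": sc.df, "p": sc.p,
                        "low_expected_warning": sc.low_expected_warning,
                    }
                )
            except ValueError as e:
                log.warning("%s: stratification comparison skipped (%s)", d.id, e)

    coverage = pd.DataFrame(
        [
            {"dataset_id": r.dataset_id, "excluded": r.excluded,
             **{f"coverage_{k}": v for k, v in sorted(r.coverage.items())},
             "reasons": "; ".join(r.reasons)}
            for r in scoring.coverage_reports
        ]
    )
    provenance = {
        "sigbench_version": __version__,
        "seed": cfg.seed,
        "rs_scheme": cfg.rs_scheme,
        "config_hash": config_hash(
            {"simulate": sim_cfg_dict, "rs_scheme": cfg.rs_scheme, "subgroups": list(cfg.subgroups)},
            cfg.seed,
        ),
        "notes": (
            "ties=efron; unknown covariate levels retained as categories; "
            "median follow-up by reverse Kaplan-Meier; p-values two-sided, "
            "no multiplicity correction"
        ),
    }
    report = BenchmarkReport(
        consort=consort,
        coverage=coverage,
        calls=scoring.calls,
        cox_rows=pd.DataFrame(cox_rows),
        univariable=pd.DataFrame(uni_rows),
        delta_lr_rows=pd.DataFrame(dlr_rows),
        logrank=pd.DataFrame(lr_rows),
        stratification=pd.DataFrame(strat_rows),
        km_curves=pd.concat(km_frames, ignore_index=True) if km_frames else pd.DataFrame(),
        median_followup_years=median_followup(outcomes),
        provenance=provenance,
    )
    write_report(report, outdir)
    return report


def write_report(report: BenchmarkReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str):
        df.to_csv(outdir / name, sep="\t", index=False, float_format=FLOAT_FMT)

    dump(report.calls, "risk_calls.tsv")
    dump(report.cox_rows, "cox_multivariable.tsv")
    dump(report.univariable, "univariable_lr_cindex.tsv")
    dump(report.delta_lr_rows, "delta_lr.tsv")
    dump(report.logrank, "km_logrank.tsv")
    dump(report.stratification, "stratification_chi2.tsv")
    dump(report.km_curves, "km_curves.tsv")
    dump(report.coverage, "coverage.tsv")
    (outdir / "consort.json").write_text(
        json.dumps(report.consort.to_dict(), indent=1) + "\n"
    )
    (outdir / "consort.txt").write_text(report.consort.to_text() + "\n")
    summary = {
        "median_followup_years": report.median_followup_years,
        "provenance": report.provenance,
    }
    (outdir / "benchmark.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
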