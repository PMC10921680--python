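"""Survival benchmarking statistics.

The benchmarking toolkit of the analysis: Kaplan–Meier curves with k-group
log-rank tests, multivariable Cox proportional-hazards models (Efron ties)
with hazard ratios against stated reference levels, univariable
likelihood-ratio statistics and concordance indices as single-number
measures of signature prognostic capacity, the ΔLR of nested adjustment
models with and without a signature, χ² comparison of risk stratification
between age groups, and reverse Kaplan–Meier median follow-up.

Model fitting is delegated to ``lifelines``; this module owns the design
encodings (unknown covariate levels are retained as explicit categories,
never dropped), the nested-model bookkeeping, and the result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .cohort import hormonal_therapy, size_category


@dataclass(frozen=True)
class CovariateSet:
    """Named clinico-pathological adjustment set (never contains the signature)."""

    name: str
    covariates: tuple[str, ...]


# Adjustment for the full cohort: ER status, nodal status, grade, tumour
# size (<2 vs >=2 cm) and hormonal therapy.  ER/LN-defined subgroups are
# adjusted for size, grade and hormonal therapy only.  Chemotherapy is never
# adjusted for (too few treated patients).
ALL_PATIENTS_ADJUSTMENT = CovariateSet("all_patients", ("er", "nodal", "grade", "size", "hormonal"))
SUBGROUP_ADJUSTMENT = CovariateSet("subgroup", ("size", "grade", "hormonal"))


@dataclass
class CoxFit:
    terms: list[str]
    coefs: pd.Series
    hr: pd.Series
    hr_lower: pd.Series
    hr_upper: pd.Series
    p: pd.Series
    log_likelihood: float
    log_likelihood_null: float
    lr: float
    lr_df: int
    lr_p: float
    c_index: float
    n: int
    events: int
    ties: str = "efron"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefs,
                "HR": self.hr,
                "HR_lower95": self.hr_lower,
                "HR_upper95": self.hr_upper,
                "p": self.p,
            }
        )


@dataclass
class DeltaLRResult:
    signature_id: str
    subgroup: str
    lr_full: float
    lr_reduced: float
    delta: float
    df: int
    p: float


@dataclass
class StratificationComparison:
    signature_id: str
    table: pd.DataFrame  # risk category × age group counts
    chi2: float
    df: int
    p: float
    low_expected_warning: bool = False


@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # category -> columns (time, survival)
    group_sizes: dict[str, int]
    statistic: float
    df: int
    p: float


def encode_covariates(clinical: pd.DataFrame, covset: CovariateSet) -> pd.DataFrame:
    """Dummy-encode an adjustment set against its reference levels.

    Reference levels: ER negative, node negative, grade 1, size < 2 cm, no
    hormonal therapy.  Unknown levels become explicit indicator columns so
    that samples with partially missing pathology stay in the model.
    """
    idx = clinical["sample_id"] if "sample_id" in clinical.columns else clinical.index
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    cols: dict[str, pd.Series] = {}

    def add_dummies(prefix: str, series: pd.Series, levels: list[str], ref: str):
        series = series.astype(object).where(series.notna(), "unknown")
        for lv in levels:
            if lv == ref:
                continue
            ind = (series == lv).astype(float)
            if ind.sum() > 0:  # drop empty levels
                cols[f"{prefix}[{lv}]"] = ind

    for cov in covset.covariates:
        if cov == "er":
            add_dummies("er", df["er"], ["neg", "pos", "unknown"], "neg")
        elif cov == "nodal":
            add_dummies("nodal", df["nodal"], ["neg", "pos", "unknown"], "neg")
        elif cov == "grade":
            grade = df["grade"].map(
                lambda g: "unknown" if pd.isna(g) or g == "unknown" else str(int(g))
            )
            add_dummies("grade", grade, ["1", "2", "3", "unknown"], "1")
        elif cov == "size":
            add_dummies("size", size_category(df["size_cm"]), ["<2", ">=2", "unknown"], "<2")
        elif cov == "hormonal":
            add_dummies("hormonal", hormonal_therapy(df["treatment"]), ["no", "yes", "unknown"], "no")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    design = pd.DataFrame(cols, index=df.index)
    design.index.name = "sample_id"
    return design


def encode_signature(categories: pd.Series, reference: str, signature_id: str = "sig") -> pd.DataFrame:
    """Indicator columns per non-reference, non-empty signature category."""
    cats = [c for c in pd.unique(categories) if c != reference]
    cats.sort()
    cols = {}
    for c in cats:
        cols[f"{signature_id}[{c}]"] = (categories == c).astype(float)
    design = pd.DataFrame(cols, index=categories.index)
    design.index.name = "sample_id"
    return design


class CoxConvergenceError(RuntimeError):
    """Partial-likelihood maximisation failed (e.g. complete separation)."""


def fit_cox(
    outcomes: pd.DataFrame,
    design: pd.DataFrame | None = None,
    ties: str = "efron",
    penalizer: float = 0.0,
) -> CoxFit:
    """Cox PH partial-likelihood fit with LR vs the null model and c-index.

    ``outcomes`` carries ``time``/``event`` indexed by sample id; ``design``
    is a numeric matrix on the same index (``None`` or empty fits the null
    model only).  ``penalizer`` adds an L2 ridge — zero by default; callers
    may retry with a small value when sparse categories separate.
    """
    if design is None:
        design = pd.DataFrame(index=outcomes.index)
    if not design.index.equals(outcomes.index):
        design = design.reindex(outcomes.index)
        if design.isna().any().any():
            raise ValueError("design and outcomes cover different samples")
    events = int(outcomes["event"].sum())
    if events < 1:
        raise ValueError("need at least one event to fit a Cox model")
    # Enforce a usable design: drop constant columns (empty or saturated
    # levels) and exact duplicates of earlier columns — both make the
    # partial-likelihood Hessian singular.
    keep: list[str] = []
    for c in design.columns:
        if design[c].nunique() <= 1:
            continue
        if any(np.array_equal(design[c].to_numpy(), design[k].to_numpy()) for k in keep):
            continue
        keep.append(c)
    design = design[keep]
    data = pd.concat([outcomes[["time", "event"]], design], axis=1)
    n = len(data)
    if design.shape[1] == 0:
        ll0 = _null_partial_loglik(data["time"].to_numpy(), data["event"].to_numpy())
        return CoxFit(
            terms=[], coefs=pd.Series(dtype=float), hr=pd.Series(dtype=float),
            hr_lower=pd.Series(dtype=float), hr_upper=pd.Series(dtype=float),
            p=pd.Series(dtype=float), log_likelihood=ll0, log_likelihood_null=ll0,
            lr=0.0, lr_df=0, lr_p=1.0, c_index=0.5, n=n, events=events, ties=ties,
        )
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tighter-than-default Newton precision so coefficients agree
            # with brute-force maximisation to < 1e-4
            cph.fit(
                data, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9},
            )
    except Exception as e:  # lifelines ConvergenceError and kin
        ev_by_col = {
            c: int(outcomes.loc[design[c] > 0, "event"].sum()) for c in design.columns
        }
        sparse = [c for c, ev in ev_by_col.items() if ev == 0 or design[c].sum() < 3]
        raise CoxConvergenceError(
            f"Cox fit did not converge ({e}); suspect separation in "
            f"columns {sparse or list(design.columns)} "
            f"(events per level: {ev_by_col})"
        ) from e
    lrt = cph.log_likelihood_ratio_test()
    ll = float(cph.log_likelihood_)
    lr = float(lrt.test_statistic)
    lr_df = int(lrt.degrees_freedom)
    summ = cph.summary
    return CoxFit(
        terms=list(design.columns),
        coefs=summ["coef"],
        hr=summ["exp(coef)"],
        hr_lower=summ["exp(coef) lower 95%"],
        hr_upper=summ["exp(coef) upper 95%"],
        p=summ["p"],
        log_likelihood=ll,
        log_likelihood_null=ll - lr / 2.0,
        lr=lr,
        lr_df=lr_df,
        lr_p=float(stats.chi2.sf(lr, lr_df)),
        c_index=float(cph.concordance_index_),
        n=n,
        events=events,
        ties=ties,
    )


def _null_partial_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood at β = 0 (all risk weights equal 1)."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        r = int((time >= t).sum())
        # Efron: the j-th tied event sees the risk set shrunk by j*d/d = j.
        ll -= sum(np.log(r - j) for j in range(d))
    return float(ll)


def c_index(outcomes: pd.DataFrame, risk_score: pd.Series) -> float:
    """Concordance of a risk score with survival; 0.5 for a constant score."""
    risk_score = risk_score.reindex(outcomes.index)
    return float(
        concordance_index(outcomes["time"], -risk_score, outcomes["event"])
    )


def univariable_summary(
    outcomes: pd.DataFrame,
    categories: pd.Series,
    reference: str,
    signature_id: str,
    penalizer: float = 0.0,
) -> dict:
    """Univariable Cox LR and c-index for one signature's categories."""
    categories = categories.reindex(outcomes.index)
    sig = encode_signature(categories, reference, signature_id)
    fit = fit_cox(outcomes, sig, penalizer=penalizer)
    lp = sig.to_numpy() @ fit.coefs.reindex(sig.columns).fillna(0.0).to_numpy()
    return {
        "signature_id": signature_id,
        "lr": fit.lr,
        "df": fit.lr_df,
        "p": fit.lr_p,
        "c_index": c_index(outcomes, pd.Series(lp, index=sig.index)),
        "n": fit.n,
        "events": fit.events,
    }


def delta_lr(
    outcomes: pd.DataFrame,
    adjustment: pd.DataFrame,
    signature: pd.DataFrame,
    signature_id: str = "sig",
    subgroup: str = "All",
    penalizer: float = 0.0,
) -> DeltaLRResult:
    """Added LR of a signature beyond the clinico-pathological adjustment.

    Both nested models are fitted on exactly the same samples; a mismatch in
    row sets raises rather than silently dropping rows.
    """
    if not adjustment.index.equals(signature.index):
        raise ValueError(
            "adjustment and signature matrices cover different samples; "
            "complete the same rows before fitting nested models"
        )
    reduced = fit_cox(outcomes, adjustment, penalizer=penalizer)
    full_design = pd.concat([adjustment, signature], axis=1)
    full = fit_cox(outcomes, full_design, penalizer=penalizer)
    sig_levels = sum(signature[c].nunique() > 1 for c in signature.columns)
    df = max(sig_levels, 1)
    lr_full = 2.0 * (full.log_likelihood - full.log_likelihood_null)
    lr_reduced = 2.0 * (reduced.log_likelihood - reduced.log_likelihood_null)
    delta = lr_full - lr_reduced
    return DeltaLRResult(
        signature_id=signature_id,
        subgroup=subgroup,
        lr_full=lr_full,
        lr_reduced=lr_reduced,
        delta=delta,
        df=df,
        p=float(stats.chi2.sf(max(delta, 0.0), df)),
    )


def km_logrank(categories: pd.Series, outcomes: pd.DataFrame) -> KMLogrankResult:
    """Product-limit curves per category and the k-group log-rank test."""
    categories = categories.reindex(outcomes.index)
    sizes = categories.value_counts()
    empty = [c for c in sizes.index if sizes[c] == 0]
    groups = [c for c in sizes.index if sizes[c] > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups for a log-rank test")
    curves: dict[str, pd.DataFrame] = {}
    for g in sorted(groups):
        mask = categories == g
        kmf = KaplanMeierFitter()
        kmf.fit(outcomes.loc[mask, "time"], outcomes.loc[mask, "event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(
        outcomes["time"], categories, outcomes["event"]
    )
    return KMLogrankResult(
        curves=curves,
        group_sizes={g: int(sizes[g]) for g in groups},
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
    )


def compare_stratification(
    calls_old: pd.Series, calls_young: pd.Series, signature_id: str = "sig"
) -> StratificationComparison:
    """χ² test of independence on the risk-category × age-group table."""
    labels = sorted(set(pd.unique(calls_old)) | set(pd.unique(calls_young)))
    table = pd.DataFrame(
        {
            "older": pd.Series(calls_old).value_counts().reindex(labels).fillna(0).astype(int),
            "younger": pd.Series(calls_young).value_counts().reindex(labels).fillna(0).astype(int),
        }
    )
    nonzero = table.sum(axis=1) > 0
    table = table[nonzero]
    if table.shape[0] < 2:
        raise ValueError("degenerate stratification table: fewer than two categories")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return StratificationComparison(
        signature_id=signature_id,
        table=table,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        low_expected_warning=bool((expected < 1).any()),
    )


def median_followup(outcomes: pd.DataFrame, method: str = "reverse_km") -> float:
    """Median follow-up in years (reverse Kaplan–Meier by default)."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes")
    if method == "reverse_km":
        kmf = KaplanMeierFitter()
        kmf.fit(outcomes["time"], 1 - outcomes["event"])
        return float(kmf.median_survival_time_)
    if method == "plain":
        return float(outcomes["time"].median())
    raise ValueError(f"unknown method {method!r}")
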