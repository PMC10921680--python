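"""CONSORT exclusion cascade, endpoint harmonisation, and analysis subgroups.

Clinical tables are pandas DataFrames with one row per sample and the
columns in :data:`CLINICAL_COLUMNS`.  Categorical biomarker columns
(er/pr/her2/nodal) take values ``pos``/``neg``/``unknown``; grade is
1/2/3/``unknown``; treatment is one of ``chemo``, ``hormonal``,
``chemo+hormonal``, ``untreated``, ``unknown``.

The cohort cascade mirrors the study design: keep patients aged ≥ 70,
then drop samples lacking ER status, lacking survival, or belonging to a
dataset excluded for insufficient signature coverage — counting each
exclusion at the first rule it hits.  Recurrence-free and distant-
metastasis-free endpoints are harmonised into a single recurrence-free
survival metric censored at 10 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "sample_id",
    "dataset_id",
    "age",
    "er",
    "pr",
    "her2",
    "nodal",
    "grade",
    "size_cm",
    "treatment",
    "endpoint_type",
    "time_years",
    "event",
]

SUBGROUP_NAMES = ("All", "ER+/LN+", "ER+/LN-", "ER+/LN-/HER2-", "55-65 ER+/LN-")

DEFAULT_HORIZON = 10.0


@dataclass
class CohortFilterReport:
    """Ordered exclusion tally; arithmetic must balance on every run."""

    n_input: int
    steps: list[tuple[str, int]]
    n_output: int

    def __post_init__(self):
        excluded = sum(n for _, n in self.steps)
        if self.n_input - excluded != self.n_output:
            raise AssertionError(
                f"CONSORT arithmetic broken: {self.n_input} - {excluded} != {self.n_output}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [{"filter": name, "n_excluded": n} for name, n in self.steps],
            "n_output": self.n_output,
        }

    def to_text(self) -> str:
        lines = [f"Assessed for eligibility: n = {self.n_input}"]
        for name, n in self.steps:
            lines.append(f"  excluded — {name}: n = {n}")
        lines.append(f"Analysis cohort: n = {self.n_output}")
        return "\n".join(lines)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    if clinical["sample_id"].duplicated().any():
        dupes = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in clinical table: {dupes[:5]}")
    has_ep = clinical["endpoint_type"].isin(["RFS", "DMFS"])
    bad_time = has_ep & (clinical["time_years"].isna() | (clinical["time_years"] < 0))
    if bad_time.any():
        rows = clinical.index[bad_time].tolist()
        raise ValueError(f"negative or missing follow-up time at rows {rows[:5]}")
    if (clinical["age"] <= 0).any():
        raise ValueError("non-positive ages in clinical table")
    return clinical


def harmonize_endpoints(clinical: pd.DataFrame, horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Harmonise RFS/DMFS into one endpoint censored at ``horizon`` years.

    Recurrence-free survival is used where recorded; distant-metastasis-free
    survival substitutes where it is the only endpoint.  Follow-up beyond
    the horizon is administratively censored (event set to 0).  Samples with
    no endpoint are omitted — they are flagged by the CONSORT cascade
    instead.  Idempotent.
    """
    has_ep = clinical["endpoint_type"].isin(["RFS", "DMFS"])
    sub = clinical.loc[has_ep, ["sample_id", "endpoint_type", "time_years", "event"]].copy()
    over = sub["time_years"] > horizon
    sub.loc[over, "time_years"] = horizon
    sub.loc[over, "event"] = 0
    sub["event"] = sub["event"].astype(int)
    sub["horizon"] = horizon
    return sub.rename(columns={"time_years": "time"}).set_index("sample_id")


def apply_consort_filters(
    clinical: pd.DataFrame,
    kept_datasets: list[str],
    age_min: float = 70.0,
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Run the ordered exclusion cascade and tally each step.

    Order: age < ``age_min`` → unknown ER → missing survival → sample in a
    coverage-excluded dataset.  Counting is first-match: a sample missing
    both ER and survival is tallied under ER only.
    """
    validate_clinical(clinical)
    df = clinical.copy()
    n_input = len(df)
    steps: list[tuple[str, int]] = []

    young = df["age"] < age_min
    steps.append((f"age under {age_min:g}", int(young.sum())))
    df = df[~young]

    no_er = ~df["er"].isin(["pos", "neg"])
    steps.append(("missing ER status", int(no_er.sum())))
    df = df[~no_er]

    no_surv = ~df["endpoint_type"].isin(["RFS", "DMFS"])
    steps.append(("missing survival information", int(no_surv.sum())))
    df = df[~no_surv]

    kept = set(kept_datasets)
    bad_ds = ~df["dataset_id"].isin(kept)
    steps.append(("insufficient signature gene coverage", int(bad_ds.sum())))
    df = df[~bad_ds]

    report = CohortFilterReport(n_input=n_input, steps=steps, n_output=len(df))
    return df.reset_index(drop=True), report


def hormonal_therapy(treatment: pd.Series) -> pd.Series:
    """Collapse the treatment field to hormonal-therapy yes/no/unknown."""
    out = pd.Series("unknown", index=treatment.index)
    out[treatment.isin(["hormonal", "chemo+hormonal"])] = "yes"
    out[treatment.isin(["chemo", "untreated"])] = "no"
    return out


def size_category(size_cm: pd.Series) -> pd.Series:
    """Dichotomise tumour size at 2 cm (< 2 vs ≥ 2), keeping unknowns."""
    out = pd.Series("unknown", index=size_cm.index, dtype=object)
    known = size_cm.notna()
    out[known & (size_cm < 2.0)] = "<2"
    out[known & (size_cm >= 2.0)] = ">=2"
    return out


def stratify_subgroups(
    cohort: pd.DataFrame,
    clinical_all: pd.DataFrame | None = None,
    kept_datasets: list[str] | None = None,
    comparator_ages: tuple[float, float] = (55.0, 65.0),
) -> dict[str, pd.Index]:
    """Clinically motivated subgroups as sample-id index sets.

    ``All`` is everyone passing the cascade; the ER+/LN± subgroups require
    known nodal status, and the HER2− subgroup additionally a negative
    HER2.  The younger-postmenopausal comparator ("55-65 ER+/LN-") applies
    the comparator age window (inclusive on both ends) to the pre-age-filter
    population with the same ER/survival/coverage rules, and needs
    ``clinical_all`` and ``kept_datasets``.
    """
    ids = cohort.set_index("sample_id")
    erpos = ids["er"] == "pos"
    lnpos = ids["nodal"] == "pos"
    lnneg = ids["nodal"] == "neg"
    her2neg = ids["her2"] == "neg"
    groups: dict[str, pd.Index] = {
        "All": ids.index,
        "ER+/LN+": ids.index[erpos & lnpos],
        "ER+/LN-": ids.index[erpos & lnneg],
        "ER+/LN-/HER2-": ids.index[erpos & lnneg & her2neg],
    }
    if clinical_all is not None and kept_datasets is not None:
        lo, hi = comparator_ages
        window = clinical_all[(clinical_all["age"] >= lo) & (clinical_all["age"] <= hi)]
        young = window[
            window["er"].isin(["pos", "neg"])
            & window["endpoint_type"].isin(["RFS", "DMFS"])
            & window["dataset_id"].isin(set(kept_datasets))
        ].set_index("sample_id")
        groups["55-65 ER+/LN-"] = young.index[
            (young["er"] == "pos") & (young["nodal"] == "neg")
        ]
    return groups
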