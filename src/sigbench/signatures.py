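"""Research-version signature scoring engines.

Six engines, one per clinically used breast-cancer signature family:

* ``score_ggi`` — weighted-sum genomic grade index, affinely rescaled per
  dataset so observed grade-1 tumours average −1 and grade-3 tumours +1;
  dichotomised GG1/GG3 at zero.  Missing histologic grade is first imputed
  from the raw score (``impute_tumour_grade``).
* ``score_70gene`` — Pearson correlation to a good-prognosis centroid;
  Low risk above a correlation threshold (default 0.4).
* ``score_recurrence_score`` — reference-gene-normalised grouped composite
  with group floors, affinely rescaled to 0–100 and clamped; categorised
  under either the original or the TAILORx cutoff scheme.
* ``score_ccs`` — mean expression of cell-cycle genes with external or
  cohort-tertile cutoffs.
* ``classify_pam50`` — Spearman nearest-centroid intrinsic subtyping over
  five subtypes, on ER-balanced median-centered expression.
* ``score_rorp`` — risk-of-recurrence proliferation score: a linear
  combination of the five subtype correlations plus a proliferation-gene
  mean.

Every engine drops signature genes absent from the platform and scores over
the intersection, recording the coverage fraction on each call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .definitions import RiskCutoffs, SignatureDefinition, _subtype_sort_key
from .preprocessing import GeneMatrix


@dataclass
class RiskCall:
    """One sample's continuous score and categorical call for one signature."""

    sample_id: str
    signature_id: str
    score: float
    category: str
    genes_used: int
    coverage: float
    correlations: dict[str, float] | None = None


@dataclass
class GradeVector:
    """Histologic grade per sample with observed/imputed provenance."""

    grade: pd.Series  # sample_id -> 1/2/3, NaN if missing
    provenance: pd.Series  # sample_id -> "observed" | "imputed"

    @classmethod
    def observed(cls, grade: pd.Series) -> "GradeVector":
        prov = pd.Series("observed", index=grade.index)
        return cls(grade.astype(float), prov)


class CoverageError(ValueError):
    """A signature cannot be scored: too few of its genes are present."""


def calls_to_frame(calls: Sequence[RiskCall], dataset_id: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "signature_id": [c.signature_id for c in calls],
            "score": [c.score for c in calls],
            "category": [c.category for c in calls],
            "genes_used": [c.genes_used for c in calls],
            "coverage": [c.coverage for c in calls],
        }
    )
    if dataset_id is not None:
        df.insert(1, "dataset_id", dataset_id)
    return df


def _available(expr: GeneMatrix, d: SignatureDefinition) -> list[str]:
    present = set(expr.genes)
    return [g for g in d.genes if g in present]


def raw_ggi_scores(expr: GeneMatrix, ggi_def: SignatureDefinition) -> pd.Series:
    """Unscaled weighted-sum scores over the available signature genes."""
    if ggi_def.engine != "weighted_sum":
        raise ValueError("grade index requires a weighted_sum definition")
    genes = _available(expr, ggi_def)
    if not genes:
        raise CoverageError(f"{ggi_def.id}: no signature genes present")
    w = np.array([ggi_def.weights[g] for g in genes])
    return expr.values.loc[genes].T @ w


def impute_tumour_grade(
    expr: GeneMatrix,
    grades: GradeVector,
    ggi_def: SignatureDefinition,
    pooled_midpoint: float | None = None,
) -> GradeVector:
    """Fill missing histologic grades from the raw grade-index score.

    A midpoint is calibrated between the mean raw scores of observed grade-1
    and grade-3 samples in the dataset; samples with missing grade become
    grade 1 below the midpoint and grade 3 at or above it.  Observed grades
    are never overwritten.  When the dataset lacks observed grade-1 or
    grade-3 samples, ``pooled_midpoint`` (calibrated on the pooled cohort)
    is used instead.
    """
    grade = grades.grade.copy()
    prov = grades.provenance.copy()
    missing = grade.index[grade.isna()]
    if len(missing) == 0:
        return GradeVector(grade, prov)
    raw = raw_ggi_scores(expr, ggi_def)
    g1 = grade.index[grade == 1]
    g3 = grade.index[grade == 3]
    if len(g1) and len(g3):
        midpoint = (raw[g1].mean() + raw[g3].mean()) / 2.0
    elif pooled_midpoint is not None:
        midpoint = pooled_midpoint
    else:
        raise ValueError(
            f"{expr.dataset_id}: cannot calibrate grade imputation "
            "(no observed grade-1/grade-3 samples and no pooled midpoint)"
        )
    imputed = pd.Series(np.where(raw[missing] < midpoint, 1.0, 3.0), index=missing)
    grade.loc[missing] = imputed
    prov.loc[missing] = "imputed"
    return GradeVector(grade, prov)


def score_ggi(
    expr: GeneMatrix, ggi_def: SignatureDefinition, grades: GradeVector
) -> list[RiskCall]:
    """Grade-index scores rescaled within the dataset to grade anchors.

    The affine map sends the mean raw score of grade-1 samples to −1 and of
    grade-3 samples to +1; calls are GG1 below zero and GG3 otherwise.
    """
    raw = raw_ggi_scores(expr, ggi_def)
    genes_used = len(_available(expr, ggi_def))
    cov = genes_used / len(ggi_def.genes)
    grade = grades.grade.reindex(raw.index)
    if grade.isna().any():
        raise ValueError(f"{expr.dataset_id}: grades incomplete; impute first")
    m1 = raw[grade == 1].mean()
    m3 = raw[grade == 3].mean()
    if not (np.isfinite(m1) and np.isfinite(m3)):
        raise ValueError(f"{expr.dataset_id}: need grade-1 and grade-3 samples to scale")
    if m1 == m3:
        raise ValueError(f"{expr.dataset_id}: degenerate scaling (grade means equal)")
    scaled = -1.0 + 2.0 * (raw - m1) / (m3 - m1)
    cut = ggi_def.cutoffs
    return [
        RiskCall(s, ggi_def.id, float(scaled[s]), cut.bin(float(scaled[s])), genes_used, cov)
        for s in scaled.index
    ]


def score_70gene(expr: GeneMatrix, d: SignatureDefinition) -> list[RiskCall]:
    """Pearson correlation to the good-prognosis centroid over shared genes."""
    genes = _available(expr, d)
    if len(genes) < 3:
        raise CoverageError(f"{d.id}: fewer than 3 overlapping genes")
    cov = len(genes) / len(d.genes)
    (cls,) = d.centroids.keys() if len(d.centroids) == 1 else (None,)
    if cls is None:
        raise ValueError(f"{d.id}: expected a single good-prognosis centroid")
    centroid = np.array([d.centroids[cls][g] for g in genes])
    sub = expr.values.loc[genes]
    calls = []
    for s in sub.columns:
        r = float(stats.pearsonr(sub[s].to_numpy(), centroid).statistic)
        calls.append(RiskCall(s, d.id, r, d.cutoffs.bin(r), len(genes), cov))
    return calls


def score_recurrence_score(
    expr: GeneMatrix,
    d: SignatureDefinition,
    scheme: RiskCutoffs | None = None,
) -> list[RiskCall]:
    """Grouped reference-normalised composite rescaled to 0–100.

    Steps per sample: subtract the mean of the reference genes from every
    gene; average each configured gene group and apply its floor; take the
    weighted sum of group scores; map through the stored affine rescale and
    clamp to [0, 100]; categorise under ``scheme`` (default: the
    definition's own cutoffs).
    """
    scheme = scheme or d.cutoffs
    present = set(expr.genes)
    missing = [g for g in d.nonreference_genes if g not in present]
    if missing:
        raise CoverageError(
            f"{d.id}: non-reference genes absent ({', '.join(sorted(missing)[:5])}); "
            "dataset should have been excluded upstream"
        )
    refs = [g for g in d.reference_genes if g in present]
    if not refs:
        raise ValueError(f"{d.id}: no reference genes present for normalization")
    genes = list(d.nonreference_genes)
    cov = (len(genes) + len(refs)) / len(d.genes)
    ref_mean = expr.values.loc[refs].mean(axis=0)
    norm = expr.values.loc[genes].sub(ref_mean, axis=1)
    a, b = d.rescale if d.rescale is not None else (0.0, 1.0)
    calls = []
    for s in norm.columns:
        unscaled = 0.0
        for gg in d.gene_groups.values():
            gscore = float(norm.loc[list(gg.genes), s].mean())
            if gg.floor is not None:
                gscore = max(gscore, gg.floor)
            unscaled += gg.weight * gscore
        score = float(np.clip(a + b * unscaled, 0.0, 100.0))
        calls.append(RiskCall(s, d.id, score, scheme.bin(score), len(genes) + len(refs), cov))
    return calls


def derive_tertile_cutoffs(scores: pd.Series, labels: tuple[str, ...]) -> RiskCutoffs:
    """Cohort-tertile thresholds; scores at a threshold fall in the lower bin."""
    s = np.sort(scores.to_numpy())
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 samples to derive tertiles")
    t1 = float(s[int(np.ceil(n / 3)) - 1])
    t2 = float(s[int(np.ceil(2 * n / 3)) - 1])
    if not t1 < t2:
        raise ValueError("degenerate tertile thresholds (too many ties)")
    return RiskCutoffs("derived_tertiles", (t1, t2), labels, "lower")


def score_ccs(
    expr: GeneMatrix, d: SignatureDefinition, cutoffs: RiskCutoffs | None = None
) -> list[RiskCall]:
    """Mean expression of available cell-cycle genes with tertile-style bins.

    ``cutoffs`` overrides the definition's; a definition whose cutoff scheme
    is named ``"derive"`` gets cohort tertiles computed from these scores.
    """
    genes = _available(expr, d)
    if not genes:
        raise CoverageError(f"{d.id}: no signature genes present")
    cov = len(genes) / len(d.genes)
    scores = expr.values.loc[genes].mean(axis=0)
    cut = cutoffs or d.cutoffs
    if cut is not None and cut.scheme_name == "derive":
        cut = derive_tertile_cutoffs(scores, cut.labels)
    return [
        RiskCall(s, d.id, float(scores[s]), cut.bin(float(scores[s])), len(genes), cov)
        for s in scores.index
    ]


def classify_pam50(expr_centered: GeneMatrix, d: SignatureDefinition) -> list[RiskCall]:
    """Nearest-centroid intrinsic subtyping by Spearman correlation.

    Expects ER-balanced median-centered expression.  The call is the
    arg-max correlation subtype; exact ties resolve to the earliest subtype
    in the fixed order (Basal-like, Her2-enriched, Luminal A, Luminal B,
    Normal-like).  The per-class correlation vector is retained for the
    downstream risk-of-recurrence composite.
    """
    genes = _available(expr_centered, d)
    if len(genes) < 3:
        raise CoverageError(f"{d.id}: fewer than 3 overlapping genes")
    cov = len(genes) / len(d.genes)
    classes = sorted(d.centroids, key=_subtype_sort_key)
    cent = np.column_stack([[d.centroids[c][g] for g in genes] for c in classes])
    cent_ranks = np.apply_along_axis(stats.rankdata, 0, cent)
    sub = expr_centered.values.loc[genes]
    calls = []
    for s in sub.columns:
        x = sub[s].to_numpy()
        if np.ptp(x) == 0:
            raise ValueError(f"{s}: all-constant expression; Spearman undefined")
        xr = stats.rankdata(x)
        corrs = {}
        for j, c in enumerate(classes):
            rho = float(np.corrcoef(xr, cent_ranks[:, j])[0, 1])
            corrs[c] = rho
        best = max(classes, key=lambda c: (corrs[c], -classes.index(c)))
        calls.append(RiskCall(s, d.id, corrs[best], best, len(genes), cov, correlations=corrs))
    return calls


def score_rorp(
    calls_pam50: Sequence[RiskCall],
    expr_centered: GeneMatrix,
    d: SignatureDefinition,
) -> list[RiskCall]:
    """Risk-of-recurrence proliferation composite.

    score = Σ_k coef_k · ρ_k + coef_prolif · mean(proliferation genes),
    with ρ_k the subtype correlations carried on the nearest-centroid calls
    and the proliferation mean taken over the centered matrix.
    """
    prolif = [g for g in d.proliferation_genes if g in set(expr_centered.genes)]
    if not prolif:
        raise CoverageError(f"{d.id}: no proliferation genes present")
    cov = len(prolif) / len(d.proliferation_genes)
    pmean = expr_centered.values.loc[prolif].mean(axis=0)
    calls = []
    for call in calls_pam50:
        if call.correlations is None:
            raise ValueError(f"{call.sample_id}: nearest-centroid correlations missing")
        score = sum(
            coef * call.correlations[cls] for cls, coef in d.coefficients.items()
        ) + d.proliferation_coef * float(pmean[call.sample_id])
        calls.append(
            RiskCall(
                call.sample_id, d.id, float(score), d.cutoffs.bin(float(score)),
                len(prolif), cov,
            )
        )
    return calls
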