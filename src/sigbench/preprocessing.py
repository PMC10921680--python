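"""Probe→gene collapsing, coverage rules, and ER-balanced median centering.

Expression arrives per dataset as a probes × samples matrix of normalised
log-expression plus a probe→gene annotation.  Probes mapping to the same
gene are combined by averaging.  Datasets are excluded when signature gene
coverage breaks the hard rules (the 70-gene signature needs ≥ 75% of its
genes; the recurrence-score composite needs every non-reference gene).

Centroid-based classification is sensitive to the ER+ skew of population
cohorts, so centering references are built by Monte-Carlo balancing: the
predominant ER group is repeatedly subsampled down to the minority group's
size, the per-gene median of each balanced set is taken, and the reference
is the mean of those medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .definitions import SignatureDefinition

log = logging.getLogger(__name__)

ER_LEVELS = ("pos", "neg", "unknown")


@dataclass
class ProbeMatrix:
    """Per-dataset probes × samples log-expression with probe→gene annotation."""

    dataset_id: str
    values: pd.DataFrame  # index: probe_id, columns: sample_id
    annotation: pd.Series  # probe_id -> gene symbol (NaN/missing = unmapped)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")


@dataclass
class GeneMatrix:
    """Per-dataset genes × samples log-expression with ER labels attached."""

    dataset_id: str
    values: pd.DataFrame  # index: gene symbol, columns: sample_id
    er_status: pd.Series | None = None  # sample_id -> pos/neg/unknown

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate gene symbols")
        if self.er_status is not None:
            self.er_status = self.er_status.reindex(self.values.columns).fillna("unknown")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class CoverageReport:
    dataset_id: str
    coverage: dict[str, float]  # signature id -> fraction of genes present
    passed: dict[str, bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return not all(self.passed.values())


@dataclass(frozen=True)
class BalancingConfig:
    """Monte-Carlo ER-balancing parameters (default 100 subsamples)."""

    n_subsamples: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


def collapse_probes(pm: ProbeMatrix) -> GeneMatrix:
    """Average probes mapping to the same gene; drop unmapped probes.

    Values flagged missing (NaN) are omitted from the average, so a gene's
    value is the mean over its observed probes.
    """
    ann = pm.annotation.reindex(pm.values.index).dropna()
    ann = ann[ann.astype(str).str.len() > 0]
    if ann.empty:
        raise ValueError(f"{pm.dataset_id}: no probes map to any gene")
    mapped = pm.values.loc[ann.index]
    gene_values = mapped.groupby(ann).mean()
    gene_values.index.name = "gene"
    return GeneMatrix(dataset_id=pm.dataset_id, values=gene_values)


def compute_coverage(
    gm: GeneMatrix, defs: Sequence[SignatureDefinition]
) -> CoverageReport:
    """Per-signature gene coverage and hard pass/fail rules for one dataset.

    The 70-gene-style rule fails a signature whose coverage falls strictly
    below ``min_coverage``; composites flagged ``requires_all_nonreference``
    fail if any non-reference gene is absent.  Signatures without a hard rule
    report coverage only.
    """
    if not defs:
        raise ValueError("no signature definitions supplied")
    present = set(gm.genes)
    coverage: dict[str, float] = {}
    passed: dict[str, bool] = {}
    reasons: list[str] = []
    for d in defs:
        n_have = sum(g in present for g in d.genes)
        frac = n_have / len(d.genes)
        coverage[d.id] = frac
        ok = True
        if d.requires_all_nonreference:
            missing = [g for g in d.nonreference_genes if g not in present]
            if missing:
                ok = False
                reasons.append(
                    f"{d.id}: non-reference genes absent ({', '.join(sorted(missing)[:5])})"
                )
        elif d.min_coverage > 0 and frac < d.min_coverage:
            ok = False
            reasons.append(f"{d.id}: coverage {frac:.3f} < {d.min_coverage:.2f}")
        passed[d.id] = ok
    return CoverageReport(gm.dataset_id, coverage, passed, reasons)


def exclude_datasets(
    reports: Sequence[CoverageReport],
) -> tuple[list[str], dict[str, list[str]]]:
    """Split datasets into kept ids and excluded ids with reasons."""
    seen = set()
    kept: list[str] = []
    excluded: dict[str, list[str]] = {}
    for r in reports:
        if r.dataset_id in seen:
            raise ValueError(f"duplicate coverage report for {r.dataset_id}")
        seen.add(r.dataset_id)
        if r.excluded:
            excluded[r.dataset_id] = list(r.reasons)
        else:
            kept.append(r.dataset_id)
    return kept, excluded


def er_balanced_reference(gm: GeneMatrix, cfg: BalancingConfig) -> pd.Series:
    """ER-balanced per-gene centering reference for one dataset.

    For each of ``cfg.n_subsamples`` rounds the predominant ER group is
    subsampled (without replacement) down to the minority group's size, the
    per-gene median of the balanced set is computed, and the reference is
    the mean of the round medians.  Samples with unknown ER status never
    contribute.  With exactly balanced groups the subsampling is a no-op and
    the reference equals the plain per-gene median of all ER-labelled
    samples.  Datasets lacking one ER group fall back to the plain per-gene
    median with a warning.
    """
    if gm.er_status is None:
        raise ValueError(f"{gm.dataset_id}: no ER labels attached")
    er = gm.er_status
    pos = list(er.index[er == "pos"])
    neg = list(er.index[er == "neg"])
    if not pos and not neg:
        raise ValueError(f"{gm.dataset_id}: no ER labels at all")
    if not pos or not neg:
        log.warning(
            "%s: only one ER group present; falling back to plain per-gene median",
            gm.dataset_id,
        )
        cols = pos or neg
        return gm.values[cols].median(axis=1)
    if len(pos) == len(neg):
        return gm.values[pos + neg].median(axis=1)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(cfg.seed)
    acc = np.zeros(gm.values.shape[0])
    maj = np.asarray(majority, dtype=object)
    for _ in range(cfg.n_subsamples):
        pick = rng.choice(maj, size=len(minority), replace=False)
        cols = minority + list(pick)
        acc += gm.values[cols].median(axis=1).to_numpy()
    return pd.Series(acc / cfg.n_subsamples, index=gm.values.index)


def center_by_reference(gm: GeneMatrix, ref: pd.Series) -> GeneMatrix:
    """Subtract the per-gene reference from every sample."""
    missing = gm.genes.difference(ref.index)
    if len(missing):
        raise ValueError(
            f"{gm.dataset_id}: reference lacks genes {sorted(missing)[:5]}"
        )
    centered = gm.values.sub(ref.reindex(gm.genes), axis=0)
    return GeneMatrix(gm.dataset_id, centered, gm.er_status)
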