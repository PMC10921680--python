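"""Synthetic multi-dataset breast-cancer compendium generator.

Emulates the statistical structure of a multi-study expression compendium
(many datasets on heterogeneous array platforms, pre-normalised
log-expression, probe-level measurement with probe→gene annotation,
platform-specific gene dropout, a strong ER+ skew, ~50% node-negative
disease, right-censored recurrence outcomes, and missingness in routine
pathology) with complete ground truth per sample:

* a latent intrinsic subtype drives the 50-gene classifier genes and ER
  status (luminal tumours are ER+ with high fidelity);
* a latent three-level risk group drives the grade-index, 70-gene,
  recurrence-score-proliferation and cell-cycle genes, histologic grade,
  and — through per-group log hazard ratios — the recurrence hazard;
* recurrence times are exponential under proportional hazards with
  independent uniform administrative censoring tuned to a realistic median
  follow-up (≈ 6.2 years), and a fraction of records carry a
  distant-metastasis endpoint instead of recurrence-free survival.

Default parameters reproduce the marginals of the cohort the analysis
targets: 39 datasets totalling roughly 9.5k samples, ER+ prevalence 0.873,
grade distribution ≈ 11/44/37% with 7.5% unknown, PR/HER2/nodal/size
missingness 22.5/26.9/7.3/6.4%, ages ≥ 70 peaking near 75 and decaying to
96, plus younger comparator ages.

Generation is a pure function of (config, master seed): random streams are
derived from ``SeedSequence(seed, spawn_key=(k,))`` with k = 0 for global
gene parameters, (1, i) for dataset i's expression, 2 for clinical
covariates, 3 for survival, so adding a dataset never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .definitions import SignatureDefinition, default_signature_set
from .preprocessing import ProbeMatrix

SUBTYPES = ("Luminal A", "Luminal B", "Her2-enriched", "Basal-like", "Normal-like")
RISK_LABELS = ("Low", "Intermediate", "High")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic compendium."""

    n_datasets: int = 39
    samples_per_dataset: tuple[int, int] = (60, 420)
    n_genes: int = 1500

    # Latent structure
    subtype_proportions: tuple[float, ...] = (0.55, 0.25, 0.08, 0.07, 0.05)
    subtype_separation: float = 3.0  # centroid scale in noise-SD units
    # P(risk | subtype), rows in SUBTYPES order, columns Low/Int/High
    risk_given_subtype: tuple[tuple[float, float, float], ...] = (
        (0.50, 0.35, 0.15),
        (0.20, 0.40, 0.40),
        (0.15, 0.35, 0.50),
        (0.10, 0.30, 0.60),
        (0.45, 0.35, 0.20),
    )
    risk_separation: float = 1.5  # per-risk-step expression shift, SD units
    noise_sd: float = 1.0
    probe_noise_sd: float = 0.25
    probes_per_gene: tuple[int, int] = (1, 3)
    n_unmapped_probes: int = 10
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    # ER structure
    er_pos_prevalence: float = 0.873
    er_luminal_fidelity: float = 0.95
    er_expr_shift: float = 2.0  # ER-module genes in ER+ tumours

    # Platform dropout per gene class (fraction of genes absent per dataset)
    dropout_background: float = 0.02
    dropout_g70: float = 0.09
    dropout_ccs: float = 0.04
    # Planted coverage failures: the first n_fail_70gene datasets get heavy
    # 70-gene dropout; the next n_fail_rs each lose one RS non-reference gene.
    n_fail_70gene: int = 1
    fail_70gene_dropout: float = 0.30
    n_fail_rs: int = 1

    # Ages: a fraction of samples are >= 70 with a ramp-to-mode then
    # geometric decay over 70–96; the remainder are younger (uniform).
    older_fraction: float = 0.15
    age_mode: float = 75.0
    age_decay: float = 0.82
    age_range: tuple[int, int] = (70, 96)
    younger_age_range: tuple[int, int] = (35, 69)

    # Clinical marginals and missingness
    pr_pos_given_known: float = 0.608
    her2_pos_given_known: float = 0.112
    nodal_neg_given_known: float = 0.546
    size_ge2_given_known: float = 0.740
    grade_given_risk: tuple[tuple[float, float, float], ...] = (
        (0.30, 0.60, 0.10),
        (0.05, 0.60, 0.35),
        (0.02, 0.25, 0.73),
    )
    grade_flip_to_missing: float = 0.075
    missing_pr: float = 0.225
    missing_her2: float = 0.269
    missing_nodal: float = 0.073
    missing_size: float = 0.064
    missing_er: float = 0.044
    missing_survival: float = 0.24
    treatment_probs: tuple[tuple[str, float], ...] = (
        ("chemo", 0.039),
        ("hormonal", 0.553),
        ("chemo+hormonal", 0.018),
        ("untreated", 0.304),
        ("unknown", 0.086),
    )

    # Survival model
    baseline_hazard: float = 0.04  # events / year at Low risk
    log_hr_by_risk: tuple[float, float, float] = (0.0, 0.35, 0.7)
    censor_max_years: float = 12.4  # uniform admin censoring; median ≈ 6.2 y
    dmfs_fraction: float = 0.30
    horizon: float = 10.0

    def __post_init__(self):
        if not np.isclose(sum(self.subtype_proportions), 1.0):
            raise ValueError("subtype proportions must sum to 1")
        for row in self.risk_given_subtype:
            if not np.isclose(sum(row), 1.0):
                raise ValueError("risk_given_subtype rows must sum to 1")
        if not 0 <= self.dropout_g70 < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    @property
    def dataset_ids(self) -> list[str]:
        return [f"ds{i:03d}" for i in range(self.n_datasets)]

    @property
    def planted_70gene_failures(self) -> list[str]:
        return self.dataset_ids[: self.n_fail_70gene]

    @property
    def planted_rs_failures(self) -> list[str]:
        return self.dataset_ids[self.n_fail_70gene : self.n_fail_70gene + self.n_fail_rs]


@dataclass
class Compendium:
    probe_matrices: dict[str, ProbeMatrix]
    clinical: pd.DataFrame
    truth: pd.DataFrame
    definitions: list[SignatureDefinition]
    config: SimulationConfig
    seed: int


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _gene_universe(cfg: SimulationConfig, defs: list[SignatureDefinition]) -> list[str]:
    sig_genes: list[str] = []
    seen = set()
    for d in defs:
        for g in d.genes:
            if g not in seen:
                seen.add(g)
                sig_genes.append(g)
    n_bg = max(cfg.n_genes - len(sig_genes), 0)
    return sig_genes + [f"BG{i:05d}" for i in range(n_bg)]


def _signal_plan(defs: list[SignatureDefinition]) -> dict:
    """Per-signature gene index structures used to plant signal."""
    by_id = {d.id: d for d in defs}
    plan = {
        "ggi_genes": list(by_id["ggi"].genes),
        "ggi_sign": np.sign([by_id["ggi"].weights[g] for g in by_id["ggi"].genes]),
        "g70_genes": list(by_id["g70"].genes),
        "g70_centroid": np.array(
            [next(iter(by_id["g70"].centroids.values()))[g] for g in by_id["g70"].genes]
        ),
        "ccs_genes": list(by_id["ccs"].genes),
        "pam_genes": list(by_id["pam50"].genes),
        "pam_centroids": {
            cls: np.array([vec[g] for g in by_id["pam50"].genes])
            for cls, vec in by_id["pam50"].centroids.items()
        },
        "prolif_genes": list(by_id["rorp"].proliferation_genes),
        "rs_prolif": list(by_id["rs"].gene_groups["proliferation"].genes),
        "rs_er": list(by_id["rs"].gene_groups["er"].genes),
        "rs_genes": list(by_id["rs"].genes),
    }
    return plan


def _baselines(cfg: SimulationConfig, genes: list[str], rs_genes: set[str], seed: int) -> pd.Series:
    rng = _rng(seed, 0)
    base = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes)), index=genes
    )
    # Recurrence-score genes (incl. references) share one baseline so that
    # reference normalisation isolates the planted signal and the stored
    # 0–100 rescale map stays meaningful.
    base[list(rs_genes)] = cfg.baseline_mean
    return base


def generate_expression(
    cfg: SimulationConfig,
    seed: int,
    defs: list[SignatureDefinition] | None = None,
) -> tuple[dict[str, ProbeMatrix], pd.DataFrame]:
    """Per-dataset probe matrices plus the sample-level truth table."""
    defs = defs if defs is not None else default_signature_set()
    plan = _signal_plan(defs)
    genes = _gene_universe(cfg, defs)
    gene_pos = {g: i for i, g in enumerate(genes)}
    baselines = _baselines(cfg, genes, set(plan["rs_genes"]), seed)

    p_lum = cfg.subtype_proportions[0] + cfg.subtype_proportions[1]
    f_lum = cfg.er_luminal_fidelity
    f_non = float(np.clip((cfg.er_pos_prevalence - f_lum * p_lum) / (1 - p_lum), 0.02, 0.98))

    probe_matrices: dict[str, ProbeMatrix] = {}
    truth_rows = []
    for i, ds in enumerate(cfg.dataset_ids):
        rng = _rng(seed, 1, i)
        n_s = int(rng.integers(cfg.samples_per_dataset[0], cfg.samples_per_dataset[1] + 1))
        sample_ids = [f"{ds}_S{j:04d}" for j in range(n_s)]

        subtype_idx = rng.choice(len(SUBTYPES), size=n_s, p=cfg.subtype_proportions)
        risk = np.array(
            [rng.choice(3, p=cfg.risk_given_subtype[k]) for k in subtype_idx]
        )
        is_lum = np.isin(subtype_idx, [0, 1])
        er_pos = rng.random(n_s) < np.where(is_lum, f_lum, f_non)

        expr = baselines.to_numpy()[:, None] + rng.normal(
            0.0, cfg.noise_sd, (len(genes), n_s)
        )
        rz = (risk - 1).astype(float)  # -1 / 0 / +1
        sep = cfg.risk_separation

        rows = [gene_pos[g] for g in plan["ggi_genes"]]
        expr[rows, :] += sep * plan["ggi_sign"][:, None] * rz[None, :]
        rows = [gene_pos[g] for g in plan["g70_genes"]]
        expr[rows, :] += -sep * plan["g70_centroid"][:, None] * rz[None, :]
        rows = [gene_pos[g] for g in plan["ccs_genes"]]
        expr[rows, :] += sep * rz[None, :]
        rows = [gene_pos[g] for g in plan["rs_prolif"]]
        expr[rows, :] += sep * rz[None, :]
        rows = [gene_pos[g] for g in plan["rs_er"]]
        expr[rows, :] += cfg.er_expr_shift * er_pos[None, :].astype(float)
        rows = [gene_pos[g] for g in plan["pam_genes"]]
        cent = np.column_stack(
            [plan["pam_centroids"][SUBTYPES[k]] for k in subtype_idx]
        )
        expr[rows, :] += cfg.subtype_separation * cent
        rows = [gene_pos[g] for g in plan["prolif_genes"]]
        expr[rows, :] += sep * rz[None, :]

        # Platform dropout: per-class gene removal, plus planted failures.
        drop = np.zeros(len(genes), dtype=bool)
        g70_set = set(plan["g70_genes"])
        ccs_set = set(plan["ccs_genes"])
        protected = set(plan["rs_genes"]) | set(plan["pam_genes"]) | set(plan["ggi_genes"])
        g70_rate = (
            cfg.fail_70gene_dropout
            if ds in cfg.planted_70gene_failures
            else cfg.dropout_g70
        )
        u = rng.random(len(genes))
        for j, g in enumerate(genes):
            if g in g70_set:
                drop[j] = u[j] < g70_rate
            elif g in ccs_set:
                drop[j] = u[j] < cfg.dropout_ccs
            elif g in protected:
                drop[j] = False
            else:
                drop[j] = u[j] < cfg.dropout_background
        if ds in cfg.planted_rs_failures:
            by_id = {d.id: d for d in defs}
            victim = by_id["rs"].nonreference_genes[
                int(rng.integers(len(by_id["rs"].nonreference_genes)))
            ]
            drop[gene_pos[victim]] = True

        kept = [g for j, g in enumerate(genes) if not drop[j]]
        kept_rows = [gene_pos[g] for g in kept]

        # Probe layer: 1–3 probes per kept gene, with probe-level noise.
        n_probes = rng.integers(
            cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1, len(kept)
        )
        probe_ids, probe_gene, blocks = [], [], []
        for g, row, k in zip(kept, kept_rows, n_probes):
            for p in range(k):
                probe_ids.append(f"{g}_p{p + 1}")
                probe_gene.append(g)
            blocks.append(
                expr[row][None, :]
                + rng.normal(0.0, cfg.probe_noise_sd, (int(k), n_s))
            )
        values = np.vstack(blocks)
        # Unmapped probes exercise annotation-based dropping downstream.
        for q in range(cfg.n_unmapped_probes):
            probe_ids.append(f"{ds}_orphan{q}")
            probe_gene.append(None)
        if cfg.n_unmapped_probes:
            values = np.vstack(
                [values, rng.normal(cfg.baseline_mean, 1.0, (cfg.n_unmapped_probes, n_s))]
            )
        pm = ProbeMatrix(
            dataset_id=ds,
            values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
            annotation=pd.Series(probe_gene, index=probe_ids, dtype=object),
        )
        probe_matrices[ds] = pm
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "dataset_id": ds,
                    "subtype": [SUBTYPES[k] for k in subtype_idx],
                    "risk_group": [RISK_LABELS[r] for r in risk],
                    "log_hazard": [cfg.log_hr_by_risk[r] for r in risk],
                    "er_true": np.where(er_pos, "pos", "neg"),
                    "seed_path": f"{seed}/(1,{i})",
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return probe_matrices, truth


def generate_clinical(cfg: SimulationConfig, truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Clinical covariates per sample, with configured missingness."""
    rng = _rng(seed, 2)
    n = len(truth)
    risk_idx = truth["risk_group"].map({lab: i for i, lab in enumerate(RISK_LABELS)}).to_numpy()

    older = rng.random(n) < cfg.older_fraction
    lo, hi = cfg.age_range
    support = np.arange(lo, hi + 1)
    ramp = np.minimum((support - (lo - 1)) / (cfg.age_mode - (lo - 1)), 1.0)
    decay = np.where(
        support > cfg.age_mode, cfg.age_decay ** (support - cfg.age_mode), 1.0
    )
    w = ramp * decay
    age_old = rng.choice(support, size=n, p=w / w.sum())
    ylo, yhi = cfg.younger_age_range
    age_young = rng.integers(ylo, yhi + 1, n)
    age = np.where(older, age_old, age_young) + rng.uniform(0.0, 1.0, n)

    def with_missing(values: np.ndarray, rate: float) -> np.ndarray:
        out = values.astype(object)
        out[rng.random(n) < rate] = "unknown"
        return out

    er = with_missing(truth["er_true"].to_numpy(), cfg.missing_er)
    pr = with_missing(
        np.where(rng.random(n) < cfg.pr_pos_given_known, "pos", "neg"), cfg.missing_pr
    )
    her2 = with_missing(
        np.where(rng.random(n) < cfg.her2_pos_given_known, "pos", "neg"), cfg.missing_her2
    )
    nodal = with_missing(
        np.where(rng.random(n) < cfg.nodal_neg_given_known, "neg", "pos"), cfg.missing_nodal
    )

    grade_probs = np.array(cfg.grade_given_risk)[risk_idx]
    grade = np.array(
        [rng.choice([1.0, 2.0, 3.0], p=p) for p in grade_probs], dtype=object
    )
    grade[rng.random(n) < cfg.grade_flip_to_missing] = np.nan

    size = np.where(
        rng.random(n) < cfg.size_ge2_given_known,
        rng.uniform(2.0, 5.0, n),
        rng.uniform(0.5, 1.999, n),
    ).astype(object)
    size[rng.random(n) < cfg.missing_size] = np.nan

    tnames = [t for t, _ in cfg.treatment_probs]
    tprobs = np.array([p for _, p in cfg.treatment_probs])
    treatment = rng.choice(tnames, size=n, p=tprobs / tprobs.sum())

    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "dataset_id": truth["dataset_id"],
            "age": age,
            "er": er,
            "pr": pr,
            "her2": her2,
            "nodal": nodal,
            "grade": grade,
            "size_cm": pd.to_numeric(pd.Series(size), errors="coerce"),
            "treatment": treatment,
        }
    )


def generate_survival(cfg: SimulationConfig, truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Endpoint type, follow-up time, and event indicator per sample.

    Exponential recurrence times under proportional hazards
    (hazard = baseline · exp(planted log-HR)) with independent uniform
    administrative censoring; a configured fraction of records carry a
    distant-metastasis endpoint label, and a configured fraction lack
    survival altogether.
    """
    rng = _rng(seed, 3)
    n = len(truth)
    hazard = cfg.baseline_hazard * np.exp(truth["log_hazard"].to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cfg.censor_max_years, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    endpoint = np.where(rng.random(n) < cfg.dmfs_fraction, "DMFS", "RFS").astype(object)
    missing = rng.random(n) < cfg.missing_survival
    endpoint[missing] = "none"
    time = time.astype(object)
    time[missing] = np.nan
    event = event.astype(object)
    event[missing] = np.nan
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "endpoint_type": endpoint,
            "time_years": pd.to_numeric(pd.Series(time), errors="coerce"),
            "event": pd.to_numeric(pd.Series(event), errors="coerce"),
        }
    )


def generate_compendium(
    cfg: SimulationConfig,
    seed: int,
    defs: list[SignatureDefinition] | None = None,
) -> Compendium:
    """Full synthetic compendium: expression, clinical table, truth."""
    defs = defs if defs is not None else default_signature_set()
    probe_matrices, truth = generate_expression(cfg, seed, defs)
    clinical = generate_clinical(cfg, truth, seed)
    surv = generate_survival(cfg, truth, seed)
    clinical = clinical.merge(surv, on="sample_id", validate="1:1")
    return Compendium(
        probe_matrices=probe_matrices,
        clinical=clinical,
        truth=truth,
        definitions=defs,
        config=cfg,
        seed=seed,
    )


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale configuration for tests and examples.

    Shrinks the compendium (datasets, samples, genes) while keeping every
    structural feature — planted coverage failures, missingness, ER skew,
    proportional-hazards outcomes — identical to the full default.
    """
    base = dict(
        n_datasets=6,
        samples_per_dataset=(120, 260),
        n_genes=400,
        older_fraction=0.55,
    )
    base.update(overrides)
    return SimulationConfig(**base)
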