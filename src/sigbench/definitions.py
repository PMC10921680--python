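"""Declarative signature definitions and risk-category cutoff schemes.

A :class:`SignatureDefinition` describes one gene-expression signature in a
form every scoring engine can consume: the gene list, per-gene weights or
per-class centroids, grouped gene sets with weights and floors (for the
recurrence-score composite), reference genes, the continuous→categorical
cutoff scheme, and the minimum fraction of genes that must be present on a
platform for the signature to be scored at all.

Definitions round-trip to a documented JSON schema, so the gene content can
be swapped (e.g. real published coefficients vs. the synthetic set shipped
with this package) without touching engine code.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

# Engines understood by sigbench.signatures
ENGINES = (
    "weighted_sum",
    "centroid_correlation",
    "mean_score",
    "rs_composite",
    "ror_composite",
)

# Fixed subtype order used for deterministic arg-max tie-breaking in the
# nearest-centroid classifier.
SUBTYPE_ORDER = (
    "Basal-like",
    "Her2-enriched",
    "Luminal A",
    "Luminal B",
    "Normal-like",
)


@dataclass(frozen=True)
class RiskCutoffs:
    """Ordered thresholds mapping a continuous score to risk categories.

    ``boundary_rule`` holds one entry per threshold: ``"lower"`` means a
    score exactly equal to the threshold falls in the lower (earlier)
    category, ``"upper"`` means it falls in the upper one.  This encodes
    printed rules such as "Low < 18, Intermediate 18–31, High > 31"
    (thresholds ``[18, 31]``, rules ``["upper", "lower"]``) without
    ambiguity at the boundaries.
    """

    scheme_name: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]
    boundary_rule: tuple[str, ...]

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "labels", tuple(self.labels))
        rule = self.boundary_rule
        if isinstance(rule, str):
            rule = (rule,) * len(t)
        object.__setattr__(self, "boundary_rule", tuple(rule))
        if len(self.labels) != len(t) + 1:
            raise ValueError(
                f"{self.scheme_name}: need len(labels) == len(thresholds)+1"
            )
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"{self.scheme_name}: thresholds must be strictly increasing")
        if len(self.boundary_rule) != len(t):
            raise ValueError(f"{self.scheme_name}: one boundary rule per threshold")
        if any(r not in ("lower", "upper") for r in self.boundary_rule):
            raise ValueError(f"{self.scheme_name}: boundary rules must be 'lower'/'upper'")

    def bin(self, score: float) -> str:
        """Assign ``score`` to a category label."""
        if not np.isfinite(score):
            raise ValueError(f"cannot bin non-finite score {score!r}")
        for t, rule, label in zip(self.thresholds, self.boundary_rule, self.labels):
            if score < t or (score == t and rule == "lower"):
                return label
        return self.labels[-1]

    def to_dict(self) -> dict:
        return {
            "scheme_name": self.scheme_name,
            "thresholds": list(self.thresholds),
            "labels": list(self.labels),
            "boundary_rule": list(self.boundary_rule),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskCutoffs":
        return cls(
            scheme_name=d["scheme_name"],
            thresholds=tuple(d["thresholds"]),
            labels=tuple(d["labels"]),
            boundary_rule=tuple(d["boundary_rule"]),
        )


# The printed recurrence-score cutoff schemes.  The original rule places 18
# and 31 inside Intermediate ("Intermediate 18–31"); the TAILORx printing
# leaves 10 and 26 unassigned, resolved here as Low ≤ 10 < Intermediate ≤ 25
# < High.
RS_ORIGINAL_CUTOFFS = RiskCutoffs(
    scheme_name="original",
    thresholds=(18.0, 31.0),
    labels=("Low risk", "Intermediate risk", "High risk"),
    boundary_rule=("upper", "lower"),
)
RS_TAILORX_CUTOFFS = RiskCutoffs(
    scheme_name="tailorx",
    thresholds=(10.0, 25.0),
    labels=("Low risk", "Intermediate risk", "High risk"),
    boundary_rule=("lower", "lower"),
)
RS_CUTOFF_SCHEMES = {"original": RS_ORIGINAL_CUTOFFS, "tailorx": RS_TAILORX_CUTOFFS}


@dataclass(frozen=True)
class GeneGroup:
    """A named gene set inside a composite score, with weight and optional floor."""

    genes: tuple[str, ...]
    weight: float
    floor: float | None = None


@dataclass
class SignatureDefinition:
    id: str
    engine: str
    genes: tuple[str, ...]
    weights: dict[str, float] | None = None
    centroids: dict[str, dict[str, float]] | None = None  # class -> gene -> value
    gene_groups: dict[str, GeneGroup] | None = None
    reference_genes: tuple[str, ...] = ()
    cutoffs: RiskCutoffs | None = None
    min_coverage: float = 0.0
    rescale: tuple[float, float] | None = None  # score = a + b * unscaled
    requires_all_nonreference: bool = False
    # ror_composite extras: per-class coefficients on centroid correlations
    # plus a proliferation term.
    coefficients: dict[str, float] | None = None
    proliferation_genes: tuple[str, ...] = ()
    proliferation_coef: float = 0.0
    # Cox reference level; defaults to the first cutoff label.
    reference_category: str | None = None

    def __post_init__(self):
        self.genes = tuple(self.genes)
        self.reference_genes = tuple(self.reference_genes)
        self.proliferation_genes = tuple(self.proliferation_genes)
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.id}: duplicate genes in definition")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError(f"{self.id}: min_coverage must be in [0, 1]")
        if self.weights is not None:
            missing = set(self.weights) - set(self.genes)
            if missing:
                raise ValueError(f"{self.id}: weights for unknown genes {sorted(missing)}")
        if self.centroids is not None:
            for cls, vec in self.centroids.items():
                if set(vec) != set(self.genes):
                    raise ValueError(f"{self.id}: centroid {cls!r} does not align with genes")

    @property
    def nonreference_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if g not in set(self.reference_genes))

    @property
    def labels(self) -> tuple[str, ...]:
        if self.engine == "centroid_correlation" and self.centroids and self.cutoffs is None:
            return tuple(sorted(self.centroids, key=_subtype_sort_key))
        if self.cutoffs is None:
            raise ValueError(f"{self.id}: no categorical labels configured")
        return self.cutoffs.labels

    @property
    def reference_label(self) -> str:
        if self.reference_category is not None:
            return self.reference_category
        return self.labels[0]

    def to_dict(self) -> dict:
        d: dict = {
            "id": self.id,
            "engine": self.engine,
            "genes": list(self.genes),
            "min_coverage": self.min_coverage,
        }
        if self.weights is not None:
            d["weights"] = [self.weights[g] for g in self.genes]
        if self.centroids is not None:
            d["centroids"] = {
                cls: [vec[g] for g in self.genes] for cls, vec in self.centroids.items()
            }
        if self.gene_groups is not None:
            d["gene_groups"] = {
                name: {
                    "genes": list(gg.genes),
                    "weight": gg.weight,
                    **({"floor": gg.floor} if gg.floor is not None else {}),
                }
                for name, gg in self.gene_groups.items()
            }
        if self.reference_genes:
            d["reference_genes"] = list(self.reference_genes)
        if self.cutoffs is not None:
            d["cutoffs"] = self.cutoffs.to_dict()
        if self.rescale is not None:
            d["rescale"] = {"a": self.rescale[0], "b": self.rescale[1]}
        if self.requires_all_nonreference:
            d["requires_all_nonreference"] = True
        if self.coefficients is not None:
            d["coefficients"] = dict(self.coefficients)
        if self.proliferation_genes:
            d["proliferation_genes"] = list(self.proliferation_genes)
        if self.proliferation_coef:
            d["proliferation_coef"] = self.proliferation_coef
        if self.reference_category is not None:
            d["reference_category"] = self.reference_category
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureDefinition":
        genes = tuple(d["genes"])
        weights = None
        if "weights" in d:
            weights = dict(zip(genes, (float(w) for w in d["weights"])))
        centroids = None
        if "centroids" in d:
            centroids = {
                c: dict(zip(genes, (float(v) for v in vec)))
                for c, vec in d["centroids"].items()
            }
        gene_groups = None
        if "gene_groups" in d:
            gene_groups = {
                name: GeneGroup(
                    genes=tuple(gg["genes"]),
                    weight=float(gg["weight"]),
                    floor=float(gg["floor"]) if "floor" in gg else None,
                )
                for name, gg in d["gene_groups"].items()
            }
        cutoffs = RiskCutoffs.from_dict(d["cutoffs"]) if "cutoffs" in d else None
        rescale = None
        if "rescale" in d:
            rescale = (float(d["rescale"]["a"]), float(d["rescale"]["b"]))
        return cls(
            id=d["id"],
            engine=d["engine"],
            genes=genes,
            weights=weights,
            centroids=centroids,
            gene_groups=gene_groups,
            reference_genes=tuple(d.get("reference_genes", ())),
            cutoffs=cutoffs,
            min_coverage=float(d.get("min_coverage", 0.0)),
            rescale=rescale,
            requires_all_nonreference=bool(d.get("requires_all_nonreference", False)),
            coefficients={k: float(v) for k, v in d["coefficients"].items()}
            if "coefficients" in d
            else None,
            proliferation_genes=tuple(d.get("proliferation_genes", ())),
            proliferation_coef=float(d.get("proliferation_coef", 0.0)),
            reference_category=d.get("reference_category"),
        )


def _subtype_sort_key(name: str):
    try:
        return (0, SUBTYPE_ORDER.index(name))
    except ValueError:
        return (1, name)


def save_signature_set(defs: Sequence[SignatureDefinition], path) -> None:
    payload = {"signatures": [d.to_dict() for d in defs]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_signature_set(path) -> list[SignatureDefinition]:
    with open(path) as fh:
        payload = json.load(fh)
    return [SignatureDefinition.from_dict(d) for d in payload["signatures"]]


def build_synthetic_signature_set(seed: int = 714) -> list[SignatureDefinition]:
    """Construct the synthetic six-signature set shipped with the package.

    The gene content is synthetic: gene symbols, weights, centroids and
    composite coefficients are drawn deterministically from ``seed`` rather
    than taken from the original signature publications (whose proprietary or
    published coefficients are deliberately not reproduced here).  The
    *structure* matches the research signatures: a weighted-sum grade index
    (GGI-like), a 70-gene good-prognosis centroid, a 21-gene reference-
    normalised composite with grouped weights and floors rescaled to 0–100
    (RS-like), a mean-expression cell-cycle score, a 50-gene five-subtype
    nearest-centroid classifier (PAM50-like), and a risk-of-recurrence
    proliferation composite over the subtype correlations.
    """
    rng = np.random.default_rng(seed)

    ggi_genes = tuple(f"GGIG{i:03d}" for i in range(1, 61))
    g70_genes = tuple(f"MPG{i:03d}" for i in range(1, 71))
    pam_genes = tuple(f"PAMG{i:03d}" for i in range(1, 51))
    ccs_genes = tuple(f"CCSG{i:03d}" for i in range(1, 31))
    rs_prolif = tuple(f"RSPR{i}" for i in range(1, 6))
    rs_her2 = ("RSHER1", "RSHER2")
    rs_er = tuple(f"RSER{i}" for i in range(1, 5))
    rs_inv = ("RSINV1", "RSINV2")
    rs_single = ("RSSG1", "RSSG2", "RSSG3")
    rs_ref = tuple(f"RSREF{i}" for i in range(1, 6))
    rs_genes = rs_prolif + rs_her2 + rs_er + rs_inv + rs_single + rs_ref

    # GGI-like: signed weights, dataset-rescaled to grade anchors downstream.
    ggi_w = rng.normal(0.0, 1.0, len(ggi_genes))
    ggi_w[np.abs(ggi_w) < 0.2] = 0.2  # keep every gene informative
    ggi = SignatureDefinition(
        id="ggi",
        engine="weighted_sum",
        genes=ggi_genes,
        weights=dict(zip(ggi_genes, ggi_w.round(4))),
        cutoffs=RiskCutoffs("ggi", (0.0,), ("GG1", "GG3"), ("upper",)),
        min_coverage=0.5,
    )

    # 70-gene-like: correlation to a good-prognosis centroid; Low risk above
    # the published research threshold of 0.4, High risk otherwise.
    g70_centroid = rng.normal(0.0, 1.0, len(g70_genes)).round(4)
    g70 = SignatureDefinition(
        id="g70",
        engine="centroid_correlation",
        genes=g70_genes,
        centroids={"good_prognosis": dict(zip(g70_genes, g70_centroid))},
        cutoffs=RiskCutoffs("g70", (0.4,), ("High risk", "Low risk"), ("lower",)),
        min_coverage=0.75,
    )

    # RS-like composite: group scores with floors, 0–100 affine rescale,
    # printed cutoff schemes.
    rs_groups = {
        "proliferation": GeneGroup(rs_prolif, weight=1.0, floor=-2.0),
        "her2": GeneGroup(rs_her2, weight=0.5, floor=-1.0),
        "er": GeneGroup(rs_er, weight=-0.7),
        "invasion": GeneGroup(rs_inv, weight=0.3),
        "single_1": GeneGroup((rs_single[0],), weight=0.15),
        "single_2": GeneGroup((rs_single[1],), weight=-0.1),
        "single_3": GeneGroup((rs_single[2],), weight=0.1),
    }
    rs = SignatureDefinition(
        id="rs",
        engine="rs_composite",
        genes=rs_genes,
        gene_groups=rs_groups,
        reference_genes=rs_ref,
        cutoffs=RS_ORIGINAL_CUTOFFS,
        min_coverage=1.0,
        rescale=(50.0, 14.0),
        requires_all_nonreference=True,
    )

    # CCS-like: plain mean of cell-cycle genes; fixed external cutoffs.
    ccs = SignatureDefinition(
        id="ccs",
        engine="mean_score",
        genes=ccs_genes,
        cutoffs=RiskCutoffs("ccs", (6.4, 7.6), ("Low", "Intermediate", "High"), "lower"),
        min_coverage=0.1,
    )

    # PAM50-like nearest-centroid classifier over five intrinsic subtypes.
    pam_centroids = {
        cls: dict(zip(pam_genes, rng.normal(0.0, 1.0, len(pam_genes)).round(4)))
        for cls in SUBTYPE_ORDER
    }
    pam50 = SignatureDefinition(
        id="pam50",
        engine="centroid_correlation",
        genes=pam_genes,
        centroids=pam_centroids,
        min_coverage=0.5,
        reference_category="Luminal A",
    )

    # ROR-P-like: linear combination of subtype correlations plus a
    # proliferation-gene mean (proliferation genes are a PAM50 subset).
    rorp = SignatureDefinition(
        id="rorp",
        engine="ror_composite",
        genes=pam_genes,
        min_coverage=0.5,
        coefficients={
            "Basal-like": 0.4,
            "Her2-enriched": 0.3,
            "Luminal A": -0.3,
            "Luminal B": 0.3,
            "Normal-like": -0.2,
        },
        proliferation_genes=pam_genes[:10],
        proliferation_coef=1.0,
        cutoffs=RiskCutoffs(
            "rorp",
            (-0.5, 0.5),
            ("Low proliferation", "Int. proliferation", "High proliferation"),
            "lower",
        ),
    )

    return [ggi, g70, rs, ccs, pam50, rorp]


def default_signature_set() -> list[SignatureDefinition]:
    """Load the synthetic signature set shipped as package data."""
    ref = importlib.resources.files("sigbench.data") / "synthetic_signatures.json"
    with importlib.resources.as_file(ref) as path:
        return load_signature_set(path)
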