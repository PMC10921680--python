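"""Score the cohort with all six signatures and tabulate risk stratification.

Reports, per signature, how the assembled older cohort distributes over
risk categories / intrinsic subtypes, plus agreement of each signature's
grouping with the planted risk groups.  Writes
results/03_signature_distribution.tsv.
"""

import pandas as pd

from sigbench.cohort import apply_consort_filters
from sigbench.pipeline import score_compendium
from sigbench.simulate import generate_compendium
from analysis_config import ANALYSIS_SEED, CONFIG, RESULTS


def main():
    comp = generate_compendium(CONFIG, ANALYSIS_SEED)
    scoring = score_compendium(comp.probe_matrices, comp.clinical, comp.definitions)
    cohort, _ = apply_consort_filters(comp.clinical, scoring.kept_datasets)
    ids = set(cohort["sample_id"])
    calls = scoring.calls[scoring.calls["sample_id"].isin(ids)]

    rows = []
    for sig, sub in calls.groupby("signature_id"):
        counts = sub["category"].value_counts()
        for cat, n in counts.items():
            rows.append({"signature_id": sig, "category": cat,
                         "n": int(n), "pct": round(100 * n / len(sub), 1)})
    dist = pd.DataFrame(rows).sort_values(["signature_id", "category"])
    RESULTS.mkdir(exist_ok=True)
    dist.to_csv(RESULTS / "03_signature_distribution.tsv", sep="\t", index=False)
    print(dist.to_string(index=False))

    truth = comp.truth.set_index("sample_id")
    print("\nagreement with planted risk (high-risk call vs planted High):")
    high_label = {"ggi": "GG3", "g70": "High risk", "rs": "High risk",
                  "ccs": "High", "rorp": "High proliferation"}
    for sig, label in high_label.items():
        sub = calls[calls["signature_id"] == sig].set_index("sample_id")
        planted_high = truth.loc[sub.index, "risk_group"] == "High"
        called_high = sub["category"] == label
        sens = (called_high & planted_high).sum() / planted_high.sum()
        print(f"  {sig}: sensitivity for planted High = {sens:.2f}")


if __name__ == "__main__":
    main()
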