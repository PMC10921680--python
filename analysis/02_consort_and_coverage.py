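"""Apply the coverage rules and the CONSORT exclusion cascade.

Datasets are dropped when the 70-gene signature falls below 75% gene
coverage or any recurrence-score non-reference gene is absent; patients are
then filtered by age (>= 70), known ER status, available survival, and
membership in a coverage-passing dataset.  Writes results/02_coverage.tsv
and results/02_consort.json.
"""

import json

import pandas as pd

from sigbench.cohort import apply_consort_filters
from sigbench.pipeline import score_compendium
from sigbench.simulate import generate_compendium
from analysis_config import ANALYSIS_SEED, CONFIG, RESULTS


def main():
    comp = generate_compendium(CONFIG, ANALYSIS_SEED)
    scoring = score_compendium(comp.probe_matrices, comp.clinical, comp.definitions)

    cov = pd.DataFrame(
        [
            {"dataset_id": r.dataset_id, "excluded": r.excluded,
             **{f"coverage_{k}": round(v, 4) for k, v in sorted(r.coverage.items())},
             "reasons": "; ".join(r.reasons)}
            for r in scoring.coverage_reports
        ]
    )
    RESULTS.mkdir(exist_ok=True)
    cov.to_csv(RESULTS / "02_coverage.tsv", sep="\t", index=False)
    med = cov[~cov["excluded"]].filter(like="coverage_").median()
    print("median gene coverage over kept datasets:")
    print(med.round(3).to_string())
    print(f"excluded datasets: {sorted(scoring.excluded_datasets)}")

    cohort, report = apply_consort_filters(comp.clinical, scoring.kept_datasets)
    (RESULTS / "02_consort.json").write_text(
        json.dumps(report.to_dict(), indent=1) + "\n"
    )
    print(report.to_text())


if __name__ == "__main__":
    main()
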