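"""Generate the synthetic compendium and describe its clinical structure.

Writes a cohort-characteristics table (counts and percentages per clinical
variable, over the older stratum that later analyses use) to
results/01_cohort_characteristics.tsv.
"""

import pandas as pd

from sigbench.simulate import generate_compendium
from analysis_config import ANALYSIS_SEED, CONFIG, RESULTS


def main():
    comp = generate_compendium(CONFIG, ANALYSIS_SEED)
    clin = comp.clinical
    older = clin[clin["age"] >= 70]
    print(f"compendium: {CONFIG.n_datasets} datasets, {len(clin)} samples, "
          f"{len(older)} aged >= 70")
    print(f"median age (older stratum): {older['age'].median():.1f} "
          f"(range {older['age'].min():.0f}-{older['age'].max():.0f})")

    rows = []
    def tally(var, series):
        counts = series.value_counts(dropna=False)
        for level, n in counts.items():
            label = "unknown" if pd.isna(level) else str(level)
            rows.append({"variable": var, "level": label,
                         "n": int(n), "pct": round(100 * n / len(series), 1)})

    tally("er", older["er"])
    tally("pr", older["pr"])
    tally("her2", older["her2"])
    tally("nodal", older["nodal"])
    tally("grade", older["grade"])
    size = pd.cut(older["size_cm"], [0, 2, 100], labels=["<2", ">=2"])
    tally("size_cm", size)
    tally("treatment", older["treatment"])

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "01_cohort_characteristics.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"ER+ fraction (older, known ER): "
          f"{(older['er'] == 'pos').sum() / older['er'].isin(['pos', 'neg']).sum():.3f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
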