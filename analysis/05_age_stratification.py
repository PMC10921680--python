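"""Compare signature risk stratification between older and younger cohorts.

χ² tests of independence on the risk-category × age-group table for
ER+/LN− patients aged >= 70 versus 55–65, alongside the ΔLR contrast
between the two windows.  Reads the benchmark tables written by
analysis/04_survival_benchmark.py (run it first).
"""

import pandas as pd

from analysis_config import RESULTS


def main():
    bench = RESULTS / "04_benchmark"
    if not bench.exists():
        raise SystemExit("run analysis/04_survival_benchmark.py first")

    strat = pd.read_csv(bench / "stratification_chi2.tsv", sep="\t")
    print("risk-stratification difference, ER+/LN- older vs 55-65 (chi-square):")
    print(strat.round(3).to_string(index=False))
    sig = strat[strat["p"] < 0.05]["signature_id"].tolist()
    print(f"\nsignatures with stratification differences at alpha=0.05: {sig or 'none'}")

    dlr = pd.read_csv(bench / "delta_lr.tsv", sep="\t")
    both = dlr[dlr["subgroup"].isin(["ER+/LN-", "55-65 ER+/LN-"])]
    piv = both.pivot(index="signature_id", columns="subgroup", values="delta").round(2)
    piv["younger_minus_older"] = (piv["55-65 ER+/LN-"] - piv["ER+/LN-"]).round(2)
    out = RESULTS / "05_age_contrast.tsv"
    piv.to_csv(out, sep="\t")
    print("\ndelta-LR by age window (ER+/LN-):")
    print(piv.to_string())
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
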