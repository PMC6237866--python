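#!/usr/bin/env python
"""Stage 4: regional statistics.

Per-region male-versus-female Welch t-tests, the two configured VOI-level
trait regressions (left amygdala / aggression in females; pooled thalamus /
cooperativeness in all subjects), and the truth-recovery scorecard.
"""

import json
from pathlib import Path

import pandas as pd

from petkin import core
from petkin.regional import sex_difference_tests, voi_trait_regression

RESULTS = Path(__file__).resolve().parents[1] / "results"

LINKS = (("baq_total", "amygdala_L", "F"),
         ("cooperativeness", "thalamus", "all"))


def main() -> None:
    table = pd.read_csv(RESULTS / "regional_bpnd.csv")
    records = core.read_cohort_table(RESULTS / "cohort.csv")

    sex = sex_difference_tests(table)
    sex.to_csv(RESULTS / "sex_differences.csv", index=False)

    rows = []
    for trait, region, sex_filter in LINKS:
        res = voi_trait_regression(table, records, trait, region,
                                   sex_filter=sex_filter)
        rows.append({"trait": trait, "region": region, "sex": sex_filter,
                     "n": res.n, "slope": res.slope, "r2": res.r2,
                     "p": res.p, "direction": res.direction})
    reg = pd.DataFrame(rows)
    reg.to_csv(RESULTS / "trait_regressions.csv", index=False)

    truth = pd.read_csv(RESULTS / "truth_bpnd.csv")
    merged = table.merge(truth, on=["subject", "region"])
    nz = merged[merged["bpnd_truth"] > 0.05]
    rel = (nz["bpnd"] - nz["bpnd_truth"]).abs() / nz["bpnd_truth"]
    recovery = {"n_rows": int(len(nz)),
                "median_rel_err_pct": float(100 * rel.median()),
                "max_rel_err_pct": float(100 * rel.max())}
    with open(RESULTS / "recovery.json", "w") as fh:
        json.dump(recovery, fh, indent=1)

    n_sig = int(sex["significant"].sum())
    print(f"sex tests: {n_sig}/{len(sex)} regions significant at 0.05")
    print(reg.to_string(index=False))
    print("recovery:", json.dumps(recovery))


if __name__ == "__main__":
    main()
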