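"""Sensitivity analyses around the final model.

Compares the final model's discrimination with: a reduced model (the
two strongest predictors), a full model that forces in age, sex,
transfer status and mechanism of injury, a worst-case recoding of early
live discharges as deaths, and a complete-case analysis without
imputation.  Also writes the reduced-model risk matrix over systolic
blood pressure and Glasgow coma scale (the triage heatmap).

Run after 01_simulate_cohort.py:
    python analysis/04_sensitivity_analyses.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from traumatriage import fit_pooled, read_cohort
from traumatriage.modeling import ModelSpec
from traumatriage.pipeline import RunConfig, run_primary, run_sensitivity
from traumatriage.validation import _frozen_scorer

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("-B", "--replicates", type=int, default=50)
    parser.add_argument("--m", default="auto")
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohort.csv")
    config = RunConfig(seed=args.seed,
                       m=args.m if args.m == "auto" else int(args.m),
                       B=args.replicates, m_boot=5)
    primary = run_primary(cohort, config)
    sens = run_sensitivity(cohort, config, primary)

    rows = [{
        "analysis": "final (primary)",
        "auroc": round(primary["performance"]["auroc"].median, 3),
        "iqr": f"{primary['performance']['auroc'].q25:.3f}-"
               f"{primary['performance']['auroc'].q75:.3f}",
        "delong_p_vs_final": "",
    }]
    for name, res in sens.items():
        rows.append({
            "analysis": name,
            "auroc": round(res["auroc"].median, 3),
            "iqr": f"{res['auroc'].q25:.3f}-{res['auroc'].q75:.3f}",
            "delong_p_vs_final": round(res["delong_p_median"], 3),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "sensitivity_analyses.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nreduced model uses: {sens['reduced']['variables']}")
    print(f"complete-case subset: n={sens['complete_case']['n']} of {len(cohort)}")

    # triage heatmap from a refit reduced model (SBP + GCS when those are
    # the two strongest predictors)
    red_spec = ModelSpec.from_dict(sens["reduced"]["spec"])
    red_fit = fit_pooled(primary["stack"], red_spec)
    scorer = _frozen_scorer(red_fit)
    if set(scorer.variables) == {"sbp", "gcs"}:
        grid = scorer.risk_heatmap(np.arange(60.0, 201.0, 5.0),
                                   np.arange(3.0, 16.0))
        grid.round(4).to_csv(RESULTS / "heatmap_reduced_model.csv")
        print("wrote heatmap_reduced_model.csv (risk over SBP x GCS)")
    print("wrote sensitivity_analyses.csv")


if __name__ == "__main__":
    main()
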