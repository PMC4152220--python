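"""Screen functional forms and derive the pooled model.

Reads the simulated cohort, imputes it per hospital (m from the
worst-hospital rule), screens each vital sign with lowess on the
log-odds scale, runs grouped backward selection at the 0.2 level, and
writes the pooled coefficient table (before shrinkage) with grouped
joint Wald p-values and the per-variable knot locations.

Run after 01_simulate_cohort.py:
    python analysis/02_screen_and_fit.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from traumatriage import (backward_select, choose_m, default_full_spec,
                          fit_pooled, lowess_screen, mice_impute, read_cohort)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--m", type=int, default=0, help="0 = worst-hospital rule")
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohort.csv")
    m = args.m or choose_m(cohort)
    print(f"imputing m={m} datasets per hospital ...")
    stack = mice_impute(cohort, m=m, seed=args.seed)

    print("lowess screening (departure-from-linearity index on the log odds;")
    print("advisory only -- the index supports, not replaces, visual assessment):")
    for v in ("sbp", "hr", "gcs"):
        *_, idx = lowess_screen(cohort, v)
        verdict = "curvature flagged" if idx > 0.2 else "compatible with linear"
        print(f"  {v}: {idx:.2f}  ({verdict})")

    spec, trace = backward_select(stack, default_full_spec(), alpha=0.2)
    print("selected model:", ", ".join(t.label() for t in spec.terms))
    fit = fit_pooled(stack, spec)

    table = fit.summary_frame()
    group_p = fit.group_p_values()
    table["group_p"] = [
        next((p for v, p in group_p.items()
              if name in fit.groups.get(v, [])), float("nan"))
        for name in table.index
    ]
    table.round(4).to_csv(RESULTS / "table2_pooled_coefficients.csv")
    knots = {v: list(ks.locations) for v, ks in fit.knots_median.items()}
    with open(RESULTS / "knots.json", "w") as fh:
        json.dump(knots, fh, indent=2)
    with open(RESULTS / "selection_trace.json", "w") as fh:
        json.dump({"m": m, "trace": trace, "selected": spec.to_dict()}, fh,
                  indent=2, default=str)

    print("\npooled coefficients (before shrinkage):")
    print(table.round(3).to_string())
    print("\nknot locations (median across imputed datasets):")
    for v, locs in knots.items():
        print(f"  {v}: {[round(x, 1) for x in locs]}")
    print(f"\nwrote table2_pooled_coefficients.csv, knots.json, selection_trace.json")


if __name__ == "__main__":
    main()
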