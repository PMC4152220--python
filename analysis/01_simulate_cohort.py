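"""Simulate the study cohort.

Draws a synthetic multicentre trauma admission cohort at the study
conditions (n = 1629, three hospitals, ~6% 24-hour mortality, ~2% early
live discharges), imposes hospital-stratified missing-at-random
missingness, and writes the analysis CSV plus a sample-characteristics
table (survivors vs non-survivors, missing-data fractions).

Run:  python analysis/01_simulate_cohort.py [--seed 1] [--n 1629]
"""

import argparse
from pathlib import Path

import pandas as pd

from traumatriage import CohortSpec, generate_cohort, impose_missingness, write_cohort
from traumatriage.imputation import choose_m
from traumatriage.synthetic import incomplete_case_proportions

RESULTS = Path(__file__).resolve().parent.parent / "results"


def characteristics_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    surv, died = df[~df["died_24h"]], df[df["died_24h"]]

    def miqr(s):
        return f"{s.median():.0f} ({s.quantile(.25):.0f}-{s.quantile(.75):.0f})"

    for var, label in [("age", "Age"), ("tti_hours", "Time to arrival (h)"),
                       ("sbp", "Systolic blood pressure"), ("hr", "Heart rate"),
                       ("gcs", "Glasgow coma scale")]:
        rows.append({
            "characteristic": label,
            "survivors": miqr(surv[var].dropna()),
            "non_survivors": miqr(died[var].dropna()),
            "missing_pct": round(100 * df[var].isna().mean(), 1),
        })
    for var, label in [("sex", "Male (%)"), ("transferred", "Transferred (%)")]:
        val = (df[var] == "male") if var == "sex" else df[var]
        rows.append({
            "characteristic": label,
            "survivors": f"{100 * val[~df['died_24h']].mean():.0f}",
            "non_survivors": f"{100 * val[df['died_24h']].mean():.0f}",
            "missing_pct": 0.0,
        })
    return pd.DataFrame(rows)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=1629)
    args = parser.parse_args()

    spec = CohortSpec(n=args.n, seed=args.seed)
    complete = generate_cohort(spec)
    cohort = impose_missingness(complete, spec)
    RESULTS.mkdir(exist_ok=True)
    write_cohort(cohort, RESULTS / "cohort.csv")
    write_cohort(complete, RESULTS / "cohort_complete.csv")

    table1 = characteristics_table(cohort.df)
    table1.to_csv(RESULTS / "table1_sample_characteristics.csv", index=False)

    df = cohort.df
    print(f"simulated {len(df)} admissions across {df.hospital_id.nunique()} hospitals")
    print(f"24-hour mortality: {100 * df.died_24h.mean():.1f}%  "
          f"({int(df.died_24h.sum())} events)")
    print(f"early live discharges: {100 * df.discharged_early.mean():.1f}%")
    per_hosp = incomplete_case_proportions(cohort)
    print("incomplete-case proportion by hospital: "
          + ", ".join(f"{h}: {100 * p:.0f}%" for h, p in per_hosp.items()))
    print(f"imputed datasets required by the worst-hospital rule: {choose_m(cohort)}")
    print(f"wrote {RESULTS / 'cohort.csv'} and table1_sample_characteristics.csv")


if __name__ == "__main__":
    main()
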