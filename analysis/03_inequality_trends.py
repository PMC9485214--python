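#!/usr/bin/env python
"""Summarize mortality inequalities and their trends.

From the stratum-period estimates of 02_estimate_lifetables.py: the
metropolitan-nonmetropolitan absolute and relative inequalities per
race-gender group (2015-2019), the between-race range gaps and how they
moved between the first and last periods (convergence/divergence), and the
correlation between absolute (SD) and relative (CV) lifespan variation.
Writes trend_changes.csv alongside the pipeline's inequality.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from lifegap import measure_correlation, trend_change
from lifegap.inequality import describe_trend_change


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results/analysis/main"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis/inequality"))
    args = parser.parse_args()

    results = pd.read_csv(args.results / "results.csv")
    ineq = pd.read_csv(args.results / "inequality.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    last = ineq.query(
        "measure == 'e0' and period == '2015-2019' and race_ethnicity != 'range'"
    )
    print("Metro-nonmetro inequality in e0, 2015-2019 "
          "(absolute in years, relative as a ratio):")
    print(
        last.pivot_table(
            index="race_ethnicity", columns="gender",
            values=["absolute", "ratio"],
        ).round(2).to_string()
    )

    # between-race range gaps: first vs last period
    ranges = ineq[ineq["race_ethnicity"] == "range"].copy()
    ranges["urbanicity"] = ranges["urbanicity_a"].str.split(":").str[0]
    rows = []
    for (measure, gender, urb), part in ranges.groupby(
        ["measure", "gender", "urbanicity"]
    ):
        part = part.sort_values("period")
        first, final = part.iloc[0], part.iloc[-1]
        change = trend_change(first["absolute"], final["absolute"])
        rows.append(
            {
                "measure": measure,
                "gender": gender,
                "urbanicity": urb,
                "first_period": first["period"],
                "last_period": final["period"],
                "first_gap": first["absolute"],
                "last_gap": final["absolute"],
                "change": change,
                "description": describe_trend_change(
                    round(first["absolute"], 1), round(final["absolute"], 1)
                ),
            }
        )
    trends = pd.DataFrame(rows)
    trends.to_csv(args.out / "trend_changes.csv", index=False)
    print("\nBetween-race range-gap trends (first vs last period):")
    print(trends.query("measure == 'e0'").round(2).to_string(index=False))

    races = results[results["race_ethnicity"] != "ALL"]
    r = measure_correlation(races["sd0"], races["cv0"])
    print(f"\nCorrelation between SD0 and CV0 across "
          f"{len(races)} stratum-periods: r = {r:.3f}")


if __name__ == "__main__":
    main()
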