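"""Behavioural group statistics over the assembled outcome table.

Joins beads draws, IST summaries, discount rates, fitted noise parameters
and the severity covariate into one per-subject table; screens the primary
outcomes for 3-SD outliers per group; then runs the battery: pooled t-tests
on sqrt(beads draws), sqrt(IST boxes) and log10(k), 2x2 mixed ANOVAs on the
secondary IST outcomes, exact Wilcoxon rank-sum on fitted noise, and the
Pearson correlation of beads draws with severity.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reflectim.metrics import group_tests, remove_outliers


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--scores-dir", type=Path, default=Path("results/scores"))
    parser.add_argument("--fit-dir", type=Path, default=Path("results/fit"))
    parser.add_argument("--out", type=Path, default=Path("results/stats.csv"))
    args = parser.parse_args()

    beads = pd.read_csv(args.cohort_dir / "beads.csv")
    table = beads.groupby("subject_id").agg(
        beads_draws_mean=("draws", "mean")).reset_index()
    table["group"] = table["subject_id"].map(
        beads[["subject_id", "group"]].drop_duplicates()
        .set_index("subject_id")["group"])
    table = table.merge(pd.read_csv(args.scores_dir / "ist_summary.csv"),
                        on="subject_id", how="left")
    table = table.merge(pd.read_csv(args.scores_dir / "kirby.csv"),
                        on="subject_id", how="left")
    table = table.merge(
        pd.read_csv(args.fit_dir / "fit_report_excl20.csv")[
            ["subject_id", "map_cs", "map_t", "fit_metric"]],
        on="subject_id", how="left")
    truth = args.cohort_dir / "ground_truth.csv"
    if truth.exists():
        table = table.merge(
            pd.read_csv(truth)[["subject_id", "audit"]], on="subject_id", how="left")

    for col in ("beads_draws_mean", "k_value"):
        by_group = {g: s.set_index("subject_id")[col].dropna()
                    for g, s in table.groupby("group")}
        _, removed = remove_outliers(by_group)
        if removed:
            print(f"outliers removed from {col}: {removed}")
            table.loc[table.subject_id.isin(removed), col] = np.nan

    stats = group_tests(table)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    stats.to_csv(args.out, index=False)
    print(stats.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    for _, row in stats.iterrows():
        if row["test"] in ("t_beads_draws", "wilcoxon_map_t"):
            verdict = "significant" if row["p"] < 0.05 else "not significant"
            print(f"-> {row['test']}: statistic={row['statistic']:.3f}, "
                  f"p={row['p']:.4f} ({verdict} at 0.05)")


if __name__ == "__main__":
    main()
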