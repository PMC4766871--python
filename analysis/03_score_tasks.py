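"""Score the IST trials and the 27-item questionnaire for every subject.

IST: boxes opened, exact P(correct), points under both reward schedules and
the sampling/discrimination error split.  Questionnaire: hyperbolic
discount rate k by maximum choice-pattern agreement, with consistency.
"""

import argparse
from pathlib import Path

import pandas as pd

from reflectim.metrics import ist_subject_summary, kirby_from_frame, score_ist_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ist", type=Path, default=Path("results/cohort/ist.csv"))
    parser.add_argument("--mcq", type=Path, default=Path("results/cohort/mcq.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/scores"))
    args = parser.parse_args()

    args.out_dir.mkdir(parents=True, exist_ok=True)
    ist = pd.read_csv(args.ist)
    scored = score_ist_frame(ist)
    scored.to_csv(args.out_dir / "ist_scores.csv", index=False)
    summary = ist_subject_summary(scored)
    summary.to_csv(args.out_dir / "ist_summary.csv", index=False)
    groups = ist[["subject_id", "group"]].drop_duplicates()
    merged = summary.merge(groups, on="subject_id")
    print("IST boxes opened (mean per group and condition):")
    for col in ("ist_boxes_fixed_win", "ist_boxes_decreasing_win"):
        print(f"  {col}: "
              + ", ".join(f"{g}={v:.2f}" for g, v in
                          merged.groupby("group")[col].mean().items()))

    kirby = kirby_from_frame(pd.read_csv(args.mcq))
    kirby.to_csv(args.out_dir / "kirby.csv", index=False)
    merged_k = kirby.merge(groups, on="subject_id")
    med = merged_k.groupby("group")["k_value"].median()
    print("discount rate k (median per group): "
          + ", ".join(f"{g}={v:.4f}" for g, v in med.items())
          + f"; mean consistency {kirby['consistency'].mean():.3f}")


if __name__ == "__main__":
    main()
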