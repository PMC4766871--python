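"""Fit the hierarchical beads model to the cohort's trial data.

Runs empirical-Bayes EM twice — once on all subjects, once excluding those
who sampled to the 20-bead cap on every trial (a heuristic "always sample"
pattern the valuation model is not meant to describe) — and writes both
per-subject fit reports plus the population hyperparameter trajectories.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from reflectim.fit import exclude_max_draw_subjects, fit_em


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--beads", type=Path, default=Path("results/cohort/beads.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/fit"))
    args = parser.parse_args()

    beads = pd.read_csv(args.beads)
    groups = beads[["subject_id", "group"]].drop_duplicates() \
        .set_index("subject_id")["group"]
    args.out_dir.mkdir(parents=True, exist_ok=True)

    kept, excluded = exclude_max_draw_subjects(beads)
    fits = {"all": fit_em(beads)}
    fits["excl20"] = fit_em(kept) if kept["subject_id"].nunique() >= 2 else fits["all"]

    populations = {}
    for name, fit in fits.items():
        frame = fit.summary_frame()
        frame["group"] = frame["subject_id"].map(groups)
        frame.to_csv(args.out_dir / f"fit_report_{name}.csv", index=False)
        p = fit.population
        populations[name] = dict(cs_mean=p.prior_cs.mean, cs_sd=p.prior_cs.sd,
                                 t_mean=p.prior_t.mean, t_sd=p.prior_t.sd,
                                 iterations=fit.iterations, converged=fit.converged)
        med = frame.groupby("group")["map_t"].median()
        print(f"[{name}] population: cs mean {p.prior_cs.mean:.4f}, "
              f"t mean {p.prior_t.mean:.3f}; median MAP t per group: "
              + ", ".join(f"{g}={v:.3f}" for g, v in med.items())
              + f"; median log prob per action {frame['fit_metric'].median():.3f}")
    print(f"excluded at-cap subjects: {excluded or 'none'}")
    (args.out_dir / "population.json").write_text(json.dumps(populations, indent=2))


if __name__ == "__main__":
    main()
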