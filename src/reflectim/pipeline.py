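"""End-to-end analysis pipeline: data in (or synthesised), statistics out.

Stages, in order: load or synthesise the three task tables -> schema
validation -> per-group 3-SD outlier screening of the behavioural primary
outcomes -> hierarchical fit of the beads model on all subjects -> a
conservative re-fit excluding subjects who sampled to the bead cap on every
trial (both fits are always reported) -> IST and questionnaire scoring ->
transforms and group statistics -> a run report whose record counts
reconcile (loaded = analysed + excluded).

Every output embeds the seed and a hash of the configuration, so a re-run
with the same configuration reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beads import BeadsConfig
from .fit import (FitResult, GridSpec, exclude_max_draw_subjects, fit_em,
                  trials_from_frame)
from .metrics import (group_tests, ist_subject_summary, kirby_from_frame,
                      remove_outliers, score_ist_frame)
from .synth import CohortSpec, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs",
           "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputPaths:
    beads: str
    ist: str | None = None
    mcq: str | None = None
    covariates: str | None = None  # subject_id, group, audit, ...


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: exactly one of ``inputs`` / ``synth`` is set."""

    out_dir: str
    seed: int = 0
    inputs: InputPaths | None = None
    synth: CohortSpec | None = None
    beads: BeadsConfig = field(default_factory=BeadsConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    em_max_iter: int = 200
    em_tol: float = 1e-3
    welch: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ValueError("exactly one of inputs / synth must be given")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how verbosely we log do not change the numbers)."""
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Build a run configuration from a YAML file.

    Nested blocks map onto the corresponding dataclasses; unknown keys are an
    error so typos do not silently fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def build(cls, block):
        if block is None:
            return None
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - names
        if unknown:
            raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**block)

    kwargs = dict(raw)
    kwargs["inputs"] = build(InputPaths, raw.get("inputs"))
    if "synth" in raw:
        synth_raw = dict(raw["synth"] or {})
        for key, sub_cls in (("beads", BeadsConfig),):
            if key in synth_raw:
                synth_raw[key] = build(sub_cls, synth_raw[key])
        kwargs["synth"] = build(CohortSpec, synth_raw)
    for key, cls in (("beads", BeadsConfig), ("grid", GridSpec)):
        if key in raw:
            kwargs[key] = build(cls, raw[key])
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - names
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    return RunConfig(**{k: v for k, v in kwargs.items() if v is not None or k == "inputs"})


@dataclass
class RunReport:
    seed: int
    config_hash: str
    counts: dict
    population_all: dict
    population_excl20: dict
    excluded_20draw_subjects: list[str]
    outlier_subjects: dict
    stats: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def validate_inputs(
    beads: pd.DataFrame,
    ist: pd.DataFrame | None = None,
    mcq: pd.DataFrame | None = None,
    config: BeadsConfig | None = None,
) -> list[dict]:
    """Schema / range / cross-table checks; returns machine-readable
    diagnostics (empty list = clean)."""
    config = config or BeadsConfig()
    diags: list[dict] = []

    required = {"subject_id", "group", "trial_index", "sequence", "draws", "declared"}
    missing = required - set(beads.columns)
    if missing:
        diags.append(dict(table="beads", row=None, problem=f"missing columns {sorted(missing)}"))
        return diags
    for idx, row in beads.iterrows():
        if not 1 <= int(row["draws"]) <= config.d_max:
            diags.append(dict(table="beads", row=int(idx),
                              problem=f"draws {row['draws']} outside 1..{config.d_max}"))
        if len(str(row["sequence"])) < int(row["draws"]):
            diags.append(dict(table="beads", row=int(idx),
                              problem="sequence shorter than draws"))
        if str(row["declared"]) not in ("A", "B"):
            diags.append(dict(table="beads", row=int(idx),
                              problem=f"declared {row['declared']!r} not in A/B"))

    beads_subjects = set(beads["subject_id"].astype(str))
    for name, frame in (("ist", ist), ("mcq", mcq)):
        if frame is None:
            continue
        subjects = set(frame["subject_id"].astype(str))
        for sid in sorted(beads_subjects - subjects):
            diags.append(dict(table=name, row=None,
                              problem=f"subject {sid} present in beads but missing here"))
        if name == "ist":
            for idx, row in frame.iterrows():
                cells = str(row["opened"]).split(";")
                if len(cells) != len(set(cells)):
                    diags.append(dict(table="ist", row=int(idx),
                                      problem="repeated opened cells"))
    return diags


def _population_dict(fit: FitResult) -> dict:
    p = fit.population
    return dict(
        cs_shape=p.prior_cs.shape, cs_rate=p.prior_cs.rate, cs_mean=p.prior_cs.mean,
        t_shape=p.prior_t.shape, t_rate=p.prior_t.rate, t_mean=p.prior_t.mean,
        converged=fit.converged, iterations=fit.iterations,
        path=[dict(cs_shape=m.prior_cs.shape, cs_rate=m.prior_cs.rate,
                   t_shape=m.prior_t.shape, t_rate=m.prior_t.rate)
              for m in fit.population_path],
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write the report files under ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load or synthesise -------------------------------------------------
    covariates = None
    if config.synth is not None:
        spec = dataclasses.replace(config.synth, seed=config.seed)
        cohort = generate_cohort(spec)
        beads, ist, mcq = cohort.beads, cohort.ist, cohort.mcq
        covariates = cohort.ground_truth[["subject_id", "group", "audit"]]
        cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        beads_config = spec.beads
    else:
        paths = config.inputs
        beads = pd.read_csv(paths.beads)
        ist = pd.read_csv(paths.ist) if paths.ist else None
        mcq = pd.read_csv(paths.mcq) if paths.mcq else None
        if paths.covariates:
            covariates = pd.read_csv(paths.covariates)
        beads_config = config.beads
    logger.info("loaded %d beads trials, %d subjects", len(beads),
                beads["subject_id"].nunique())

    # --- validate -----------------------------------------------------------
    diags = validate_inputs(beads, ist, mcq, beads_config)
    if diags:
        raise ValueError(f"input validation failed: {diags[:5]} (stage: validate)")

    groups = beads[["subject_id", "group"]].drop_duplicates().set_index("subject_id")["group"]

    # --- behavioural outcome table -----------------------------------------
    table = (
        beads.groupby("subject_id")
        .agg(beads_draws_mean=("draws", "mean"))
        .reset_index()
    )
    table["group"] = table["subject_id"].map(groups)
    if ist is not None:
        scored = score_ist_frame(ist)
        scored.to_csv(out / "ist_scores.csv", index=False)
        table = table.merge(ist_subject_summary(scored), on="subject_id", how="left")
        table = table.rename(columns={"ist_boxes_fixed_win": "ist_boxes_fixed_win"})
    if mcq is not None:
        kirby = kirby_from_frame(mcq)
        kirby.to_csv(out / "kirby.csv", index=False)
        table = table.merge(kirby, on="subject_id", how="left")
    if covariates is not None:
        table = table.merge(
            covariates.drop(columns=[c for c in ("group",) if c in covariates]),
            on="subject_id", how="left",
        )

    # --- outlier screening of primary outcomes ------------------------------
    outliers: dict[str, list] = {}
    for col in ("beads_draws_mean", "k_value"):
        if col not in table.columns:
            continue
        by_group = {
            g: sub.set_index("subject_id")[col].dropna()
            for g, sub in table.groupby("group")
        }
        _, removed = remove_outliers(by_group)
        outliers[col] = sorted(map(str, removed))
        table.loc[table["subject_id"].astype(str).isin(outliers[col]), col] = np.nan
    logger.info("outliers removed per outcome: %s",
                {k: len(v) for k, v in outliers.items()})

    # --- hierarchical model fits: all subjects, then 20-draws excluded ------
    fit_all = fit_em(beads, beads_config, grid=config.grid,
                     max_iter=config.em_max_iter, tol=config.em_tol)
    kept, excluded_ids = exclude_max_draw_subjects(beads, beads_config)
    if kept["subject_id"].nunique() >= 2:
        fit_excl = fit_em(kept, beads_config, grid=config.grid,
                          max_iter=config.em_max_iter, tol=config.em_tol)
    else:
        fit_excl = fit_all
    for fit, name in ((fit_all, "fit_report_all"), (fit_excl, "fit_report_excl20")):
        frame = fit.summary_frame()
        frame["group"] = frame["subject_id"].map(groups)
        frame["seed"] = config.seed
        frame["config_hash"] = config.config_hash()
        frame.to_csv(out / f"{name}.csv", index=False)
    (out / "population.json").write_text(json.dumps(
        dict(seed=config.seed, config_hash=config.config_hash(),
             all=_population_dict(fit_all), excl20=_population_dict(fit_excl)),
        indent=2))

    # the conservative (20-draws-excluded) fit feeds the group contrast
    table = table.merge(
        fit_excl.summary_frame()[["subject_id", "map_cs", "map_t", "fit_metric"]],
        on="subject_id", how="left",
    )
    table["seed"] = config.seed
    table.to_csv(out / "group_table.csv", index=False)

    # --- group statistics ---------------------------------------------------
    stats_frame = group_tests(table, welch=config.welch)
    stats_frame["seed"] = config.seed
    stats_frame["config_hash"] = config.config_hash()
    stats_frame.to_csv(out / "stats.csv", index=False)

    n_loaded = int(beads["subject_id"].nunique())
    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        counts=dict(
            subjects_loaded=n_loaded,
            beads_trials=len(beads),
            excluded_20draws=len(excluded_ids),
            analysed_excl20=n_loaded - len(excluded_ids),
            outliers={k: len(v) for k, v in outliers.items()},
        ),
        population_all=_population_dict(fit_all),
        population_excl20=_population_dict(fit_excl),
        excluded_20draw_subjects=excluded_ids,
        outlier_subjects=outliers,
        stats=stats_frame.drop(columns=["config_hash"]).to_dict("records"),
    )
    (out / "run_report.json").write_text(report.to_json())
    return report
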