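"""Synthetic two-group cohorts with known ground truth.

Emulates a healthy-volunteer (HV) vs binge-drinker (BD) design: each
subject's beads-task behaviour is generated from the ideal-observer-with-
noise model with (cs, t) drawn from group-specific gamma distributions (BD:
higher-mean, more variable noise; cost of sampling small in both groups);
IST behaviour from a threshold agent that keeps opening boxes until the
opened-colour margin reaches a subject-specific threshold (lowered under the
decreasing-win schedule by a cost-sensitivity offset); and questionnaire
choices from a hyperbolic discounter with logistic choice noise.  A severity
covariate (AUDIT-like score) is drawn per group with a configurable
correlation to the subject's log noise parameter.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .beads import BeadsConfig, SubjectParams, build_value_table, simulate_trial
from .fit import GammaPrior, PopulationModel
from .metrics import (GRID_SIZE, ISTTrial, MCQItem, N_CELLS, load_mcq_items,
                      score_ist_trial)

__all__ = ["GroupHyperParams", "ISTAgentSpec", "MCQAgentSpec", "CohortSpec",
           "SyntheticCohort", "generate_cohort", "generate_fixture_suite"]

IST_COLOURS = ("R", "B")


@dataclass(frozen=True)
class GroupHyperParams:
    """Gamma hyperparameters over (cs, t) for one group, mean/SD form."""

    cs_mean: float = 0.02
    cs_sd: float = 0.01
    t_mean: float = 0.25
    t_sd: float = 0.12

    def population(self) -> PopulationModel:
        return PopulationModel(
            prior_cs=GammaPrior.from_mean_sd(self.cs_mean, self.cs_sd),
            prior_t=GammaPrior.from_mean_sd(self.t_mean, self.t_sd),
        )


@dataclass(frozen=True)
class ISTAgentSpec:
    """Margin-threshold box-opening agent.

    The subject's base threshold is drawn from a normal (rounded, clipped to
    [1, 12]); under the decreasing-win schedule it drops by
    ``cost_sensitivity`` boxes (floor 1), producing earlier decisions when
    sampling is penalised.
    """

    threshold_mean: float = 5.0
    threshold_sd: float = 2.0
    cost_sensitivity: float = 2.0
    trials_per_condition: int = 10


@dataclass(frozen=True)
class MCQAgentSpec:
    """Hyperbolic discounter: log k ~ Normal(log k_median, sigma); choices
    are logistic in the value difference with temperature ``tau`` (currency
    units); ``tau = 0`` is the deterministic chooser."""

    log_k_median: float = float(np.log(0.01))
    log_k_sigma: float = 1.0
    tau: float = 2.0


@dataclass(frozen=True)
class SeveritySpec:
    """AUDIT-like severity covariate per group, correlated with log noise."""

    mean: float
    sd: float
    corr_with_log_t: float = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Complete description of a synthetic two-group study."""

    n_hv: int = 30
    n_bd: int = 30
    trials_per_subject: int = 3
    beads: BeadsConfig = field(default_factory=BeadsConfig)
    hv: GroupHyperParams = field(default_factory=GroupHyperParams)
    bd: GroupHyperParams = field(
        default_factory=lambda: GroupHyperParams(t_mean=0.6, t_sd=0.35)
    )
    ist_hv: ISTAgentSpec = field(default_factory=ISTAgentSpec)
    ist_bd: ISTAgentSpec = field(default_factory=ISTAgentSpec)
    mcq_hv: MCQAgentSpec = field(default_factory=MCQAgentSpec)
    mcq_bd: MCQAgentSpec = field(default_factory=MCQAgentSpec)
    severity_hv: SeveritySpec = field(default_factory=lambda: SeveritySpec(4.0, 2.8))
    severity_bd: SeveritySpec = field(default_factory=lambda: SeveritySpec(15.5, 5.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hv < 2 or self.n_bd < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")


@dataclass
class SyntheticCohort:
    """Generated dataset: one row per beads trial / IST trial / MCQ response,
    with ground-truth parameters aligned by subject id."""

    beads: pd.DataFrame
    ist: pd.DataFrame
    mcq: pd.DataFrame
    ground_truth: pd.DataFrame
    spec: CohortSpec


def _make_board(rng: np.random.Generator) -> str:
    """5x5 two-colour board with a majority count uniform on 13..17."""
    majority_n = int(rng.integers(13, 18))
    majority_colour = IST_COLOURS[int(rng.integers(2))]
    minority_colour = IST_COLOURS[1] if majority_colour == IST_COLOURS[0] else IST_COLOURS[0]
    cells = [majority_colour] * majority_n + [minority_colour] * (N_CELLS - majority_n)
    rng.shuffle(cells)
    return "".join(cells)


def _ist_agent_trial(
    rng: np.random.Generator, threshold: int, condition: str
) -> ISTTrial:
    grid = _make_board(rng)
    order = rng.permutation(N_CELLS)
    counts = {c: 0 for c in IST_COLOURS}
    opened: list[tuple[int, int]] = []
    for idx in order:
        r, c = divmod(int(idx), GRID_SIZE)
        opened.append((r, c))
        counts[grid[idx]] += 1
        if abs(counts[IST_COLOURS[0]] - counts[IST_COLOURS[1]]) >= threshold:
            break
    a, b = IST_COLOURS
    choice = a if counts[a] > counts[b] else b
    return ISTTrial(grid=grid, opened=tuple(opened), choice=choice, condition=condition)


def _mcq_choices(
    rng: np.random.Generator, k: float, tau: float, items: list[MCQItem]
) -> list[str]:
    out = []
    for it in items:
        v_imm = it.immediate_amount
        v_del = it.delayed_amount / (1.0 + k * it.delay_days)
        if tau <= 0:
            imm = v_imm > v_del
        else:
            p_imm = 1.0 / (1.0 + np.exp(-(v_imm - v_del) / tau))
            imm = rng.random() < p_imm
        out.append("immediate" if imm else "delayed")
    return out


def _threshold(rng: np.random.Generator, spec: ISTAgentSpec, condition: str) -> int:
    base = rng.normal(spec.threshold_mean, spec.threshold_sd)
    if condition == "decreasing_win":
        base -= spec.cost_sensitivity
    return int(np.clip(round(base), 1, 12))


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a full two-group cohort (beads + IST + MCQ + ground truth)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    items = load_mcq_items()

    beads_rows, ist_rows, mcq_rows, truth_rows = [], [], [], []
    groups = [("HV", spec.n_hv, spec.hv, spec.ist_hv, spec.mcq_hv, spec.severity_hv),
              ("BD", spec.n_bd, spec.bd, spec.ist_bd, spec.mcq_bd, spec.severity_bd)]
    for group, n, hyper, ist_spec, mcq_spec, sev_spec in groups:
        pop = hyper.population()
        # severity correlated with log t through a shared standard normal
        z_shared = rng.standard_normal(n)
        z_noise = rng.standard_normal(n)
        t_vals = gamma_ppf_from_z(z_shared, pop.prior_t)
        cs_vals = rng.gamma(pop.prior_cs.shape, 1.0 / pop.prior_cs.rate, size=n)
        rho = sev_spec.corr_with_log_t
        audit = sev_spec.mean + sev_spec.sd * (
            rho * z_shared + np.sqrt(1.0 - rho ** 2) * z_noise
        )
        audit = np.clip(np.round(audit, 1), 0.0, None)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            params = SubjectParams(cs=float(cs_vals[i]), t=float(t_vals[i]))
            table = build_value_table(params, spec.beads)
            for trial_index in range(spec.trials_per_subject):
                true_jar = "A" if rng.random() < 0.5 else "B"
                trial = simulate_trial(params, spec.beads, true_jar, rng, table=table)
                beads_rows.append(dict(
                    subject_id=sid, group=group, trial_index=trial_index,
                    sequence=trial.sequence, draws=trial.draws,
                    declared=trial.declared, true_jar=true_jar,
                    confidence=round(float(rng.beta(5, 2)), 3),
                ))
            thresholds = {}
            for condition in ("fixed_win", "decreasing_win"):
                thr = _threshold(rng, ist_spec, condition)
                thresholds[condition] = thr
                for trial_index in range(ist_spec.trials_per_condition):
                    ist_trial = _ist_agent_trial(rng, thr, condition)
                    ist_rows.append(dict(
                        subject_id=sid, group=group, trial_index=trial_index,
                        condition=condition, grid=ist_trial.grid,
                        opened=";".join(f"{r},{c}" for r, c in ist_trial.opened),
                        choice=ist_trial.choice,
                    ))
            k = float(np.exp(rng.normal(mcq_spec.log_k_median, mcq_spec.log_k_sigma)))
            for it, choice in zip(items, _mcq_choices(rng, k, mcq_spec.tau, items)):
                mcq_rows.append(dict(subject_id=sid, group=group,
                                     item_id=it.item_id, choice=choice))
            truth_rows.append(dict(
                subject_id=sid, group=group, cs=params.cs, t=params.t,
                ist_threshold_fixed=thresholds["fixed_win"],
                ist_threshold_decreasing=thresholds["decreasing_win"],
                k=k, audit=float(audit[i]),
            ))
    return SyntheticCohort(
        beads=pd.DataFrame(beads_rows),
        ist=pd.DataFrame(ist_rows),
        mcq=pd.DataFrame(mcq_rows),
        ground_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def gamma_ppf_from_z(z: np.ndarray, prior: GammaPrior) -> np.ndarray:
    """Map standard normal draws through the gamma quantile function
    (Gaussian copula), preserving rank correlation with the normal draws."""
    from scipy.stats import gamma as gamma_dist, norm

    u = norm.cdf(z)
    return gamma_dist.ppf(u, a=prior.shape, scale=1.0 / prior.rate)


def generate_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict:
    """Write a small seeded cohort plus expected scoring outputs for
    regression tests; returns the file manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(
        n_hv=6, n_bd=6, trials_per_subject=3,
        ist_hv=ISTAgentSpec(trials_per_condition=2),
        ist_bd=ISTAgentSpec(trials_per_condition=2),
        seed=seed,
    )
    cohort = generate_cohort(spec)

    from .metrics import ist_trials_from_frame  # local import: cycle-free

    expected_ist = []
    for row, trial in zip(cohort.ist.itertuples(index=False),
                          ist_trials_from_frame(cohort.ist)):
        score = score_ist_trial(trial)
        expected_ist.append(dict(
            subject_id=row.subject_id, trial_index=row.trial_index,
            condition=row.condition, boxes_opened=score.boxes_opened,
            p_correct=score.p_correct, points=score.points,
            correct=score.correct, error_type=score.error_type,
        ))
    files = {
        "beads.csv": cohort.beads,
        "ist.csv": cohort.ist,
        "mcq.csv": cohort.mcq,
        "ground_truth.csv": cohort.ground_truth,
        "expected_ist_scores.csv": pd.DataFrame(expected_ist),
    }
    manifest = {"seed": seed, "files": sorted(files), "n_hv": spec.n_hv,
                "n_bd": spec.n_bd}
    for name, frame in files.items():
        frame.to_csv(out / name, index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["files"].append("manifest.json")
    manifest["files"].sort()
    return manifest
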