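"""Hierarchical empirical-Bayes fitting of (cs, t) across a cohort.

Subjects' cost-of-sampling and cognitive-noise parameters are assumed drawn
from population gamma distributions.  Fitting alternates:

* E-step — each subject's posterior over (cs, t) is evaluated on a fixed
  log-spaced grid (log joint = log gamma priors + summed trial log
  likelihoods; posterior masses include the trapezoid cell measure so grid
  expectations are proper quadrature approximations of posterior moments);
* M-step — the gamma hyperparameters are re-estimated by maximum likelihood
  from the posterior-weighted first moments and mean logs (digamma equation
  solved by safeguarded root finding, with moment matching as a fallback for
  degenerate posteriors).

The per-subject model fit is summarised as log probability per action (nats
per decision point) at the MAP parameters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, logsumexp
from scipy.stats import gamma as gamma_dist

from .beads import BeadsConfig, BeadsTrial, _prefix_state, _solve_lattice

__all__ = [
    "GammaPrior",
    "PopulationModel",
    "GridSpec",
    "SubjectPosterior",
    "FitResult",
    "subject_e_step",
    "m_step",
    "fit_em",
    "exclude_max_draw_subjects",
    "trials_from_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma distribution in shape/rate form (mean = shape / rate)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError(f"gamma shape and rate must be > 0, got {self}")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) / self.rate

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float) -> "GammaPrior":
        shape = (mean / sd) ** 2
        return cls(shape=shape, rate=shape / mean)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return gamma_dist.logpdf(x, a=self.shape, scale=1.0 / self.rate)


@dataclass(frozen=True)
class PopulationModel:
    """Population gamma hyperpriors over cost-of-sampling and noise."""

    prior_cs: GammaPrior
    prior_t: GammaPrior


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced E-step grid over (cs, t)."""

    cs_min: float = 1e-4
    cs_max: float = 0.5
    n_cs: int = 40
    t_min: float = 0.01
    t_max: float = 5.0
    n_t: int = 40

    def __post_init__(self) -> None:
        if self.cs_min <= 0 or self.t_min <= 0:
            raise ValueError("grid nodes must be strictly positive")
        if self.cs_max <= self.cs_min or self.t_max <= self.t_min:
            raise ValueError("grid bounds must be increasing")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        cs = np.geomspace(self.cs_min, self.cs_max, self.n_cs)
        t = np.geomspace(self.t_min, self.t_max, self.n_t)
        return cs, t

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened meshgrid (cs varies slowest)."""
        cs, t = self.axes()
        cc, tt = np.meshgrid(cs, t, indexing="ij")
        return cc.ravel(), tt.ravel()

    def log_measure(self) -> np.ndarray:
        """Log trapezoid cell widths, flattened like :meth:`points`."""
        cs, t = self.axes()
        return (np.log(_trapezoid_widths(cs))[:, None]
                + np.log(_trapezoid_widths(t))[None, :]).ravel()


def _trapezoid_widths(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    return w


@dataclass
class SubjectPosterior:
    """Grid posterior over (cs, t) for one subject."""

    subject_id: str
    cs_grid: np.ndarray
    t_grid: np.ndarray
    log_joint: np.ndarray  # log prior + log likelihood at each grid point
    weights: np.ndarray    # normalised posterior masses (incl. cell measure)
    map_cs: float
    map_t: float
    subject_loglik: float  # summed trial log likelihood at the MAP point
    n_actions: int

    @property
    def map_estimate(self) -> tuple[float, float]:
        return self.map_cs, self.map_t

    @property
    def fit_metric(self) -> float:
        """Log probability per action (decision point), nats."""
        return self.subject_loglik / self.n_actions

    def posterior_mean(self) -> tuple[float, float]:
        return float(self.weights @ self.cs_grid), float(self.weights @ self.t_grid)


@dataclass
class FitResult:
    population: PopulationModel
    population_path: list[PopulationModel]
    subjects: list[SubjectPosterior]
    converged: bool
    iterations: int
    objective_path: list[float]  # log marginal likelihood of the hyperparameters

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            pm_cs, pm_t = s.posterior_mean()
            rows.append(
                dict(
                    subject_id=s.subject_id,
                    map_cs=s.map_cs,
                    map_t=s.map_t,
                    post_mean_cs=pm_cs,
                    post_mean_t=pm_t,
                    subject_loglik=s.subject_loglik,
                    n_actions=s.n_actions,
                    fit_metric=s.fit_metric,
                )
            )
        return pd.DataFrame(rows)


def trials_from_frame(frame: pd.DataFrame) -> dict[str, list[BeadsTrial]]:
    """Group a beads-trial table (CSV schema) into per-subject trial lists."""
    out: dict[str, list[BeadsTrial]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            BeadsTrial(
                sequence=row.sequence,
                draws=int(row.draws),
                declared=str(row.declared),
                true_jar=getattr(row, "true_jar", None),
            )
        )
    return out


def _grid_logliks(
    subjects: dict[str, list[BeadsTrial]], grid: GridSpec, config: BeadsConfig
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[str, int]]:
    """Summed trial log likelihood of every subject at every grid point.

    The belief-lattice solution is computed once, vectorised over all grid
    points, and reused across subjects; this is the expensive step of the fit
    and is independent of the hyperparameters, so EM iterations are cheap.
    """
    cs, t = grid.points()
    log_pi, _, _ = _solve_lattice(cs, t, config)

    # log policy lookups per (depth, n_a, action) are shared across subjects
    logliks: dict[str, np.ndarray] = {}
    n_actions: dict[str, int] = {}
    for sid, trials in subjects.items():
        total = np.zeros(len(cs))
        n_act = 0
        for trial in trials:
            if trial.draws > config.d_max:
                raise ValueError(
                    f"subject {sid}: draws {trial.draws} exceeds cap {config.d_max}"
                )
            for k in range(1, trial.draws + 1):
                st = _prefix_state(trial.sequence, k)
                if k < trial.draws:
                    a = 0
                elif trial.declared == "A":
                    a = 1
                else:
                    a = 2
                total = total + log_pi[k][:, st.n_a, a]
            n_act += trial.draws
        logliks[sid] = total
        n_actions[sid] = n_act
    return cs, t, logliks, n_actions


def _e_step_from_loglik(
    sid: str,
    cs: np.ndarray,
    t: np.ndarray,
    log_measure: np.ndarray,
    loglik: np.ndarray,
    n_actions: int,
    population: PopulationModel,
) -> SubjectPosterior:
    log_prior = population.prior_cs.logpdf(cs) + population.prior_t.logpdf(t)
    log_joint = log_prior + loglik
    log_mass = log_joint + log_measure
    weights = np.exp(log_mass - logsumexp(log_mass))
    # MAP on the density log-joint; ties to smallest cs then smallest t
    best = np.flatnonzero(log_joint >= log_joint.max() - 1e-12)
    order = np.lexsort((t[best], cs[best]))
    idx = best[order[0]]
    return SubjectPosterior(
        subject_id=sid,
        cs_grid=cs,
        t_grid=t,
        log_joint=log_joint,
        weights=weights,
        map_cs=float(cs[idx]),
        map_t=float(t[idx]),
        subject_loglik=float(loglik[idx]),
        n_actions=n_actions,
    )


def subject_e_step(
    trials: list[BeadsTrial],
    population: PopulationModel,
    config: BeadsConfig,
    grid: GridSpec | None = None,
    subject_id: str = "subject",
) -> SubjectPosterior:
    """Posterior over (cs, t) for one subject on the E-step grid."""
    if not trials:
        raise ValueError("subject has no trials")
    grid = grid or GridSpec()
    cs, t, logliks, n_actions = _grid_logliks({subject_id: trials}, grid, config)
    return _e_step_from_loglik(
        subject_id, cs, t, grid.log_measure(), logliks[subject_id],
        n_actions[subject_id], population,
    )


def _gamma_mle(m1: float, mean_log: float) -> GammaPrior:
    """Gamma MLE from the sufficient statistics E[x] and E[log x].

    Solves log(shape) - digamma(shape) = log(m1) - mean_log on a bracketing
    interval; falls back to a near-degenerate large-shape solution when the
    statistics are (numerically) inconsistent with a proper gamma.
    """
    s = math.log(m1) - mean_log
    if not np.isfinite(s) or s <= 1e-12:
        # all mass effectively on one point: variance ~ 0
        shape = 1e6
        return GammaPrior(shape=shape, rate=shape / m1)
    # standard closed-form initialisation brackets the root well
    f = lambda a: math.log(a) - digamma(a) - s
    lo, hi = 1e-8, 1e8
    if f(lo) < 0 or f(hi) > 0:  # root outside safeguard range
        shape = (3 - s + math.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    else:
        shape = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return GammaPrior(shape=shape, rate=shape / m1)


def m_step(subjects: list[SubjectPosterior]) -> PopulationModel:
    """Re-estimate the population gamma hyperparameters from the E-step.

    Uses each subject's posterior-weighted first moment and mean log of cs
    and t, averaged across subjects, as the gamma sufficient statistics.
    """
    if len(subjects) < 2:
        raise ValueError("population update needs at least 2 subjects")
    priors = []
    for grid_attr in ("cs_grid", "t_grid"):
        m1s, mlogs = [], []
        for s in subjects:
            x = getattr(s, grid_attr)
            m1s.append(float(s.weights @ x))
            mlogs.append(float(s.weights @ np.log(x)))
        m1 = float(np.mean(m1s))
        mean_log = float(np.mean(mlogs))
        try:
            priors.append(_gamma_mle(m1, mean_log))
        except (ValueError, RuntimeError):
            var = float(np.var(m1s)) or m1 ** 2 * 1e-6
            logger.warning("gamma MLE failed for %s; moment matching", grid_attr)
            priors.append(GammaPrior(shape=m1 ** 2 / var, rate=m1 / var))
    return PopulationModel(prior_cs=priors[0], prior_t=priors[1])


def _log_marginal(
    log_prior: np.ndarray, log_measure: np.ndarray, logliks: dict[str, np.ndarray]
) -> float:
    return float(sum(logsumexp(log_prior + ll + log_measure) for ll in logliks.values()))


def fit_em(
    cohort: pd.DataFrame | dict[str, list[BeadsTrial]],
    config: BeadsConfig | None = None,
    init: PopulationModel | None = None,
    grid: GridSpec | None = None,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> FitResult:
    """Fit the population model to a cohort by expectation maximisation.

    ``cohort`` is either a beads-trial table (CSV schema) or a mapping from
    subject id to trial list.  Hyperparameters are updated until the relative
    change in all four (shape, rate) components drops below ``tol`` or
    ``max_iter`` is reached; non-convergence is flagged, not raised.
    """
    config = config or BeadsConfig()
    grid = grid or GridSpec()
    init = init or PopulationModel(
        prior_cs=GammaPrior.from_mean_sd(0.05, 0.05 / math.sqrt(2)),  # shape 2
        prior_t=GammaPrior.from_mean_sd(0.5, 0.5 / math.sqrt(2)),
    )
    subjects_trials = (
        trials_from_frame(cohort) if isinstance(cohort, pd.DataFrame) else cohort
    )
    if not subjects_trials:
        raise ValueError("empty cohort")
    for sid, trials in subjects_trials.items():
        if not trials:
            raise ValueError(f"subject {sid} has no trials")

    cs, t, logliks, n_actions = _grid_logliks(subjects_trials, grid, config)
    log_measure = grid.log_measure()
    sids = list(subjects_trials)
    L = np.stack([logliks[sid] for sid in sids])  # (subjects, grid)
    log_x = np.stack([np.log(cs), np.log(t)])

    population = init
    path = [population]
    objective: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        log_prior = population.prior_cs.logpdf(cs) + population.prior_t.logpdf(t)
        log_mass = L + (log_prior + log_measure)[None, :]
        norm = logsumexp(log_mass, axis=1)
        objective.append(float(norm.sum()))
        weights = np.exp(log_mass - norm[:, None])
        # vectorised M-step: gamma MLE from mean posterior moments
        new_priors = []
        for x, lx in ((cs, log_x[0]), (t, log_x[1])):
            m1 = float((weights @ x).mean())
            mean_log = float((weights @ lx).mean())
            new_priors.append(_gamma_mle(m1, mean_log))
        new_pop = PopulationModel(prior_cs=new_priors[0], prior_t=new_priors[1])
        old = np.array([population.prior_cs.shape, population.prior_cs.rate,
                        population.prior_t.shape, population.prior_t.rate])
        new = np.array([new_pop.prior_cs.shape, new_pop.prior_cs.rate,
                        new_pop.prior_t.shape, new_pop.prior_t.rate])
        population = new_pop
        path.append(population)
        if np.all(np.abs(new - old) / np.abs(old) < tol):
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    # final E-step under the last hyperparameters so posteriors match them
    log_prior = population.prior_cs.logpdf(cs) + population.prior_t.logpdf(t)
    posteriors = [
        _e_step_from_loglik(sid, cs, t, log_measure, logliks[sid],
                            n_actions[sid], population)
        for sid in subjects_trials
    ]
    objective.append(_log_marginal(log_prior, log_measure, logliks))
    return FitResult(
        population=population,
        population_path=path,
        subjects=posteriors,
        converged=converged,
        iterations=iteration,
        objective_path=objective,
    )


def exclude_max_draw_subjects(
    cohort: pd.DataFrame, config: BeadsConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Split off subjects who sampled to the bead cap on every trial.

    Deciding only at the forced horizon is consistent with a simple
    "always sample" heuristic rather than look-ahead valuation, so the fit is
    conservatively re-run without these subjects.
    """
    config = config or BeadsConfig()
    if cohort.empty:
        return cohort.copy(), []
    at_cap = cohort.groupby("subject_id")["draws"].apply(
        lambda d: bool((d == config.d_max).all())
    )
    excluded = sorted(str(s) for s in at_cap[at_cap].index)
    kept = cohort[~cohort["subject_id"].astype(str).isin(excluded)].copy()
    return kept, excluded
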