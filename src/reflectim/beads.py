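"""Ideal-Bayesian-observer model of the beads task with sampling cost and noise.

The beads task presents beads drawn from one of two jars with complementary
colour ratios (majority proportion ``q``, default 0.80).  After each bead the
participant either draws another bead or declares a jar, up to a cap of
``d_max`` beads.  The model treats the participant as a Bayesian observer who
values actions by backward induction over the belief lattice: declaring pays
the probability of being correct (on a unit reward scale), sampling costs
``cs`` per bead and yields the expected value of the successor belief state.
Choice is a softmax in the action values with temperature ``t`` ("cognitive
noise"), which controls both choice consistency and how strongly distant
future outcomes propagate into present value (the propagated state value is
the policy-weighted action value, so high noise attenuates look-ahead).

The ``t = 0`` limit is the deterministic ideal observer; ties there are broken
by ``BeadsConfig.tie_break``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BeadsConfig",
    "BeliefState",
    "SubjectParams",
    "ActionValues",
    "BeadsTrial",
    "ValueTable",
    "posterior_a",
    "predictive_next",
    "build_value_table",
    "policy_at",
    "trial_loglik",
    "simulate_trial",
]

#: Absolute tolerance used to detect value ties in the deterministic (t = 0)
#: mode.  The zero-cost sample-vs-declare tie is exact only in real
#: arithmetic; float rounding would otherwise break it arbitrarily.
_TIE_ATOL = 1e-9

_ACTIONS = ("sample", "declare_a", "declare_b")


@dataclass(frozen=True)
class BeadsConfig:
    """Task environment for the beads task.

    Parameters
    ----------
    q:
        Majority-colour proportion of each jar (Jar A is mostly colour A).
    d_max:
        Maximum number of beads that may be viewed.
    reward_correct, reward_incorrect:
        Utilities of a correct / incorrect declaration.  The default unit
        scale (1, 0) makes ``cs`` and ``t`` dimensionless fractions of the
        declaration reward.
    prior_a:
        Prior probability that the beads come from Jar A.
    tie_break:
        How exact value ties are resolved in the deterministic (t = 0) mode.
    value_rule:
        How state value is propagated: ``"softmax_expectation"`` (policy
        weighted action value; default) or ``"logsumexp"``
        (t * logsumexp(Q / t)).
    """

    q: float = 0.80
    d_max: int = 20
    reward_correct: float = 1.0
    reward_incorrect: float = 0.0
    prior_a: float = 0.5
    tie_break: str = "prefer_sample"
    value_rule: str = "softmax_expectation"

    def __post_init__(self) -> None:
        if not 0.5 < self.q < 1.0:
            raise ValueError(f"q must lie in (0.5, 1), got {self.q}")
        if self.d_max < 1:
            raise ValueError(f"d_max must be >= 1, got {self.d_max}")
        if not self.reward_correct > self.reward_incorrect:
            raise ValueError("reward_correct must exceed reward_incorrect")
        if not 0.0 < self.prior_a < 1.0:
            raise ValueError(f"prior_a must lie in (0, 1), got {self.prior_a}")
        if self.tie_break not in ("prefer_sample", "prefer_declare"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.value_rule not in ("softmax_expectation", "logsumexp"):
            raise ValueError(f"unknown value_rule {self.value_rule!r}")


@dataclass(frozen=True)
class BeliefState:
    """Evidence counts: beads of colour A and colour B seen so far."""

    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError(f"negative bead counts: ({self.n_a}, {self.n_b})")

    @property
    def depth(self) -> int:
        return self.n_a + self.n_b


@dataclass(frozen=True)
class SubjectParams:
    """Free parameters of one subject.

    ``cs`` is the subjective cost per bead sampled and ``t`` the cognitive
    noise (softmax temperature), both in units of the declaration reward.
    ``t = 0`` selects the deterministic ideal-observer limit.
    """

    cs: float
    t: float

    def __post_init__(self) -> None:
        if self.cs < 0:
            raise ValueError(f"cs must be >= 0, got {self.cs}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")


@dataclass(frozen=True)
class ActionValues:
    """Action values at one belief state; ``q_sample`` is None at the cap."""

    q_declare_a: float
    q_declare_b: float
    q_sample: float | None


@dataclass(frozen=True)
class BeadsTrial:
    """One beads-task trial record.

    ``sequence`` is the full drawable bead order (colours 'A'/'B', length
    ``d_max``); ``draws`` is the number of beads viewed before declaring.
    """

    sequence: str
    draws: int
    declared: str
    true_jar: str | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1 (first decision follows the first bead)")
        if self.declared not in ("A", "B"):
            raise ValueError(f"declared must be 'A' or 'B', got {self.declared!r}")
        if len(self.sequence) < self.draws:
            raise ValueError("sequence shorter than draws")
        bad = set(self.sequence) - {"A", "B"}
        if bad:
            raise ValueError(f"sequence contains non-colour symbols {bad}")


def _check_state(state: BeliefState, config: BeadsConfig) -> None:
    if state.depth > config.d_max:
        raise ValueError(
            f"state ({state.n_a}, {state.n_b}) exceeds the {config.d_max}-bead cap"
        )


def posterior_a(state: BeliefState, config: BeadsConfig) -> float:
    """Posterior probability of Jar A given the evidence counts.

    Bayes rule over the two known binomial sources, computed in log space.
    With a symmetric prior the posterior depends on the counts only through
    ``n_a - n_b``.
    """
    _check_state(state, config)
    log_q, log_1mq = math.log(config.q), math.log1p(-config.q)
    la = math.log(config.prior_a) + state.n_a * log_q + state.n_b * log_1mq
    lb = math.log1p(-config.prior_a) + state.n_a * log_1mq + state.n_b * log_q
    # p = exp(la) / (exp(la) + exp(lb)) = 1 / (1 + exp(lb - la))
    return 1.0 / (1.0 + math.exp(lb - la))


def predictive_next(state: BeliefState, config: BeadsConfig) -> float:
    """Marginal probability that the next bead shows colour A."""
    _check_state(state, config)
    if state.depth >= config.d_max:
        raise RuntimeError("no further bead can be drawn at the cap")
    p = posterior_a(state, config)
    return p * config.q + (1.0 - p) * (1.0 - config.q)


def _posterior_lattice(config: BeadsConfig) -> list[np.ndarray]:
    """P(Jar A) for every state, as per-depth vectors indexed by n_a."""
    log_q, log_1mq = math.log(config.q), math.log1p(-config.q)
    lp, l1mp = math.log(config.prior_a), math.log1p(-config.prior_a)
    out = []
    for d in range(config.d_max + 1):
        n_a = np.arange(d + 1)
        la = lp + n_a * log_q + (d - n_a) * log_1mq
        lb = l1mp + n_a * log_1mq + (d - n_a) * log_q
        out.append(1.0 / (1.0 + np.exp(lb - la)))
    return out


def _deterministic_policy(qv: np.ndarray, has_sample: bool, config: BeadsConfig) -> np.ndarray:
    """One-hot (or tie-split) policy for the t = 0 limit.

    ``qv`` has shape (..., n_actions) with action order (sample, a, b) when
    ``has_sample`` else (a, b).  Ties within ``_TIE_ATOL`` are resolved by the
    configured tie-break; a residual declare-declare tie splits evenly.
    """
    best = qv.max(axis=-1, keepdims=True)
    tied = qv >= best - _TIE_ATOL
    pol = np.zeros_like(qv)
    if has_sample:
        sample_tied = tied[..., 0]
        declare_tied = tied[..., 1:]
        any_declare = declare_tied.any(axis=-1)
        if config.tie_break == "prefer_sample":
            take_sample = sample_tied
        else:
            take_sample = sample_tied & ~any_declare
        pol[..., 0] = np.where(take_sample, 1.0, 0.0)
        n_declare = declare_tied.sum(axis=-1)
        share = declare_tied / np.maximum(n_declare, 1)[..., None]
        pol[..., 1:] = np.where(take_sample[..., None], 0.0, share)
    else:
        pol[...] = tied / tied.sum(axis=-1, keepdims=True)
    return pol


def _solve_lattice(
    cs: np.ndarray, t: np.ndarray, config: BeadsConfig
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Backward induction over the belief lattice, vectorised over parameters.

    ``cs`` and ``t`` are parallel 1-D arrays of m parameter pairs.  Returns,
    per depth d, arrays of shape (m, d+1, n_actions):

    - ``log_pi[d]`` log policy over (sample, declare_a, declare_b); the sample
      column is -inf at d = d_max,
    - ``qvals[d]`` the action values (NaN sample column at the cap),

    and per depth the state values ``vals[d]`` of shape (m, d+1).

    Indexing within a depth is by n_a.  States at depth 0 exist (no bead seen)
    so the table supports querying the prior state, although the first
    decision point of a trial follows the first bead.
    """
    m = len(cs)
    post = _posterior_lattice(config)
    rc, ri = config.reward_correct, config.reward_incorrect
    positive_t = t > 0
    t_safe = np.where(positive_t, t, 1.0)

    log_pi: list[np.ndarray] = [None] * (config.d_max + 1)  # type: ignore[list-item]
    qvals: list[np.ndarray] = [None] * (config.d_max + 1)  # type: ignore[list-item]
    vals: list[np.ndarray] = [None] * (config.d_max + 1)  # type: ignore[list-item]

    v_next: np.ndarray | None = None
    for d in range(config.d_max, -1, -1):
        pa = post[d][None, :]  # (1, d+1)
        q_a = np.broadcast_to(pa * rc + (1 - pa) * ri, (m, d + 1))
        q_b = np.broadcast_to((1 - pa) * rc + pa * ri, (m, d + 1))
        terminal = d == config.d_max
        if terminal:
            qv = np.stack([np.full((m, d + 1), -np.inf), q_a, q_b], axis=-1)
        else:
            pred = pa * config.q + (1 - pa) * (1 - config.q)  # P(next bead = A)
            ev = pred * v_next[:, 1:] + (1 - pred) * v_next[:, :-1]
            q_s = -cs[:, None] + ev
            qv = np.stack([q_s, q_a, q_b], axis=-1)

        # softmax policy (stable); -inf sample column drops out naturally
        logits = qv / t_safe[:, None, None]
        lse = logsumexp(logits, axis=-1, keepdims=True)
        lp_soft = logits - lse
        if config.value_rule == "softmax_expectation":
            v_soft = np.einsum("mda,mda->md", np.exp(lp_soft), np.where(np.isfinite(qv), qv, 0.0))
        else:  # logsumexp rule: V = t * log sum exp(Q / t)
            v_soft = t_safe[:, None] * lse[..., 0]

        if not positive_t.all():
            if terminal:
                pol_det = _deterministic_policy(qv[..., 1:], has_sample=False, config=config)
                pol_full = np.concatenate([np.zeros((m, d + 1, 1)), pol_det], axis=-1)
            else:
                pol_full = _deterministic_policy(qv, has_sample=True, config=config)
            with np.errstate(divide="ignore"):
                lp_det = np.log(pol_full)
            v_det = np.where(np.isfinite(qv), qv, -np.inf).max(axis=-1)
            sel = positive_t[:, None, None]
            lp = np.where(sel, lp_soft, lp_det)
            v = np.where(positive_t[:, None], v_soft, v_det)
        else:
            lp, v = lp_soft, v_soft

        log_pi[d], qvals[d], vals[d] = lp, qv, v
        v_next = v
    return log_pi, qvals, vals


class ValueTable:
    """Complete solution of the model for one (cs, t) pair: action values,
    state values and the softmax policy at every reachable belief state."""

    def __init__(self, params: SubjectParams, config: BeadsConfig):
        self.params = params
        self.config = config
        lp, qv, vv = _solve_lattice(
            np.array([params.cs]), np.array([params.t]), config
        )
        self._log_pi = [a[0] for a in lp]
        self._q = [a[0] for a in qv]
        self._v = [a[0] for a in vv]

    def _locate(self, state: BeliefState) -> tuple[int, int]:
        _check_state(state, self.config)
        return state.depth, state.n_a

    def action_values(self, state: BeliefState) -> ActionValues:
        d, i = self._locate(state)
        q = self._q[d][i]
        return ActionValues(
            q_declare_a=float(q[1]),
            q_declare_b=float(q[2]),
            q_sample=None if d == self.config.d_max else float(q[0]),
        )

    def state_value(self, state: BeliefState) -> float:
        d, i = self._locate(state)
        return float(self._v[d][i])

    def log_policy(self, state: BeliefState) -> np.ndarray:
        """Log policy as (sample, declare_a, declare_b); -inf where unavailable."""
        d, i = self._locate(state)
        return self._log_pi[d][i].copy()

    def policy(self, state: BeliefState) -> np.ndarray:
        return np.exp(self.log_policy(state))

    def states(self) -> Iterable[BeliefState]:
        for d in range(self.config.d_max + 1):
            for n_a in range(d + 1):
                yield BeliefState(n_a, d - n_a)


def build_value_table(params: SubjectParams, config: BeadsConfig) -> ValueTable:
    """Solve the model by backward induction from the bead cap to the prior."""
    return ValueTable(params, config)


def policy_at(state: BeliefState, table: ValueTable) -> np.ndarray:
    """Action probabilities (sample, declare_a, declare_b) at a state."""
    return table.policy(state)


def _prefix_state(sequence: str, k: int) -> BeliefState:
    n_a = sequence[:k].count("A")
    return BeliefState(n_a, k - n_a)


def trial_loglik(
    trial: BeadsTrial,
    params: SubjectParams,
    config: BeadsConfig,
    table: ValueTable | None = None,
) -> float:
    """Log probability (nats) of one trial's action record under the model.

    The record implies "sample" at each decision point before the last bead
    viewed and "declare" at the last; the log policy of each observed action
    is summed along the belief states reached by the bead sequence.
    """
    if trial.draws > config.d_max:
        raise ValueError(f"draws {trial.draws} exceeds cap {config.d_max}")
    if table is None:
        table = build_value_table(params, config)
    total = 0.0
    for k in range(1, trial.draws + 1):
        lp = table.log_policy(_prefix_state(trial.sequence, k))
        if k < trial.draws:
            total += float(lp[0])
        else:
            total += float(lp[1] if trial.declared == "A" else lp[2])
    return total


def simulate_trial(
    params: SubjectParams,
    config: BeadsConfig,
    true_jar: str,
    seed: int | np.random.Generator,
    sequence: str | None = None,
    table: ValueTable | None = None,
) -> BeadsTrial:
    """Simulate one trial: draw a bead order from ``true_jar`` and walk the
    policy, sampling actions stochastically.  Reproducible given the seed.

    Action draws use a fixed cumulative ordering (sample, declare_a,
    declare_b) against a single uniform per decision point, so simulations at
    different parameters under common random numbers are coupled: any change
    that lowers the sample probability can only shorten the trial.
    """
    if true_jar not in ("A", "B"):
        raise ValueError(f"true_jar must be 'A' or 'B', got {true_jar!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_a = config.q if true_jar == "A" else 1.0 - config.q
    if sequence is None:
        bead_u = rng.random(config.d_max)
        sequence = "".join("A" if u < p_a else "B" for u in bead_u)
    action_u = rng.random(config.d_max)
    if table is None:
        table = build_value_table(params, config)
    for k in range(1, config.d_max + 1):
        pol = table.policy(_prefix_state(sequence, k))
        u = action_u[k - 1]
        if u < pol[0]:
            continue  # sample another bead
        declared = "A" if u < pol[0] + pol[1] else "B"
        return BeadsTrial(sequence=sequence, draws=k, declared=declared, true_jar=true_jar)
    # unreachable: sample probability is exactly 0 at the cap
    raise AssertionError("policy failed to terminate at the bead cap")
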