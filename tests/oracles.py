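"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force and memoisation-free (plain
Python floats, exhaustive enumeration) and shares no code with the package
internals beyond the configuration objects.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from reflectim.beads import BeadsConfig


# --- beads task: exhaustive recursion over all continuations ----------------

def oracle_posterior(n_a: int, n_b: int, cfg: BeadsConfig) -> float:
    wa = cfg.prior_a * cfg.q ** n_a * (1 - cfg.q) ** n_b
    wb = (1 - cfg.prior_a) * (1 - cfg.q) ** n_a * cfg.q ** n_b
    return wa / (wa + wb)


def oracle_action_values(n_a: int, n_b: int, cs: float, t: float, cfg: BeadsConfig):
    """(q_sample or None, q_declare_a, q_declare_b) by direct recursion."""
    p = oracle_posterior(n_a, n_b, cfg)
    qa = p * cfg.reward_correct + (1 - p) * cfg.reward_incorrect
    qb = (1 - p) * cfg.reward_correct + p * cfg.reward_incorrect
    if n_a + n_b == cfg.d_max:
        return None, qa, qb
    pred = p * cfg.q + (1 - p) * (1 - cfg.q)
    qs = -cs + (pred * oracle_state_value(n_a + 1, n_b, cs, t, cfg)
                + (1 - pred) * oracle_state_value(n_a, n_b + 1, cs, t, cfg))
    return qs, qa, qb


def oracle_policy(n_a: int, n_b: int, cs: float, t: float, cfg: BeadsConfig):
    """Softmax policy (sample, declare_a, declare_b); sample prob 0 at cap."""
    qs, qa, qb = oracle_action_values(n_a, n_b, cs, t, cfg)
    qvals = [qa, qb] if qs is None else [qs, qa, qb]
    mx = max(qvals)
    ws = [math.exp((q - mx) / t) for q in qvals]
    z = sum(ws)
    probs = [w / z for w in ws]
    return [0.0] + probs if qs is None else probs


def oracle_state_value(n_a: int, n_b: int, cs: float, t: float, cfg: BeadsConfig) -> float:
    qs, qa, qb = oracle_action_values(n_a, n_b, cs, t, cfg)
    pol = oracle_policy(n_a, n_b, cs, t, cfg)
    qvals = [0.0 if qs is None else qs, qa, qb]
    if cfg.value_rule == "softmax_expectation":
        return sum(p * q for p, q in zip(pol, qvals))
    mx = max(q for q in ([qa, qb] if qs is None else [qs, qa, qb]))
    return mx + t * math.log(sum(
        math.exp((q - mx) / t) for q in ([qa, qb] if qs is None else [qs, qa, qb])
    ))


def oracle_record_probability(
    sequence: str, draws: int, declared: str, cs: float, t: float, cfg: BeadsConfig
) -> float:
    """P(observed record | bead sequence) by enumerating every action path.

    Walks all (stop-time, declaration) outcomes of the decision process along
    the fixed bead sequence and accumulates the probability of each; returns
    the mass on the observed record.  The full outcome distribution sums to 1,
    which callers may additionally assert.
    """
    outcomes = oracle_outcome_distribution(sequence, cs, t, cfg)
    return outcomes.get((draws, declared), 0.0)


def oracle_outcome_distribution(sequence: str, cs: float, t: float, cfg: BeadsConfig):
    outcomes: dict[tuple[int, str], float] = {}

    def walk(k: int, mass: float) -> None:
        n_a = sequence[:k].count("A")
        n_b = k - n_a
        ps, pa, pb = oracle_policy(n_a, n_b, cs, t, cfg)
        outcomes[(k, "A")] = outcomes.get((k, "A"), 0.0) + mass * pa
        outcomes[(k, "B")] = outcomes.get((k, "B"), 0.0) + mass * pb
        if k < cfg.d_max:
            walk(k + 1, mass * ps)

    walk(1, 1.0)
    return outcomes


# --- IST ---------------------------------------------------------------------

def oracle_ist_p_correct(n_opened: int, n_chosen_colour: int) -> float:
    """Exhaustive enumeration over all 2^u unopened-cell colourings."""
    u = 25 - n_opened
    hits = 0
    for combo in itertools.product((0, 1), repeat=u):
        if n_chosen_colour + sum(combo) >= 13:
            hits += 1
    return float(Fraction(hits, 2 ** u))


# --- classical statistics ----------------------------------------------------

def oracle_pooled_t(x: list[float], y: list[float]) -> tuple[float, int]:
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, df


def oracle_exact_ranksum_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = sorted(x + y)
    ranks = {}
    for v in set(pooled):
        idx = [i + 1 for i, p in enumerate(pooled) if p == v]
        ranks[v] = sum(idx) / len(idx)
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    all_ranks = [ranks[v] for v in pooled]
    stats = [sum(combo) for combo in itertools.combinations(all_ranks, n)]
    mean_w = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(stats)


def oracle_mixed_anova_2x2(groups: dict[str, list[tuple[float, float]]]):
    """Classical univariate mixed-model ANOVA for 2 groups x 2 conditions.

    ``groups`` maps group label to per-subject (condition1, condition2)
    pairs.  Returns F statistics for the between-group effect, the within
    (condition) effect and the interaction, with their error dfs.
    """
    labels = sorted(groups)
    ns = {g: len(groups[g]) for g in labels}
    n_total = sum(ns.values())
    grand = sum(v for g in labels for pair in groups[g] for v in pair) / (2 * n_total)

    subj_means = {g: [sum(p) / 2 for p in groups[g]] for g in labels}
    group_means = {g: sum(subj_means[g]) / ns[g] for g in labels}
    cond_means_by_group = {
        g: [sum(p[c] for p in groups[g]) / ns[g] for c in (0, 1)] for g in labels
    }
    # weighted condition means (cell-means model, matching balanced-within design)
    cond_means = [
        sum(p[c] for g in labels for p in groups[g]) / n_total for c in (0, 1)
    ]

    ss_group = 2 * sum(ns[g] * (group_means[g] - grand) ** 2 for g in labels)
    ss_subj = 2 * sum(
        (m - group_means[g]) ** 2 for g in labels for m in subj_means[g]
    )
    ss_cond = n_total * sum((cm - grand) ** 2 for cm in cond_means)
    ss_inter = sum(
        ns[g] * (cond_means_by_group[g][c] - group_means[g] - cond_means[c] + grand) ** 2
        for g in labels for c in (0, 1)
    )
    ss_within_err = sum(
        (groups[g][i][c] - cond_means_by_group[g][c] - subj_means[g][i] + group_means[g]) ** 2
        for g in labels for i in range(ns[g]) for c in (0, 1)
    )
    df_between_err = n_total - 2
    df_within_err = n_total - 2
    f_group = (ss_group / 1) / (ss_subj / df_between_err) if ss_subj else math.inf
    f_cond = (ss_cond / 1) / (ss_within_err / df_within_err) if ss_within_err else math.inf
    f_inter = (ss_inter / 1) / (ss_within_err / df_within_err) if ss_within_err else math.inf
    return dict(
        f_group=f_group, f_cond=f_cond, f_inter=f_inter,
        df_between=(1, df_between_err), df_within=(1, df_within_err),
        ss=dict(group=ss_group, subj=ss_subj, cond=ss_cond, inter=ss_inter,
                within_err=ss_within_err),
    )
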