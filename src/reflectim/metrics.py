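"""Scoring of the Information Sampling Task and the 27-item Monetary Choice
Questionnaire, and the behavioural group statistics.

IST: a 5x5 board of two colours; the participant opens boxes and then names
the majority colour.  P(correct) treats each unopened box as an independent
fair coin and is the exact probability that the chosen colour holds the
25-cell majority given the opened evidence.  Points follow the two reward
schedules (fixed win: flat 100; decreasing win: 250 minus 10 per opened box).

MCQ: the hyperbolic discount rate k (per day) is assigned as the candidate
item-indifference value whose implied deterministic choice pattern
(immediate iff k exceeds the item's indifference k, V = A / (1 + kD))
agrees with the most responses; ties take the geometric mean.

Group statistics mirror a standard two-group behavioural battery: per-group
3-SD outlier screening, square-root transforms for count-like sampling
outcomes and log10 for k, pooled-variance t-tests, a 2x2 mixed ANOVA
(between: group; within: reward condition), exact Wilcoxon rank-sum for the
fitted noise parameters and Pearson correlations against severity covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ISTTrial",
    "ISTScore",
    "PointSchedule",
    "MCQItem",
    "ist_p_correct",
    "ist_points",
    "ist_error_type",
    "score_ist_trial",
    "kirby_k",
    "load_mcq_items",
    "ist_trials_from_frame",
    "score_ist_frame",
    "ist_subject_summary",
    "kirby_from_frame",
    "remove_outliers",
    "mixed_anova_2x2",
    "group_tests",
]

GRID_SIZE = 5
N_CELLS = GRID_SIZE * GRID_SIZE
MAJORITY = N_CELLS // 2 + 1  # 13 of 25


@dataclass(frozen=True)
class ISTTrial:
    """One IST trial: board contents, opening order and colour choice.

    ``grid`` is a 25-character row-major string over exactly two colour
    labels; ``opened`` lists distinct 0-based (row, col) coordinates in the
    order touched; ``condition`` is ``"fixed_win"`` or ``"decreasing_win"``.
    """

    grid: str
    opened: tuple[tuple[int, int], ...]
    choice: str
    condition: str = "fixed_win"

    def __post_init__(self) -> None:
        if len(self.grid) != N_CELLS:
            raise ValueError(f"grid must have {N_CELLS} cells, got {len(self.grid)}")
        colours = sorted(set(self.grid))
        if len(colours) != 2:
            raise ValueError(f"grid must contain exactly two colours, got {colours}")
        if self.choice not in colours:
            raise ValueError(f"choice {self.choice!r} not a board colour {colours}")
        if not 1 <= len(self.opened) <= N_CELLS:
            raise ValueError("must open between 1 and 25 boxes")
        if len(set(self.opened)) != len(self.opened):
            raise ValueError("opened cells must be distinct")
        for r, c in self.opened:
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
                raise ValueError(f"cell ({r}, {c}) out of bounds")
        if self.condition not in ("fixed_win", "decreasing_win"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def colours(self) -> tuple[str, str]:
        a, b = sorted(set(self.grid))
        return a, b

    def cell(self, r: int, c: int) -> str:
        return self.grid[r * GRID_SIZE + c]

    @property
    def opened_colours(self) -> list[str]:
        return [self.cell(r, c) for r, c in self.opened]

    @property
    def true_majority(self) -> str:
        a, b = self.colours
        return a if self.grid.count(a) >= MAJORITY else b


@dataclass(frozen=True)
class PointSchedule:
    """IST reward schedule; only the win amounts are printed on the
    instrument, so the loss and floor are configurable."""

    fixed_win: int = 100
    decreasing_start: int = 250
    decreasing_step: int = 10
    penalty: int = 100
    floor: int = 0


@dataclass(frozen=True)
class ISTScore:
    boxes_opened: int
    p_correct: float
    points: int
    correct: bool
    error_type: str  # none | sampling_error | discrimination_error


def ist_p_correct(trial: ISTTrial) -> float:
    """Exact P(chosen colour is the 25-cell majority | opened evidence).

    Each unopened cell is an independent fair coin; with m opened cells of
    the chosen colour and u unopened cells, the probability is the binomial
    tail  sum_{j : m + j >= 13} C(u, j) / 2^u, evaluated in exact rational
    arithmetic before conversion to float.
    """
    m = sum(1 for c in trial.opened_colours if c == trial.choice)
    u = N_CELLS - len(trial.opened)
    need = max(MAJORITY - m, 0)
    total = Fraction(0)
    for j in range(need, u + 1):
        total += Fraction(math.comb(u, j), 2 ** u)
    return float(total)


def ist_points(trial: ISTTrial, schedule: PointSchedule | None = None) -> int:
    """Points won (or lost) on a trial under its reward condition."""
    schedule = schedule or PointSchedule()
    correct = trial.choice == trial.true_majority
    if trial.condition == "fixed_win":
        return schedule.fixed_win if correct else -schedule.penalty
    win = max(
        schedule.decreasing_start - schedule.decreasing_step * len(trial.opened),
        schedule.floor,
    )
    return win if correct else -schedule.penalty


def ist_error_type(trial: ISTTrial) -> str:
    """Classify an incorrect choice.

    A *discrimination error* goes against the majority of the opened boxes
    (the evidence was misread); a *sampling error* follows the opened
    majority but the board majority differs (the evidence was insufficient).
    Ties among opened colours count as sampling errors.
    """
    if trial.choice == trial.true_majority:
        return "none"
    opened = trial.opened_colours
    a, b = trial.colours
    ca, cb = opened.count(a), opened.count(b)
    if ca == cb:
        return "sampling_error"
    opened_majority = a if ca > cb else b
    return "sampling_error" if trial.choice == opened_majority else "discrimination_error"


def score_ist_trial(trial: ISTTrial, schedule: PointSchedule | None = None) -> ISTScore:
    return ISTScore(
        boxes_opened=len(trial.opened),
        p_correct=ist_p_correct(trial),
        points=ist_points(trial, schedule),
        correct=trial.choice == trial.true_majority,
        error_type=ist_error_type(trial),
    )


@dataclass(frozen=True)
class MCQItem:
    """One questionnaire item: immediate amount now vs larger amount later."""

    item_id: int
    immediate_amount: float
    delayed_amount: float
    delay_days: float

    def __post_init__(self) -> None:
        if not self.delayed_amount > self.immediate_amount > 0:
            raise ValueError("need delayed_amount > immediate_amount > 0")
        if self.delay_days <= 0:
            raise ValueError("delay must be positive")

    @property
    def k_indiff(self) -> float:
        """Discount rate at which the two options are equally valued."""
        return (self.delayed_amount / self.immediate_amount - 1.0) / self.delay_days


def load_mcq_items() -> list[MCQItem]:
    """The packaged 27-item questionnaire (amounts in currency units, delays
    in days); editable data, not code."""
    with resources.files("reflectim.data").joinpath("mcq27.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        MCQItem(
            item_id=int(r.item_id),
            immediate_amount=float(r.immediate_amount),
            delayed_amount=float(r.delayed_amount),
            delay_days=float(r.delay_days),
        )
        for r in frame.itertuples(index=False)
    ]


def kirby_k(
    responses: list[str], items: list[MCQItem] | None = None
) -> tuple[float, float]:
    """Assign the hyperbolic discount rate k from 27 immediate/delayed choices.

    Candidate k values are the item indifference points; the assigned k is
    the candidate whose implied pattern (immediate iff k > k_indiff)
    maximises agreement, geometric mean over ties.  Returns (k, consistency)
    with consistency the maximal agreement proportion.
    """
    items = items if items is not None else load_mcq_items()
    if len(responses) != len(items):
        raise ValueError(f"got {len(responses)} responses for {len(items)} items")
    bad = set(responses) - {"immediate", "delayed"}
    if bad:
        raise ValueError(f"responses must be 'immediate'/'delayed', got {bad}")
    k_ind = np.array([it.k_indiff for it in items])
    chose_imm = np.array([r == "immediate" for r in responses])
    candidates = np.unique(k_ind)
    agreement = np.array(
        [(chose_imm == (k > k_ind)).sum() for k in candidates]
    )
    best = agreement.max()
    winners = candidates[agreement == best]
    if len(winners) == 1:
        k = float(winners[0])  # exact: no log/exp round trip
    else:
        k = float(np.exp(np.mean(np.log(winners))))
    return k, best / len(items)


def ist_trials_from_frame(frame: pd.DataFrame) -> list[ISTTrial]:
    """Parse the IST CSV schema (grid as 25-char string, opened as
    semicolon-separated "r,c" pairs) into trial objects, row order kept."""
    trials = []
    for row in frame.itertuples(index=False):
        opened = tuple(
            tuple(int(x) for x in cell.split(","))
            for cell in str(row.opened).split(";")
        )
        trials.append(ISTTrial(grid=str(row.grid), opened=opened,  # type: ignore[arg-type]
                               choice=str(row.choice), condition=str(row.condition)))
    return trials


def score_ist_frame(
    frame: pd.DataFrame, schedule: PointSchedule | None = None
) -> pd.DataFrame:
    """Score every IST trial row; returns the input ids plus score columns."""
    records = []
    for row, trial in zip(frame.itertuples(index=False), ist_trials_from_frame(frame)):
        s = score_ist_trial(trial, schedule)
        records.append(dict(
            subject_id=row.subject_id, trial_index=row.trial_index,
            condition=row.condition, boxes_opened=s.boxes_opened,
            p_correct=s.p_correct, points=s.points, correct=s.correct,
            error_type=s.error_type,
        ))
    return pd.DataFrame(records)


def ist_subject_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition IST summary in wide form: mean boxes
    opened, mean P(correct), total points and the sampling-error rate."""
    g = scored.groupby(["subject_id", "condition"])
    summary = g.agg(
        boxes=("boxes_opened", "mean"),
        pcorrect=("p_correct", "mean"),
        points=("points", "sum"),
        sampling_error=("error_type", lambda e: float((e == "sampling_error").mean())),
    ).reset_index()
    wide = summary.pivot(index="subject_id", columns="condition")
    wide.columns = [
        {"boxes": "ist_boxes", "pcorrect": "ist_pcorrect",
         "points": "ist_points", "sampling_error": "ist_sampling_error"}[m] + f"_{c}"
        for m, c in wide.columns
    ]
    return wide.reset_index()


def kirby_from_frame(
    frame: pd.DataFrame, items: list[MCQItem] | None = None
) -> pd.DataFrame:
    """Per-subject discount rate and consistency from an MCQ response table
    (columns: subject_id, item_id, choice)."""
    items = items if items is not None else load_mcq_items()
    by_id = {it.item_id: it for it in items}
    rows = []
    for sid, sub in frame.groupby("subject_id", sort=False):
        sub = sub.set_index("item_id")["choice"]
        try:
            responses = [str(sub.loc[it.item_id]) for it in items]
        except KeyError as err:
            raise ValueError(f"subject {sid} missing MCQ item {err}") from None
        k, consistency = kirby_k(responses, items)
        rows.append(dict(subject_id=sid, k_value=k, consistency=consistency))
    return pd.DataFrame(rows)


def remove_outliers(
    values_by_group: dict[str, pd.Series]
) -> tuple[dict[str, pd.Series], list]:
    """Single-pass per-group screening at mean +/- 3 sample SD.

    Zero-SD groups remove nothing.  Returns the kept values per group and
    the removed index labels (subject ids).
    """
    kept: dict[str, pd.Series] = {}
    removed: list = []
    for group, values in values_by_group.items():
        v = values.astype(float)
        if len(v) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 values")
        sd = v.std(ddof=1)
        if sd == 0:
            mask = pd.Series(True, index=v.index)
        else:
            mask = (v - v.mean()).abs() <= 3 * sd
        kept[group] = v[mask]
        removed.extend(v.index[~mask].tolist())
    return kept, removed


def mixed_anova_2x2(
    long: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """2x2 mixed-measures ANOVA (between-subject group, within-subject
    condition); returns the pingouin table (Source, F, DF1, DF2, p-unc)."""
    import pingouin as pg

    table = pg.mixed_anova(
        data=long, dv=dv, within=within, between=between, subject=subject
    )
    return table


def _sqrt(series: pd.Series, name: str) -> pd.Series:
    if (series < 0).any():
        raise ValueError(f"negative values in {name}; cannot sqrt-transform")
    return np.sqrt(series)


def _log10(series: pd.Series, name: str) -> pd.Series:
    bad = series.index[series <= 0]
    if len(bad):
        raise ValueError(f"non-positive {name} for subjects {list(bad)}; cannot log10")
    return np.log10(series)


def group_tests(
    table: pd.DataFrame,
    groups: tuple[str, str] = ("HV", "BD"),
    welch: bool = False,
    severity_col: str = "audit",
) -> pd.DataFrame:
    """Behavioural group statistics over a per-subject outcome table.

    Expects one row per subject with a ``group`` column plus outcome columns
    (``beads_draws_mean``, per-condition IST columns, ``k_value``; optional
    ``map_t`` from the model fit and a severity covariate).  Applies the
    transforms (sqrt for beads/IST, log10 for k) before testing; originals
    stay untouched in the input table.  Returns a tidy frame of test name,
    statistic, df, p and group sizes.
    """
    g1, g2 = groups
    present = set(table["group"])
    if not {g1, g2} <= present:
        raise ValueError(f"need both groups {groups}, table has {sorted(present)}")
    a_rows = table[table["group"] == g1]
    b_rows = table[table["group"] == g2]
    results: list[dict] = []

    def add(name, statistic, df, p, n1, n2):
        results.append(
            dict(test=name, statistic=float(statistic),
                 df=float(df) if df is not None else np.nan,
                 p=float(p), n_group1=int(n1), n_group2=int(n2))
        )

    def ttest(name, col, transform):
        if col not in table.columns:
            return
        x = transform(a_rows.set_index("subject_id")[col].dropna(), col)
        y = transform(b_rows.set_index("subject_id")[col].dropna(), col)
        res = stats.ttest_ind(x, y, equal_var=not welch)
        add(f"t_{name}", res.statistic, res.df, res.pvalue, len(x), len(y))

    ttest("beads_draws", "beads_draws_mean", _sqrt)
    ttest("ist_boxes_fixed", "ist_boxes_fixed_win", _sqrt)
    ttest("log10_k", "k_value", _log10)

    # secondary IST outcomes: 2x2 mixed ANOVA per measure
    for measure in ("ist_points", "ist_pcorrect", "ist_sampling_error"):
        cols = [f"{measure}_fixed_win", f"{measure}_decreasing_win"]
        if not all(c in table.columns for c in cols):
            continue
        sub = table[["subject_id", "group", *cols]].dropna()
        long = sub.melt(
            id_vars=["subject_id", "group"], value_vars=cols,
            var_name="condition", value_name="value",
        )
        aov = mixed_anova_2x2(long)
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        for src_label, src in (("group", "group"), ("cost", "condition"),
                               ("group_x_cost", "Interaction")):
            row = aov[aov["Source"] == src].iloc[0]
            add(f"anova_{measure}_{src_label}", row["F"], row["DF2"],
                row[p_col], len(sub[sub["group"] == g1]), len(sub[sub["group"] == g2]))

    # fitted cognitive noise: exact rank-sum
    if "map_t" in table.columns:
        x = a_rows["map_t"].dropna()
        y = b_rows["map_t"].dropna()
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        add("wilcoxon_map_t", res.statistic, None, res.pvalue, len(x), len(y))
        res1 = stats.mannwhitneyu(x, y, alternative="less", method="auto")
        add("wilcoxon_map_t_one_sided", res1.statistic, None, res1.pvalue, len(x), len(y))

    # severity correlation with evidence seeking, across groups
    if severity_col in table.columns and "beads_draws_mean" in table.columns:
        sub = table[["beads_draws_mean", severity_col]].dropna()
        r, p = stats.pearsonr(sub["beads_draws_mean"], sub[severity_col])
        add("pearson_beads_severity", r, len(sub) - 2, p,
            len(sub), len(sub))

    return pd.DataFrame(results)
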