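"""Behavioral analyses: exclusion, stay probabilities, ANOVA, regressions.

The analysis battery mirrors a standard two-stage-task workflow:

* perseverator exclusion (subjects choosing one action on more than 95% of
  trials show no learning and are removed);
* per-subject stay probabilities stratified by the previous trial's outcome
  and transition type, and the 2 (outcome) x 2 (transition) x 2 (condition)
  mixed-design ANOVA on them -- the model-free signature is an outcome main
  effect, the model-based signature an outcome x transition interaction,
  and a condition difference in the balance of the two systems appears as
  the three-way interaction;
* performance summaries (total points; probability of choosing the
  advantageous first-stage action, defined only from block 2 on);
* two-sample t comparisons of summaries or fitted parameters between
  conditions, the OLS regression of the model-free no-reward increment on
  the decay factor plus a treatment indicator, and the ANCOVA of that
  increment on condition with the advantageous-choice probability as
  covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from .task import TaskConfig

#: The four previous-trial cells of the stay analysis, in fixed order.
STAY_CELLS = (
    ("rewarded", "common"),
    ("rewarded", "rare"),
    ("unrewarded", "common"),
    ("unrewarded", "rare"),
)
STAY_COLUMNS = tuple(f"stay_{o}_{t}" for o, t in STAY_CELLS)


def exclude_perseverators(
    dataset: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects whose modal first-stage action exceeds ``threshold``.

    The boundary is strict: a subject at exactly the threshold is retained.
    Returns the retained trial log and the excluded subject ids.
    """
    excluded: list[str] = []
    for sid, sub in dataset.groupby("subject_id", sort=True):
        p_modal = sub["choice1"].value_counts(normalize=True).iloc[0]
        if p_modal > threshold:
            excluded.append(str(sid))
    retained = dataset[~dataset["subject_id"].isin(excluded)].reset_index(drop=True)
    return retained, excluded


@dataclass(frozen=True)
class StayTable:
    """Per-subject stay probabilities and cell counts for the four cells."""

    probs: dict
    counts: dict

    def as_row(self) -> dict:
        row = {}
        for (o, t), col in zip(STAY_CELLS, STAY_COLUMNS):
            row[col] = self.probs[(o, t)]
            row[f"n_{o}_{t}"] = self.counts[(o, t)]
        return row


def stay_probabilities(trials: pd.DataFrame) -> StayTable:
    """Stay probability per (previous outcome, previous transition) cell.

    Each trial t >= 2 is classified by trial t-1's outcome and transition;
    "stay" means repeating the previous first-stage choice.  Block
    boundaries do not interrupt the sequence (reversals are uncued), and an
    empty cell yields NaN with a zero count.
    """
    df = trials.sort_values("trial")
    choice = df["choice1"].to_numpy()
    rewarded = np.where(df["outcome"].to_numpy() > 0, "rewarded", "unrewarded")
    transition = df["transition"].to_numpy()
    stay = choice[1:] == choice[:-1]
    prev_out, prev_tr = rewarded[:-1], transition[:-1]
    probs, counts = {}, {}
    for o, t in STAY_CELLS:
        mask = (prev_out == o) & (prev_tr == t)
        n = int(mask.sum())
        counts[(o, t)] = n
        probs[(o, t)] = float(stay[mask].mean()) if n else float("nan")
    return StayTable(probs=probs, counts=counts)


def cohort_stay_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: condition, four stay probabilities, counts."""
    rows = []
    for sid, sub in dataset.groupby("subject_id", sort=True):
        row = {"subject_id": str(sid), "condition": str(sub["condition"].iloc[0])}
        row.update(stay_probabilities(sub).as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def stay_anova(stay_table: pd.DataFrame) -> pd.DataFrame:
    """Mixed-design ANOVA on the stay probabilities.

    Within-subject factors: outcome (rewarded / unrewarded) and transition
    (common / rare); between-subject factor: condition (two levels).
    Subjects with any empty cell are dropped with a warning.  Returns one
    row per effect with F, df1, df2 and p.

    The split-plot decomposition is computed from orthonormal per-subject
    contrasts: the subject mean carries the between-subject stratum
    (condition, with subjects-within-condition error), and each within
    contrast (outcome, transition, their product) carries its own stratum
    whose error is the contrast's residual within-condition variance.
    Effect sums of squares use unweighted condition means, matching the
    conventional Type-III treatment of (possibly) unequal group sizes.
    """
    df = stay_table.copy()
    bad = df[list(STAY_COLUMNS)].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} subject(s) with empty stay cells: "
            f"{df.loc[bad, 'subject_id'].tolist()}",
            stacklevel=2,
        )
        df = df[~bad]
    groups = sorted(df["condition"].unique())
    if len(groups) != 2:
        raise ValueError(f"stay_anova needs exactly two conditions; got {groups}")
    counts = df["condition"].value_counts()
    if counts.min() < 2:
        raise ValueError("stay_anova needs at least two subjects per condition")

    y = df[list(STAY_COLUMNS)].to_numpy()  # columns: RC, RR, UC, UR
    # orthonormal per-subject contrasts
    strata = {
        "subject_mean": y @ np.array([1, 1, 1, 1]) / 2.0,
        "outcome": y @ np.array([1, 1, -1, -1]) / 2.0,
        "transition": y @ np.array([1, -1, 1, -1]) / 2.0,
        "outcome * transition": y @ np.array([1, -1, -1, 1]) / 2.0,
    }
    cond = df["condition"].to_numpy()
    n_g = np.array([(cond == g).sum() for g in groups], dtype=float)
    n_total = int(n_g.sum())
    df_err = n_total - 2

    rows = []

    def _stratum(name: str, t: np.ndarray, between_label: str, within_label: str | None):
        m_g = np.array([t[cond == g].mean() for g in groups])
        ss_err = sum(((t[cond == g] - m) ** 2).sum() for g, m in zip(groups, m_g))
        ms_err = ss_err / df_err
        effects = []
        if within_label is not None:
            # grand within effect: unweighted mean of group means vs zero
            grand = m_g.mean()
            ss = grand**2 / ((1.0 / n_g).sum() / 4.0)
            effects.append((within_label, ss))
        # condition (interaction with the within contrast, or main effect)
        diff = m_g[0] - m_g[1]
        ss_b = diff**2 / (1.0 / n_g[0] + 1.0 / n_g[1])
        effects.append((between_label, ss_b))
        for label, ss in effects:
            if ms_err == 0.0:
                raise ValueError(
                    f"degenerate (zero) error variance in the {name} stratum"
                )
            f = ss / ms_err
            rows.append(
                {
                    "effect": label,
                    "F": f,
                    "df1": 1,
                    "df2": df_err,
                    "p": float(sps.f.sf(f, 1, df_err)),
                }
            )

    _stratum("subject_mean", strata["subject_mean"], "condition", None)
    _stratum("outcome", strata["outcome"], "condition * outcome", "outcome")
    _stratum("transition", strata["transition"], "condition * transition", "transition")
    _stratum(
        "outcome * transition",
        strata["outcome * transition"],
        "condition * outcome * transition",
        "outcome * transition",
    )
    order = [
        "condition",
        "outcome",
        "transition",
        "condition * outcome",
        "condition * transition",
        "outcome * transition",
        "condition * outcome * transition",
    ]
    out = pd.DataFrame(rows).set_index("effect").loc[order].reset_index()
    return out


@dataclass(frozen=True)
class PerformanceSummary:
    """Session-level performance: points, advantage rate, choice bias."""

    total_points: int
    p_advantageous: float
    p_same_action: float


def performance_summary(trials: pd.DataFrame, config: TaskConfig) -> PerformanceSummary:
    """Summarize one session.

    ``p_advantageous`` is the proportion of first-stage choices matching
    the advantageous action, computed only over blocks where one exists
    (block 1 of the default schedule is symmetric and contributes
    nothing).  ``p_same_action`` is the modal first-stage choice frequency
    over all trials (the perseveration measure).
    """
    df = trials.sort_values("trial")
    total = int(df["outcome"].sum())
    adv_map = {
        b: config.advantageous_action(b) for b in range(1, config.n_blocks + 1)
    }
    mask = df["block"].map(lambda b: adv_map[int(b)] is not None)
    sub = df[mask]
    if len(sub):
        hits = sub["choice1"].to_numpy() == sub["block"].map(
            lambda b: adv_map[int(b)]
        ).to_numpy()
        p_adv = float(hits.mean())
    else:
        p_adv = float("nan")
    p_same = float(df["choice1"].value_counts(normalize=True).iloc[0])
    return PerformanceSummary(total, p_adv, p_same)


def cohort_performance(dataset: pd.DataFrame, config: TaskConfig) -> pd.DataFrame:
    rows = []
    for sid, sub in dataset.groupby("subject_id", sort=True):
        s = performance_summary(sub, config)
        rows.append(
            {
                "subject_id": str(sid),
                "condition": str(sub["condition"].iloc[0]),
                "total_points": s.total_points,
                "p_advantageous": s.p_advantageous,
                "p_same_action": s.p_same_action,
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    table: pd.DataFrame, columns: list[str] | None = None, group_col: str = "condition"
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests per column between the two conditions.

    The t statistic is signed as first group minus second group with groups
    in sorted label order (so control minus stress for the default labels).
    A column with zero pooled variance but a nonzero group difference has
    no finite t and raises.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups; got {groups}")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two subjects per group")
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in (group_col, "subject_id")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for col in columns:
        x, y = g1[col].to_numpy(float), g2[col].to_numpy(float)
        dof = len(x) + len(y) - 2
        if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
            if x.mean() == y.mean():
                t, p = 0.0, 1.0
            else:
                raise ValueError(
                    f"zero pooled variance with unequal means in column {col!r}"
                )
        else:
            t, p = sps.ttest_ind(x, y)
        rows.append(
            {
                "variable": col,
                f"mean_{groups[0]}": x.mean(),
                f"mean_{groups[1]}": y.mean(),
                "t": float(t),
                "df": dof,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def delta_regression(
    fits: pd.DataFrame,
    outcome: str = "d_minus_mf",
    group_col: str = "condition",
    treated_label: str = "stress",
) -> pd.DataFrame:
    """OLS of a fitted parameter on the decay factor plus treatment.

    Tests whether the treatment effect on ``outcome`` (by default the
    model-free no-reward increment) survives controlling for gamma.
    Returns unstandardized B with SE, the standardized coefficient beta,
    t and p per predictor.
    """
    y = fits[outcome].to_numpy(float)
    gamma = fits["gamma"].to_numpy(float)
    treat = (fits[group_col] == treated_label).to_numpy(float)
    if len(y) < 5:
        raise ValueError("need at least two more subjects than predictors")
    X = np.column_stack([gamma, treat])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(y), X])) < 3:
        raise ValueError("collinear or constant predictors (gamma, treatment)")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    sd_y = y.std(ddof=1)
    rows = []
    for i, name in enumerate(["intercept", "gamma", "treatment"]):
        beta = (
            float("nan")
            if i == 0
            else float(model.params[i] * X[:, i - 1].std(ddof=1) / sd_y)
        )
        rows.append(
            {
                "predictor": name,
                "B": float(model.params[i]),
                "SE": float(model.bse[i]),
                "beta": beta,
                "t": float(model.tvalues[i]),
                "p": float(model.pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


def delta_ancova(
    fits: pd.DataFrame,
    performance: pd.DataFrame,
    outcome: str = "d_minus_mf",
    covariate: str = "p_advantageous",
    group_col: str = "condition",
) -> pd.DataFrame:
    """ANCOVA: condition effect on a fitted parameter, adjusting a covariate.

    By default tests whether the condition difference in the model-free
    no-reward increment survives adjustment for the advantageous-choice
    probability.  Returns the pingouin ANCOVA table (F, df, p per term).
    """
    merged = fits.merge(
        performance[["subject_id", covariate]], on="subject_id", validate="1:1"
    )
    if merged[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    return pg.ancova(data=merged, dv=outcome, covar=covariate, between=group_col)
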