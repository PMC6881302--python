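"""Model-agnostic stay/switch analysis of learning-phase behavior.

The signature analysis of the two-step task asks, trial by trial, whether
the participant returned to ("stayed with") the same second-stage stock as
on the previous usable trial.  Because both stocks are reachable from both
advisor pairs, a model-based learner returns to a rewarded stock regardless
of which pair it starts with (a main effect of previous reward), while a
model-free learner does so preferentially when the same pair — hence the
same rewarded advisor — is available (a reward-by-same-state interaction).
The analysis is a hierarchical logistic regression of stay on the previous
trial's reward (z-scored within subject), whether the start state repeated
(+1/-1), and their product, with subject-level random intercept and slopes.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .results import RegressionResult
from .task import TrialRecord

__all__ = [
    "exclusion_filter",
    "code_stay_switch",
    "build_stay_table",
    "fit_stay_model",
    "stay_probability_table",
]

MISS_THRESHOLD = 0.20


def exclusion_filter(
    sessions: dict[str, Sequence[TrialRecord]],
    threshold: float = MISS_THRESHOLD,
) -> tuple[set[str], pd.DataFrame]:
    """Exclude subjects who missed the response deadline too often.

    A subject is excluded iff their miss proportion is *strictly greater*
    than ``threshold`` (a rate of exactly 20% is retained).  Returns the
    included subject ids and a per-subject report of miss rates.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    rows = []
    included: set[str] = set()
    for sid, session in sessions.items():
        miss_rate = float(np.mean([rec.missed for rec in session]))
        excluded = miss_rate > threshold
        if not excluded:
            included.add(sid)
        rows.append(
            {"subject_id": sid, "miss_rate": miss_rate, "excluded": excluded}
        )
    report = pd.DataFrame(rows).set_index("subject_id")
    return included, report


def code_stay_switch(session: Sequence[TrialRecord]) -> pd.DataFrame:
    """Lag-1 stay/switch coding for one subject's session.

    One row is produced for each non-missed trial that has at least one
    earlier non-missed trial; the "previous" trial is the most recent
    non-missed one, so missed trials lengthen the lag rather than dropping
    the data.  Columns: subject_id, trial, stay (1 if the same stock was
    reached as on the previous usable trial), prev_reward_z (previous
    trial's reward, z-scored within subject over the included rows),
    same_state (+1 if the start state repeated, -1 otherwise), and their
    interaction.  A subject whose previous rewards have zero variance
    cannot be z-scored; an empty table is returned with a warning.
    """
    rows = []
    prev: Optional[TrialRecord] = None
    for rec in session:
        if rec.missed:
            continue
        if prev is not None:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial": rec.trial,
                    "stay": int(rec.stock == prev.stock),
                    "prev_reward": float(prev.reward),
                    "same_state": 1 if rec.start_state == prev.start_state else -1,
                }
            )
        prev = rec
    if len(rows) < 1:
        return _empty_stay_table()
    table = pd.DataFrame(rows)
    sd = table["prev_reward"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn(
            f"subject {session[0].subject_id}: previous rewards have zero "
            "variance; cannot z-score, subject dropped from stay analysis"
        )
        return _empty_stay_table()
    table["prev_reward_z"] = (table["prev_reward"] - table["prev_reward"].mean()) / sd
    table["interaction"] = table["prev_reward_z"] * table["same_state"]
    return table[
        ["subject_id", "trial", "stay", "prev_reward_z", "same_state", "interaction"]
    ]


def _empty_stay_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["subject_id", "trial", "stay", "prev_reward_z", "same_state", "interaction"]
    )


def build_stay_table(
    sessions: dict[str, Sequence[TrialRecord]],
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Concatenate per-subject stay tables, applying the exclusion rule."""
    if apply_exclusion:
        included, _ = exclusion_filter(sessions)
    else:
        included = set(sessions)
    tables = [
        code_stay_switch(sessions[sid]) for sid in sorted(included)
    ]
    tables = [t for t in tables if len(t) > 0]
    if not tables:
        return _empty_stay_table()
    return pd.concat(tables, ignore_index=True)


_STAY_TERMS = {
    "Intercept": "intercept",
    "prev_reward_z": "prev_reward_z",
    "same_state": "same_state",
    "interaction": "interaction",
}


def fit_stay_model(table: pd.DataFrame) -> RegressionResult:
    """Hierarchical logistic regression of stay on the lag-1 predictors.

    Fixed effects: previous reward (z), same start state (+1/-1), and their
    interaction.  Random effects: subject-level intercept and slopes,
    variances only (uncorrelated).  Estimated by maximizing the marginal
    likelihood under the Laplace approximation with lme4's ``glmer``
    (through :mod:`twostep_social.rbridge`); the method field of the result
    records the approximation.  If that fit fails, the documented fallback
    runs per-subject logistic regressions and tests each coefficient across
    subjects with a one-sample t test.
    """
    if table["subject_id"].nunique() < 2:
        raise ValueError("stay model needs at least 2 subjects")
    outcomes = table["stay"].unique()
    if len(outcomes) < 2:
        return RegressionResult(
            coefficients=_empty_coef_table(),
            converged=False,
            method="none",
            notes=f"degenerate outcome: stay is constant at {outcomes[0]} "
            "(complete separation); model not fit",
        )
    try:
        return _fit_stay_glmm(table)
    except Exception as exc:  # noqa: BLE001 - any optimizer failure routes to fallback
        result = _fit_stay_per_subject(table)
        result.notes = f"mixed-model fit failed ({exc!r}); per-subject fallback used"
        return result


def _empty_coef_table() -> pd.DataFrame:
    return pd.DataFrame(
        np.nan,
        index=list(_STAY_TERMS.values()),
        columns=["estimate", "se", "stat", "p"],
    )


def _fit_stay_glmm(table: pd.DataFrame) -> RegressionResult:
    from .rbridge import glmer_logistic

    raw = glmer_logistic(
        table[["subject_id", "stay", "prev_reward_z", "same_state", "interaction"]]
    )
    coef = pd.DataFrame(
        {
            "estimate": raw["estimate"],
            "se": raw["se"],
            "stat": raw["z"],
            "p": raw["p"],
        },
        index=raw["terms"],
    )
    rand = {
        f"{name}_var": float(v)
        for name, v in zip(raw["re_names"], raw["re_vars"])
    }
    notes = "; ".join(raw.get("messages", []))
    if raw.get("singular"):
        notes = (notes + "; " if notes else "") + (
            "singular fit: at least one random-effect variance estimated at 0"
        )
    return RegressionResult(
        coefficients=coef,
        random_variances=rand,
        converged=bool(raw["converged"]),
        method="glmer_laplace (lme4, marginal ML, uncorrelated random effects)",
        notes=notes,
    )


def _fit_stay_per_subject(table: pd.DataFrame) -> RegressionResult:
    import statsmodels.api as sm

    coefs = []
    for _, sub in table.groupby("subject_id"):
        X = sm.add_constant(
            sub[["prev_reward_z", "same_state", "interaction"]], has_constant="add"
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(sub["stay"], X).fit_regularized(
                    alpha=0.1, disp=False, maxiter=200
                )
            coefs.append(np.asarray(res.params))
        except Exception:  # noqa: BLE001 - skip inseparable subjects
            continue
    coefs = np.array(coefs)
    if len(coefs) < 2:
        return RegressionResult(
            coefficients=_empty_coef_table(), converged=False,
            method="per_subject_logistic", notes="too few fit-able subjects",
        )
    est = coefs.mean(axis=0)
    se = coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs))
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df=len(coefs) - 1)
    coef = pd.DataFrame(
        {"estimate": est, "se": se, "stat": t, "p": p},
        index=list(_STAY_TERMS.values()),
    )
    return RegressionResult(
        coefficients=coef,
        random_variances={
            f"{name}_var": float(v)
            for name, v in zip(_STAY_TERMS.values(), coefs.var(axis=0, ddof=1))
        },
        converged=True,
        method="per_subject_logistic",
    )


def stay_probability_table(
    sessions: dict[str, Sequence[TrialRecord]],
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Mean stay probability in the 2x2 (reward split x same state) design.

    For each subject the previous reward is median-split (within subject),
    giving four cells: high/low previous reward crossed with same/different
    start state.  Returns cell means over subjects with within-subject
    adjusted standard errors (subject means removed before computing the SE,
    with the Morey small-sample correction for the number of cells).
    """
    if apply_exclusion:
        included, _ = exclusion_filter(sessions)
    else:
        included = set(sessions)
    per_subject = []
    for sid in sorted(included):
        t = code_stay_switch(sessions[sid])
        if len(t) == 0:
            continue
        raw = t.copy()
        median = raw["prev_reward_z"].median()
        raw["high_reward"] = raw["prev_reward_z"] > median
        cells = {}
        for high in (False, True):
            for same in (-1, 1):
                mask = (raw["high_reward"] == high) & (raw["same_state"] == same)
                if mask.sum() > 0:
                    cells[(high, same)] = float(raw.loc[mask, "stay"].mean())
        if cells:
            per_subject.append((sid, cells))
    keys = [(h, s) for h in (False, True) for s in (-1, 1)]
    cell_values = {k: [] for k in keys}
    # within-subject adjustment: remove each subject's own mean
    for sid, cells in per_subject:
        sub_mean = np.mean(list(cells.values()))
        for k, v in cells.items():
            cell_values[k].append((v, v - sub_mean))
    rows = []
    n_cells = len(keys)
    morey = np.sqrt(n_cells / (n_cells - 1))
    for high, same in keys:
        vals = cell_values[(high, same)]
        raw_vals = np.array([v for v, _ in vals])
        adj_vals = np.array([a for _, a in vals])
        n = len(vals)
        se = (
            morey * adj_vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        )
        rows.append(
            {
                "prev_reward": "high" if high else "low",
                "same_state": "same" if same == 1 else "different",
                "stay_prob": raw_vals.mean() if n else np.nan,
                "se_within": se,
                "n_subjects": n,
            }
        )
    return pd.DataFrame(rows)
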