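"""Post-task liking regression on latent advisor values.

After the learning phase, participants rate how much they like each of the
four advisors on a 1-7 scale.  The analysis regresses those ratings on each
advisor's final model-free and model-based value (extracted from the fitted
learner and z-scored within subject), the subject's model-based weight w
(z-scored between subjects), and the w-by-value interactions, in a
hierarchical linear model with subject-level random intercept and slopes.
Simple effects of model-free value at a given percentile of w are obtained
by recentering w before the interaction terms are built and refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .results import RegressionResult

__all__ = [
    "LikingRecord",
    "build_attitude_design",
    "fit_liking_model",
    "simple_effects",
]

RATING_MIN, RATING_MAX = 1, 7

_FIXED_TERMS = ["intercept", "mf_value_z", "mb_value_z", "w_z", "w_x_mf", "w_x_mb"]


@dataclass(frozen=True)
class LikingRecord:
    """One liking rating of one advisor by one subject (1-7 scale)."""

    subject_id: str
    advisor_id: int
    rating: int

    def __post_init__(self) -> None:
        if not RATING_MIN <= self.rating <= RATING_MAX:
            raise ValueError(
                f"rating {self.rating} outside [{RATING_MIN}, {RATING_MAX}]"
            )
        if not 0 <= self.advisor_id <= 3:
            raise ValueError(f"advisor_id {self.advisor_id} outside 0..3")


def _zscore(x: np.ndarray) -> Optional[np.ndarray]:
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    return (x - np.mean(x)) / sd


def build_attitude_design(
    fits: Mapping[str, FitResult],
    likings: Sequence[LikingRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Join ratings to latent values and standardize the regressors.

    The value regressors are z-scored within subject (over the four
    advisors) and w is z-scored between subjects; the interaction columns
    are products of the standardized columns.  Subjects with zero variance
    in either value regressor cannot be standardized and are dropped with a
    warning; zero variance in w across subjects is an error.

    Besides the model columns the design retains ``w_raw`` so that simple
    effects can recenter w on its raw [0, 1] scale.
    """
    if isinstance(likings, pd.DataFrame):
        liking_df = likings.copy()
    else:
        liking_df = pd.DataFrame(
            [
                {"subject_id": r.subject_id, "advisor_id": r.advisor_id, "rating": r.rating}
                for r in likings
            ]
        )
    missing = set(liking_df["subject_id"]) - set(fits)
    if missing:
        raise ValueError(f"liking rows without a matching fit: {sorted(missing)}")

    rows = []
    for sid, sub in liking_df.groupby("subject_id"):
        fit = fits[sid]
        adv = sub["advisor_id"].to_numpy()
        mf_z = _zscore(fit.final_q_mf)
        mb_z = _zscore(fit.final_q_mb)
        if mf_z is None or mb_z is None:
            warnings.warn(
                f"subject {sid}: zero variance in a value regressor; dropped "
                "from attitude analysis"
            )
            continue
        for advisor_id, rating in zip(adv, sub["rating"].to_numpy()):
            rows.append(
                {
                    "subject_id": sid,
                    "advisor_id": int(advisor_id),
                    "rating": float(rating),
                    "mf_value_z": float(mf_z[advisor_id]),
                    "mb_value_z": float(mb_z[advisor_id]),
                    "w_raw": float(fit.map_params.w),
                }
            )
    design = pd.DataFrame(rows)
    if design.empty:
        raise ValueError("no usable subjects in attitude design")
    w_by_subject = design.groupby("subject_id")["w_raw"].first()
    w_sd = w_by_subject.std(ddof=1)
    if not np.isfinite(w_sd) or w_sd <= 1e-12:
        raise ValueError("w has zero variance across subjects; w_z undefined")
    w_mean = w_by_subject.mean()
    design["w_z"] = (design["w_raw"] - w_mean) / w_sd
    design["w_x_mf"] = design["w_z"] * design["mf_value_z"]
    design["w_x_mb"] = design["w_z"] * design["mb_value_z"]
    return design


def fit_liking_model(design: pd.DataFrame) -> RegressionResult:
    """Hierarchical linear regression of liking on the five predictors.

    Random effects are subject-level variances (no correlations) for the
    intercept and the within-subject-varying predictors; w itself is
    constant within subject, so a random w slope would be confounded with
    the random intercept and is not included.  Fit by REML (statsmodels
    MixedLM with variance components).  The test statistics are t values
    with a containment-style approximate df, recorded in the result.
    """
    if design["subject_id"].nunique() < 2:
        raise ValueError("liking model needs at least 2 subjects")
    try:
        return _fit_liking_mixed(design)
    except Exception as exc:  # noqa: BLE001 - route optimizer failures to fallback
        result = _fit_liking_ols(design)
        result.notes = f"mixed-model fit failed ({exc!r}); cluster-robust OLS used"
        return result


def _fit_liking_mixed(design: pd.DataFrame) -> RegressionResult:
    import statsmodels.formula.api as smf

    vc_terms = ["mf_value_z", "mb_value_z", "w_x_mf", "w_x_mb"]
    notes = ""

    def _fit_with(terms):
        vc = {t: f"0 + {t}" for t in terms}
        model = smf.mixedlm(
            "rating ~ mf_value_z + mb_value_z + w_z + w_x_mf + w_x_mb",
            design,
            groups=design["subject_id"],
            re_formula="1",
            vc_formula=vc if vc else None,
        )
        # variance components often sit at the zero boundary here; the
        # derivative-free Powell search is robust there
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method="powell")
            if not fit.converged:
                fit = model.fit(reml=True)
        return model, fit

    model, fit = _fit_with(vc_terms)
    if not np.isfinite(fit.bse[model.exog_names].to_numpy()).all():
        # a variance component estimated at exactly 0 makes the Hessian
        # singular (NaN standard errors): drop those components and refit
        kept = [
            t for t, v in zip(model.exog_vc.names, np.asarray(fit.vcomp))
            if v > 1e-8
        ]
        notes = (
            "random-effect variances at 0 dropped for SEs: "
            + ", ".join(sorted(set(vc_terms) - set(kept)))
        )
        model, fit = _fit_with(kept)
        vc_terms = kept
    n_obs = len(design)
    n_subjects = design["subject_id"].nunique()
    k_fixed = len(_FIXED_TERMS)
    df = max(n_obs - n_subjects - (k_fixed - 1), 1)
    names = [n for n in fit.params.index if n in model.exog_names]
    est = np.array([fit.params[n] for n in names])
    se = np.array([fit.bse[n] for n in names])
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    coef = pd.DataFrame(
        {"estimate": est, "se": se, "stat": t, "p": p},
        index=["intercept" if n == "Intercept" else n for n in names],
    )
    rand = {"intercept_var": float(fit.cov_re.iloc[0, 0])}
    for name, value in zip(model.exog_vc.names, np.asarray(fit.vcomp)):
        rand[f"{name}_var"] = float(value)
    rand["residual_var"] = float(fit.scale)
    return RegressionResult(
        coefficients=coef,
        random_variances=rand,
        converged=bool(fit.converged),
        method=f"reml_mixedlm (containment df={df})",
        notes=notes,
    )


def _fit_liking_ols(design: pd.DataFrame) -> RegressionResult:
    import statsmodels.formula.api as smf

    fit = smf.ols(
        "rating ~ mf_value_z + mb_value_z + w_z + w_x_mf + w_x_mb", design
    ).fit(cov_type="cluster", cov_kwds={"groups": design["subject_id"]})
    est = fit.params.to_numpy()
    se = fit.bse.to_numpy()
    t = est / se
    df = design["subject_id"].nunique() - 1
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    coef = pd.DataFrame(
        {"estimate": est, "se": se, "stat": t, "p": p},
        index=["intercept" if n == "Intercept" else n for n in fit.params.index],
    )
    return RegressionResult(
        coefficients=coef, converged=True, method="ols_cluster_robust"
    )


def simple_effects(
    design: pd.DataFrame,
    percentile: Optional[float] = None,
    center: Optional[float] = None,
) -> dict:
    """Model-free value effect at a chosen point of the w distribution.

    Recenters w at either the given raw-scale ``center`` or the cohort's
    ``percentile`` of raw fitted w (linear interpolation between order
    statistics), keeping the original between-subject SD as the scale, then
    rebuilds the interaction columns and refits the liking model.  The
    returned dict reports the model-free value coefficient at that center
    together with the center used and the full refit result.
    """
    if (percentile is None) == (center is None):
        raise ValueError("specify exactly one of percentile or center")
    w_by_subject = design.groupby("subject_id")["w_raw"].first()
    if percentile is not None:
        if not 0.0 < percentile < 1.0:
            raise ValueError("percentile must be in (0, 1)")
        center = float(np.quantile(w_by_subject.to_numpy(), percentile))
    w_sd = float(w_by_subject.std(ddof=1))
    recentered = design.copy()
    recentered["w_z"] = (recentered["w_raw"] - center) / w_sd
    recentered["w_x_mf"] = recentered["w_z"] * recentered["mf_value_z"]
    recentered["w_x_mb"] = recentered["w_z"] * recentered["mb_value_z"]
    result = fit_liking_model(recentered)
    row = result.coefficients.loc["mf_value_z"]
    return {
        "center_w": float(center),
        "estimate": float(row["estimate"]),
        "se": float(row["se"]),
        "stat": float(row["stat"]),
        "p": float(row["p"]),
        "result": result,
    }
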