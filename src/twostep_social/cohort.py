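"""Synthetic-cohort generator: complete studies with known ground truth.

Emulates the study's structure — a cohort of participants (default 65, the
study's planned sample), each completing 150 two-step trials, optionally
missing trials at a configurable rate, and afterwards rating each of the
four advisors on a 1-7 liking scale.  Agents are hybrid learners whose
parameters are drawn from configurable distributions; the default w
distribution is a Beta with mean 0.83 (the group mean reported for this
task framing) and meaningful between-subject spread.  Liking ratings are
generated from the agents' *true* final latent values, so any downstream
estimation error is attributable to the fitting stage, not the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agent import AgentParameters, simulate_agent
from .attitudes import RATING_MAX, RATING_MIN, LikingRecord
from .fitting import replay_final_values
from .task import TaskConfig, TrialRecord

__all__ = [
    "CohortSpec",
    "LikingCoeffs",
    "sample_agent_parameters",
    "inject_missed_trials",
    "generate_liking",
    "generate_study",
    "simulate_session",
]

# parameter spec: point value, ("beta", a, b), ("uniform", lo, hi),
# ("normal", mu, sd) for unbounded parameters only, or a callable rng -> float
ParamSpec = Union[float, tuple, Callable[[np.random.Generator], float]]

_BOUNDED = {"alpha": (0.0, 1.0), "lam": (0.0, 1.0), "w": (0.0, 1.0), "beta": (0.0, math.inf)}


@dataclass(frozen=True)
class LikingCoeffs:
    """Generative coefficients of the liking model, on the rating scale.

    rating = intercept + b_mb * z(q_mb)
             + (b_mf_base + b_mf_w_slope * (1 - w)) * z(q_mf) + noise

    The model-free contribution grows as w falls: agents who weight
    model-free learning more also like high-model-free-value advisors more,
    the moderation direction observed in this task.
    """

    intercept: float = 4.0
    b_mb: float = 0.5
    b_mf_base: float = 0.5
    b_mf_w_slope: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _default_params() -> dict:
    return {
        "alpha": 0.5,
        "beta": 4.2416,
        "lam": 0.5,
        "w": ("beta", 2.49, 0.51),  # mean 0.83, SD ~0.19
        "pi": 0.15,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic study."""

    n_subjects: int = 65
    params: dict = field(default_factory=_default_params)
    miss_rate: float = 0.0
    liking_coeffs: LikingCoeffs = field(default_factory=LikingCoeffs)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must be in [0, 1)")
        for name in ("alpha", "beta", "lam", "w", "pi"):
            if name not in self.params:
                raise ValueError(f"missing parameter spec for {name}")
            _validate_param_spec(name, self.params[name])


def _validate_param_spec(name: str, spec: ParamSpec) -> None:
    bounds = _BOUNDED.get(name)
    if isinstance(spec, (int, float)):
        if bounds and not bounds[0] <= spec <= bounds[1]:
            raise ValueError(f"point value {spec} for {name} outside bounds {bounds}")
        return
    if callable(spec):
        return
    family = spec[0]
    if family == "beta":
        if name == "pi":
            return  # support [0,1] is fine for an unbounded parameter too
        if bounds != (0.0, 1.0) and name != "beta":
            raise ValueError(f"beta distribution unsuitable for {name}")
        return
    if family == "uniform":
        lo, hi = float(spec[1]), float(spec[2])
        if bounds and not (bounds[0] <= lo and hi <= bounds[1]):
            raise ValueError(
                f"uniform({lo}, {hi}) support for {name} escapes bounds {bounds}"
            )
        return
    if family == "normal":
        if bounds is not None:
            raise ValueError(
                f"normal distribution has unbounded support; invalid for "
                f"bounded parameter {name}"
            )
        return
    if family == "gamma":
        if name in ("alpha", "lam", "w"):
            raise ValueError(f"gamma support escapes [0,1] bounds for {name}")
        return
    raise ValueError(f"unknown distribution family {family!r} for {name}")


def _draw(spec: ParamSpec, rng: np.random.Generator) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if callable(spec):
        return float(spec(rng))
    family = spec[0]
    if family == "beta":
        return float(rng.beta(spec[1], spec[2]))
    if family == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if family == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if family == "gamma":
        return float(rng.gamma(spec[1], spec[2]))
    raise ValueError(f"unknown distribution family {family!r}")


def sample_agent_parameters(
    spec: CohortSpec, rng: np.random.Generator
) -> list[AgentParameters]:
    """Draw one parameter vector per subject from the cohort spec."""
    out = []
    for _ in range(spec.n_subjects):
        out.append(
            AgentParameters(
                **{name: _draw(spec.params[name], rng) for name in
                   ("alpha", "beta", "lam", "w", "pi")}
            )
        )
    return out


def simulate_session(
    params: AgentParameters,
    config: TaskConfig,
    miss_rate: float,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Simulate one session with trials independently missed at ``miss_rate``."""
    mask = None
    if miss_rate > 0:
        mask = rng.random(config.n_trials) < miss_rate
    return simulate_agent(params, config, rng, subject_id=subject_id, miss_mask=mask)


def inject_missed_trials(
    session: Sequence[TrialRecord],
    miss_rate: float,
    rng: np.random.Generator,
    params: Optional[AgentParameters] = None,
    config: Optional[TaskConfig] = None,
) -> list[TrialRecord]:
    """Mark trials as missed at rate ``miss_rate`` and regenerate the session.

    Missed trials must cause no value updates, so a session with injected
    misses cannot be produced by blanking fields of an existing session —
    the agent's trajectory after a miss differs.  When any trial is flagged,
    the session is therefore re-simulated with the miss mask applied, which
    requires the generating ``params`` and ``config``.  With miss_rate = 0
    (or when no trial happens to be flagged) the input session is returned
    unchanged.
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must be in [0, 1]")
    n = len(session)
    mask = rng.random(n) < miss_rate
    if not mask.any():
        return list(session)
    if params is None or config is None:
        raise ValueError(
            "re-simulation after miss injection requires params and config"
        )
    return simulate_agent(
        params, config, rng, subject_id=session[0].subject_id, miss_mask=mask
    )


def generate_liking(
    truth: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[LikingRecord]:
    """Generate 1-7 liking ratings from TRUE final latent values.

    ``truth`` needs one row per subject with columns ``subject_id``, ``w``,
    ``final_q_mf_0..3`` and ``final_q_mb_0..3``.  Values are z-scored within
    subject (a zero-variance regressor contributes 0), combined with the
    generative coefficients, perturbed by Gaussian noise, rounded
    half-away-from-zero and clamped to the 1-7 scale.
    """
    c = spec.liking_coeffs
    records: list[LikingRecord] = []
    for _, row in truth.iterrows():
        q_mf = np.array([row[f"final_q_mf_{i}"] for i in range(4)], dtype=float)
        q_mb = np.array([row[f"final_q_mb_{i}"] for i in range(4)], dtype=float)
        mf_z = _z_or_zero(q_mf)
        mb_z = _z_or_zero(q_mb)
        b_mf = c.b_mf_base + c.b_mf_w_slope * (1.0 - float(row["w"]))
        for adv in range(4):
            mu = c.intercept + c.b_mb * mb_z[adv] + b_mf * mf_z[adv]
            value = mu + rng.normal(0.0, c.noise_sd)
            rating = math.floor(value + 0.5) if value >= 0 else math.ceil(value - 0.5)
            rating = int(min(max(rating, RATING_MIN), RATING_MAX))
            records.append(
                LikingRecord(
                    subject_id=str(row["subject_id"]), advisor_id=adv, rating=rating
                )
            )
    return records


def _z_or_zero(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_study(
    spec: CohortSpec,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study: trials, liking ratings, ground truth.

    Returns (trials, liking, agents) DataFrames in the pipeline's file
    formats.  ``agents`` carries each subject's true parameters and true
    final latent values, sufficient to score every downstream stage.  The
    output is fully reproducible from (spec, config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = sample_agent_parameters(spec, rng)
    trial_rows = []
    truth_rows = []
    for i, p in enumerate(params):
        sid = f"s{i:03d}"
        session = simulate_session(p, config, spec.miss_rate, rng, subject_id=sid)
        for rec in session:
            trial_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial": rec.trial,
                    "start_state": rec.start_state,
                    "choice": rec.choice,
                    "advisor_id": rec.advisor_id,
                    "stock": rec.stock,
                    "reward": rec.reward,
                    "missed": int(rec.missed),
                }
            )
        non_missed = [r for r in session if not r.missed]
        truth = {
            "subject_id": sid,
            "alpha": p.alpha, "beta": p.beta, "lam": p.lam, "w": p.w, "pi": p.pi,
        }
        if non_missed:
            final_mf, final_mb = replay_final_values(p, session, config)
        else:
            mid = 0.5 * (config.reward_min + config.reward_max)
            final_mf = final_mb = np.full(config.n_advisors, mid)
        for adv in range(config.n_advisors):
            truth[f"final_q_mf_{adv}"] = float(final_mf[adv])
            truth[f"final_q_mb_{adv}"] = float(final_mb[adv])
        truth_rows.append(truth)
    agents = pd.DataFrame(truth_rows)
    liking_records = generate_liking(agents, spec, rng)
    liking = pd.DataFrame(
        [
            {"subject_id": r.subject_id, "advisor_id": r.advisor_id, "rating": r.rating}
            for r in liking_records
        ]
    )
    trials = pd.DataFrame(trial_rows)
    return trials, liking, agents
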