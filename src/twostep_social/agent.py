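"""Hybrid model-free / model-based learner for the two-step advisor task.

The agent mixes two controllers when choosing an advisor:

* a *model-free* controller caching values for advisors at the first stage
  (one value per (start_state, slot) cell) and for stocks at the second
  stage, updated by temporal-difference learning with learning rate
  ``alpha`` and eligibility trace ``lam``;
* a *model-based* controller that evaluates each advisor prospectively by
  looking the advisor's stock up in the (known, deterministic) transition
  map and reading off that stock's current second-stage value.

The weighting parameter ``w`` in [0, 1] sets the relative influence of the
two controllers in the softmax choice rule (0 = purely model-free,
1 = purely model-based); ``beta`` is the inverse temperature and ``pi`` a
perseveration bonus for repeating the previous first-stage response.
There is no second-stage choice in this task variant (the second stage is
revealed by a single keypress), so the policy covers first-stage choices
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task import (
    TaskConfig,
    TrialRecord,
    advisor_identity,
    emit_payout,
    generate_start_state_sequence,
    initial_walk_state,
    step_reward_walk,
    transition,
)

__all__ = [
    "AgentParameters",
    "ValueState",
    "mb_values",
    "choice_probabilities",
    "update_values",
    "simulate_agent",
]


@dataclass(frozen=True)
class AgentParameters:
    """Parameter vector of the hybrid learner.

    alpha : learning rate in [0, 1]
    beta  : softmax inverse temperature, >= 0
    lam   : eligibility-trace weight in [0, 1]
    w     : model-based weight in [0, 1]
    pi    : perseveration (response-stickiness) strength, unbounded
    """

    alpha: float
    beta: float
    lam: float
    w: float
    pi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be non-negative")
        for name in ("alpha", "beta", "lam", "w", "pi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class ValueState:
    """Cached values: q_mf per (start_state, slot), q_stage2 per stock."""

    q_mf: np.ndarray  # shape (2, 2)
    q_stage2: np.ndarray  # shape (2,)

    @classmethod
    def initial(cls, config: TaskConfig, value: Optional[float] = None) -> "ValueState":
        """Start all values at the payout-range midpoint (unbiased default)."""
        if value is None:
            value = 0.5 * (config.reward_min + config.reward_max)
        return cls(
            q_mf=np.full((config.n_start_states, 2), float(value)),
            q_stage2=np.full(config.n_stocks, float(value)),
        )

    def copy(self) -> "ValueState":
        return ValueState(q_mf=self.q_mf.copy(), q_stage2=self.q_stage2.copy())


def mb_values(vs: ValueState, config: TaskConfig) -> np.ndarray:
    """Model-based advisor values: look each advisor's stock up in the map.

    Returns a (n_start_states, 2) array; advisors leading to the same stock
    necessarily share a model-based value.
    """
    out = np.empty_like(vs.q_mf)
    for s in range(config.n_start_states):
        for a in range(2):
            out[s, a] = vs.q_stage2[transition(s, a, config)]
    return out


def choice_probabilities(
    vs: ValueState,
    p: AgentParameters,
    state: int,
    prev_slot: Optional[int],
    config: TaskConfig,
) -> np.ndarray:
    """Softmax policy over the two advisor slots of ``state``.

    Net value V(a) = w * Q_MB(state, a) + (1 - w) * Q_MF(state, a); the
    logit of slot a is beta * V(a) + pi * 1[a == prev_slot].  The max logit
    is subtracted before exponentiation to guard against overflow.
    """
    q_mb = mb_values(vs, config)
    logits = np.empty(2)
    for a in range(2):
        v = p.w * q_mb[state, a] + (1.0 - p.w) * vs.q_mf[state, a]
        logits[a] = p.beta * v + (p.pi if a == prev_slot else 0.0)
    logits -= logits.max()
    ex = np.exp(logits)
    return ex / ex.sum()


def update_values(
    vs: ValueState, trial: TrialRecord, p: AgentParameters
) -> ValueState:
    """TD(lambda)-style model-free update after one completed trial.

    With s = start_state, a = choice, k = stock, r = reward:

        delta1 = q_stage2[k] - q_mf[s, a]        (stage-1 prediction error)
        q_mf[s, a]  += alpha * delta1
        delta2 = r - q_stage2[k]                 (reward prediction error)
        q_stage2[k] += alpha * delta2
        q_mf[s, a]  += alpha * lam * delta2      (eligibility trace)

    delta1 uses q_stage2 *before* its reward update.  Missed trials carry no
    choice or reward and leave the values untouched.
    """
    if trial.missed:
        return vs.copy()
    out = vs.copy()
    s, a, k = trial.start_state, trial.choice, trial.stock
    delta1 = out.q_stage2[k] - out.q_mf[s, a]
    out.q_mf[s, a] += p.alpha * delta1
    delta2 = trial.reward - out.q_stage2[k]
    out.q_stage2[k] += p.alpha * delta2
    out.q_mf[s, a] += p.alpha * p.lam * delta2
    return out


def simulate_agent(
    p: AgentParameters,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    miss_mask: Optional[np.ndarray] = None,
) -> list[TrialRecord]:
    """Forward-simulate one full session of the task.

    Per trial: sample the (balanced, permuted) start state, choose an advisor
    by the softmax policy, transition deterministically to the stock, pay out
    from the current walk position, update values, then advance the walk.
    Trials flagged in ``miss_mask`` are recorded as missed: no choice is
    made, no values update, and the perseveration chain is broken; the
    reward walk still advances (task time passes regardless of responding).
    """
    states = generate_start_state_sequence(config, rng)
    walk = initial_walk_state(config, rng)
    vs = ValueState.initial(config)
    prev_slot: Optional[int] = None
    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        s = int(states[t])
        if miss_mask is not None and miss_mask[t]:
            records.append(
                TrialRecord(
                    subject_id=subject_id, trial=t, start_state=s,
                    choice=None, advisor_id=None, stock=None, reward=None,
                    missed=True,
                )
            )
            prev_slot = None
        else:
            probs = choice_probabilities(vs, p, s, prev_slot, config)
            a = int(rng.random() < probs[1])
            k = transition(s, a, config)
            r = emit_payout(walk, k, config)
            rec = TrialRecord(
                subject_id=subject_id, trial=t, start_state=s,
                choice=a, advisor_id=advisor_identity(s, a), stock=k,
                reward=r, missed=False,
            )
            records.append(rec)
            vs = update_values(vs, rec, p)
            prev_slot = a
        walk = step_reward_walk(walk, config, rng)
    return records
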