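"""Structure and stochastic reward process of the social two-step task.

The task has two first-stage states (each showing a distinct pair of
financial advisors) and two second-stage states (the "Axiom" and "Zephyr"
stocks).  Choosing an advisor transitions *deterministically* to the stock
that advisor invests in; within each advisor pair one advisor leads to each
stock, so both stocks are reachable from both first-stage states.  Stock
payouts range from 0 to 9 points and drift over trials as a Gaussian random
walk with reflecting bounds, which keeps agents learning throughout the
session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "RewardWalkState",
    "TrialRecord",
    "step_reward_walk",
    "emit_payout",
    "generate_start_state_sequence",
    "transition",
    "advisor_identity",
    "DEFAULT_TRANSITION_MAP",
]

# (start_state, advisor_slot) -> stock.  Within each start state one slot
# leads to each stock, and each stock is reachable from both states.
DEFAULT_TRANSITION_MAP: dict[tuple[int, int], int] = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 0,
    (1, 1): 1,
}


@dataclass(frozen=True)
class TaskConfig:
    """Structural and stochastic constants of the task.

    Parameters
    ----------
    n_trials
        Number of main-task trials (150 in the study design), split evenly
        between the first-stage states.
    walk_sd
        Standard deviation, in points, of the per-step Gaussian increment of
        each stock's latent value (2.0 in the study design).
    reward_min, reward_max
        Reflecting bounds of the latent reward walk (0 and 9 points).
    transition_map
        Deterministic (start_state, advisor_slot) -> stock mapping.
    reward_init
        Optional fixed initial latent value per stock; when None the initial
        values are drawn uniformly on [reward_min, reward_max].
    integer_payouts
        When True (default), displayed payouts are the latent value rounded
        half-away-from-zero to an integer; when False the continuous latent
        value is paid out.
    """

    n_trials: int = 150
    n_start_states: int = 2
    n_advisors: int = 4
    n_stocks: int = 2
    walk_sd: float = 2.0
    reward_min: float = 0.0
    reward_max: float = 9.0
    transition_map: dict[tuple[int, int], int] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_MAP)
    )
    reward_init: Optional[Sequence[float]] = None
    integer_payouts: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.walk_sd <= 0:
            raise ValueError(f"walk_sd must be positive, got {self.walk_sd}")
        if not self.reward_min < self.reward_max:
            raise ValueError("reward_min must be strictly below reward_max")
        if self.n_trials % self.n_start_states != 0:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by "
                f"n_start_states={self.n_start_states}"
            )
        for state in range(self.n_start_states):
            stocks = sorted(
                self.transition_map[(state, slot)] for slot in range(2)
            )
            if stocks != list(range(self.n_stocks)):
                raise ValueError(
                    "transition_map must map the two slots of each start "
                    f"state onto distinct stocks; state {state} maps to {stocks}"
                )
        if self.reward_init is not None:
            if len(self.reward_init) != self.n_stocks:
                raise ValueError("reward_init must give one value per stock")
            for v in self.reward_init:
                if not (self.reward_min <= v <= self.reward_max):
                    raise ValueError("reward_init outside reward bounds")


@dataclass(frozen=True)
class RewardWalkState:
    """Latent (continuous) value of each stock at one point in the session."""

    latent_values: tuple[float, ...]
    trial_index: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """One first-stage choice and its outcome.

    On a missed trial (no response before the deadline) ``choice``,
    ``advisor_id``, ``stock`` and ``reward`` are all None and ``missed`` is
    True; no reward is delivered and no learning occurs.
    """

    subject_id: str
    trial: int
    start_state: int
    choice: Optional[int]
    advisor_id: Optional[int]
    stock: Optional[int]
    reward: Optional[float]
    missed: bool = False

    def __post_init__(self) -> None:
        blank = (self.choice is None, self.stock is None, self.reward is None)
        if self.missed and not all(blank):
            raise ValueError("missed trial must have no choice/stock/reward")
        if not self.missed and any(blank):
            raise ValueError("non-missed trial must record choice/stock/reward")


def advisor_identity(start_state: int, slot: int) -> int:
    """Global advisor id in {0..3} from (start_state, slot)."""
    return 2 * start_state + slot


def initial_walk_state(config: TaskConfig, rng: np.random.Generator) -> RewardWalkState:
    """Initial latent stock values: fixed from config or uniform on the range."""
    if config.reward_init is not None:
        values = tuple(float(v) for v in config.reward_init)
    else:
        values = tuple(
            float(rng.uniform(config.reward_min, config.reward_max))
            for _ in range(config.n_stocks)
        )
    return RewardWalkState(latent_values=values, trial_index=0)


def _reflect(x: float, lo: float, hi: float) -> float:
    # mirror at the violated bound, repeated until inside [lo, hi]
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        if x < lo:
            x = 2.0 * lo - x
    return x


def step_reward_walk(
    state: RewardWalkState,
    config: TaskConfig,
    rng: np.random.Generator,
    return_increments: bool = False,
):
    """Advance every stock's latent value by one Gaussian random-walk step.

    Each stock receives an independent N(0, walk_sd) increment and the result
    is reflected into [reward_min, reward_max] by mirroring at the violated
    bound.  With ``return_increments`` the raw (pre-reflection) increments are
    returned as well, which is useful for calibration checks.
    """
    if config.walk_sd <= 0:
        raise ValueError("walk_sd must be positive")
    increments = rng.normal(0.0, config.walk_sd, size=len(state.latent_values))
    new_values = tuple(
        _reflect(v + dv, config.reward_min, config.reward_max)
        for v, dv in zip(state.latent_values, increments)
    )
    new_state = RewardWalkState(
        latent_values=new_values, trial_index=state.trial_index + 1
    )
    if return_increments:
        return new_state, increments
    return new_state


def emit_payout(
    state: RewardWalkState,
    stock: int,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Payout of ``stock`` at the walk's current position.

    Integer payouts round half-away-from-zero (6.5 -> 7) and are clipped to
    the point range; continuous payouts return the latent value unchanged.
    """
    if not 0 <= stock < config.n_stocks:
        raise ValueError(f"invalid stock id {stock}")
    value = state.latent_values[stock]
    if not config.integer_payouts:
        return float(value)
    rounded = math.floor(value + 0.5) if value >= 0 else math.ceil(value - 0.5)
    return float(min(max(rounded, config.reward_min), config.reward_max))


def generate_start_state_sequence(
    config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random permutation of an exactly balanced start-state multiset."""
    if config.n_trials % config.n_start_states != 0:
        raise ValueError("n_trials must be divisible by n_start_states")
    per_state = config.n_trials // config.n_start_states
    seq = np.repeat(np.arange(config.n_start_states), per_state)
    return rng.permutation(seq)


def transition(start_state: int, choice: int, config: TaskConfig) -> int:
    """Deterministic advisor -> stock transition (pure table lookup)."""
    key = (start_state, choice)
    if key not in config.transition_map:
        raise ValueError(f"invalid (start_state, choice) = {key}")
    return config.transition_map[key]


def config_from_dict(d: dict) -> TaskConfig:
    """Build a TaskConfig from a plain (e.g. YAML-loaded) mapping.

    ``transition_map`` may be given as a mapping with "state,slot" string
    keys, as produced by :func:`config_to_dict`.
    """
    d = dict(d)
    tm = d.get("transition_map")
    if tm is not None and not isinstance(next(iter(tm)), tuple):
        d["transition_map"] = {
            tuple(int(x) for x in k.split(",")): int(v) for k, v in tm.items()
        }
    return TaskConfig(**d)


def config_to_dict(config: TaskConfig) -> dict:
    """Plain-dict form of a TaskConfig, safe for YAML round-tripping."""
    d = {
        "n_trials": config.n_trials,
        "n_start_states": config.n_start_states,
        "n_advisors": config.n_advisors,
        "n_stocks": config.n_stocks,
        "walk_sd": config.walk_sd,
        "reward_min": config.reward_min,
        "reward_max": config.reward_max,
        "transition_map": {
            f"{s},{a}": v for (s, a), v in config.transition_map.items()
        },
        "integer_payouts": config.integer_payouts,
    }
    if config.reward_init is not None:
        d["reward_init"] = list(config.reward_init)
    if config.seed is not None:
        d["seed"] = config.seed
    return d
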