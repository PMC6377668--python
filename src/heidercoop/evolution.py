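"""Prisoner's-Dilemma payoffs and the frequency-dependent Moran process.

In each interaction a cooperator pays ``c`` and delivers ``b > c`` to its
partner; defection is free and yields nothing.  Payoffs accumulate over the
``i`` interactions of a generation, and at the generation boundary one
uniformly chosen agent revises its strategy: with probability ``u`` it
mutates to a uniformly random strategy from the pool, otherwise it adopts
the strategy of an agent drawn with probability proportional to
``exp(payoff)`` (itself included, so it may re-adopt its own strategy).
Summed over strategies this is exactly the textbook frequency-dependent
Moran transition kernel with exponential fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import Action, Strategy

__all__ = [
    "PayoffParams",
    "MoranParams",
    "accrue_payoff",
    "adoption_probabilities",
    "moran_update",
]


@dataclass(frozen=True)
class PayoffParams:
    """Prisoner's-Dilemma parameters: b = benefit to partner, c = cost of C."""

    b: float = 4.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("b and c must be non-negative")
        if not self.c < self.b:
            raise ValueError(f"Prisoner's Dilemma requires c < b, got c={self.c}, b={self.b}")


@dataclass(frozen=True)
class MoranParams:
    """Moran-update parameters: mutation probability and reachable strategies."""

    u: float = 0.01
    strategy_pool: Sequence[Strategy] = (
        Strategy.HEIDER,
        Strategy.FRIEND,
        Strategy.DEFECTOR,
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"mutation probability must be in [0, 1], got {self.u}")
        pool = tuple(Strategy(s) for s in self.strategy_pool)
        if not pool:
            raise ValueError("strategy pool must not be empty")
        object.__setattr__(self, "strategy_pool", pool)


def accrue_payoff(
    a_x: Action, a_y: Action, params: PayoffParams
) -> tuple[float, float]:
    """Payoff increments (for x, for y) from one action pair."""
    a_x, a_y = Action(a_x), Action(a_y)
    pi_x = params.b * (a_y == Action.C) - params.c * (a_x == Action.C)
    pi_y = params.b * (a_x == Action.C) - params.c * (a_y == Action.C)
    return float(pi_x), float(pi_y)


def adoption_probabilities(
    payoffs: np.ndarray, strategies: np.ndarray
) -> dict[Strategy, float]:
    """Probability that the revising agent adopts each present strategy.

    ``P(adopt X) = sum_{i: strategy_i = X} exp(pi_i) / sum_j exp(pi_j)``.
    Exponentials are max-shifted first; the ratio is unchanged (the form is
    shift-invariant) and the computation cannot overflow for any payoff
    scale the parameter grids reach.
    """
    payoffs = np.asarray(payoffs, dtype=float)
    strategies = np.asarray(strategies)
    w = np.exp(payoffs - payoffs.max())
    total = w.sum()
    return {
        Strategy(s): float(w[strategies == s].sum() / total)
        for s in np.unique(strategies)
    }


def moran_update(
    state,
    params: MoranParams,
    rng: np.random.Generator,
    *,
    reset_on_adoption: str = "change",
):
    """One Moran strategy revision over a :class:`SimulationState`.

    A uniformly chosen focal agent mutates (probability ``u``) to a uniform
    strategy from the pool, or imitates an agent drawn proportionally to
    ``exp(payoff)``.  Depending on ``reset_on_adoption``
    (``"never"/"always"/"change"``), the focal agent's relationships (its
    row and column) are reset to neutral 0 — the adopting agent re-enters
    the population socially blank.  Payoffs are then reset for the next
    generation.  Mutates and returns ``state``.

    This is the reference implementation of the kernel's generation
    boundary; long runs should go through
    :func:`heidercoop.simulation_engine.run_simulation`.
    """
    n = len(state.strategies)
    focal = int(rng.integers(n))
    old = int(state.strategies[focal])
    if rng.random() < params.u:
        state.strategies[focal] = int(
            params.strategy_pool[int(rng.integers(len(params.strategy_pool)))]
        )
    else:
        w = np.exp(state.payoffs - state.payoffs.max())
        z = int(rng.choice(n, p=w / w.sum()))
        state.strategies[focal] = int(state.strategies[z])
    changed = int(state.strategies[focal]) != old
    if reset_on_adoption == "always" or (reset_on_adoption == "change" and changed):
        state.S[focal, :] = 0.0
        state.S[:, focal] = 0.0
        state.S[focal, focal] = 1.0
    state.payoffs[:] = 0.0
    return state
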