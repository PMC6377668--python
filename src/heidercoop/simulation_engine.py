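"""Simulation orchestration: configs, the iteration loop, trajectories.

Each iteration has three stages: (1) every agent is randomly paired with
another agent, (2) every agent chooses cooperate/defect from the
reputation matrix as it stood at the start of the iteration (decisions are
simultaneous — no pair's update can leak into another pair's decision in
the same iteration), (3) relationships are updated from the realized
action pairs, after which memory-constrained agents forget their weakest
relationships.  When evolution is enabled, every ``interactions_per_generation``
iterations one agent revises its strategy through a frequency-dependent
Moran process and the generation's payoffs are reset.

:func:`run_simulation` executes the whole schedule through the compiled
kernel; :func:`run_iteration` is a plain-numpy single step over explicit
state, useful for inspection and testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel, core_model, evolution
from .core_model import (
    Action,
    InvalidPopulationError,
    ModelParams,
    Strategy,
)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "Trajectory",
    "random_pairing",
    "run_iteration",
    "run_simulation",
]

_RESET_MODES = {"never": _kernel.RESET_NEVER, "always": _kernel.RESET_ALWAYS,
                "change": _kernel.RESET_ON_CHANGE}

#: Trajectory record column names, aligned with the kernel record layout.
RECORD_COLUMNS = [
    "iteration",
    "n_heider",
    "n_friend",
    "n_defector",
    "n_enemy",
    "n_incomplete",
    "coop_rate",
    "mean_payoff_heider",
    "mean_payoff_friend",
    "mean_payoff_defector",
    "mean_payoff_enemy",
    "mean_payoff_incomplete",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All free parameters of a single simulation run.

    Parameters
    ----------
    n
        Population size.
    composition
        Agents per strategy, e.g. ``{Strategy.HEIDER: 34, Strategy.FRIEND: 33,
        Strategy.DEFECTOR: 33}``.  Must sum to ``n``.
    r
        Relationship increment per interaction.
    b, c
        Prisoner's-Dilemma benefit (to the partner of a C action) and cost
        (to the cooperator); ``c < b`` whenever evolution is enabled.
    interactions_per_generation
        Pairing iterations between two Moran updates (the interaction
        frequency ``i``).
    u
        Mutation probability per Moran update.
    k
        Memory capacity (stored off-diagonal relationships per agent);
        ``None`` = unlimited.
    temperature
        Logistic decision scale.
    iterations
        Total pairing iterations.
    seed
        RNG seed; with the config it fully determines the trajectory.
    record_every
        Measurement stride in iterations; defaults to one record per
        generation.
    evolve
        Whether the Moran process runs at all (off for the pure
        network-formation analyses).
    mutation_pool
        Strategies reachable by mutation; defaults to the strategies
        present in ``composition``.
    reset_on_adoption
        What happens to the relationships of an agent that revises its
        strategy: ``"change"`` (default) resets its row and column to
        neutral when the strategy actually changes — the adopting agent
        re-enters the population socially blank, as under a birth-death
        reading of the Moran process; ``"always"`` resets on every update;
        ``"never"`` keeps all relationships (pure social-learning reading).
    normalize_rs
        Divide relationship scores by ``n - 1`` (exploratory; off in the
        model proper).
    snapshot_every
        If > 0, store a copy of the reputation matrix every that many
        iterations (for community-trajectory analyses).
    """

    n: int
    composition: Mapping[Strategy, int]
    r: float = 0.3
    b: float = 4.0
    c: float = 1.0
    interactions_per_generation: int = 10
    u: float = 0.01
    k: int | None = None
    temperature: float = 0.2
    iterations: int = 100_000
    seed: int = 0
    record_every: int | None = None
    evolve: bool = False
    mutation_pool: Sequence[Strategy] | None = None
    reset_on_adoption: str = "change"
    normalize_rs: bool = False
    snapshot_every: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidPopulationError(f"need at least 2 agents, got n={self.n}")
        comp = {Strategy(s): int(m) for s, m in dict(self.composition).items()}
        object.__setattr__(self, "composition", comp)
        if any(m < 0 for m in comp.values()):
            raise ValueError("strategy counts must be non-negative")
        if sum(comp.values()) != self.n:
            raise ValueError(
                f"composition sums to {sum(comp.values())}, expected n={self.n}"
            )
        if self.r <= 0 or self.temperature <= 0:
            raise ValueError("r and temperature must be > 0")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"mutation probability u must be in [0, 1], got {self.u}")
        if self.evolve and not self.c < self.b:
            raise ValueError("evolution requires c < b (otherwise C is dominated)")
        if self.k is not None and not 1 <= self.k <= self.n - 1:
            raise ValueError(f"memory capacity must be in [1, n-1], got k={self.k}")
        if self.interactions_per_generation < 1:
            raise ValueError("interactions_per_generation must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.reset_on_adoption not in _RESET_MODES:
            raise ValueError(
                f"reset_on_adoption must be one of {sorted(_RESET_MODES)}"
            )
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.mutation_pool is not None:
            pool = tuple(Strategy(s) for s in self.mutation_pool)
            if not pool:
                raise ValueError("mutation pool must not be empty")
            object.__setattr__(self, "mutation_pool", pool)

    @property
    def effective_k(self) -> int:
        return self.n - 1 if self.k is None else self.k

    @property
    def effective_record_every(self) -> int:
        return (
            self.interactions_per_generation
            if self.record_every is None
            else self.record_every
        )

    @property
    def effective_pool(self) -> tuple[Strategy, ...]:
        if self.mutation_pool is not None:
            return tuple(self.mutation_pool)
        return tuple(s for s, m in sorted(self.composition.items()) if m > 0)

    def strategy_vector(self) -> np.ndarray:
        """Per-agent strategy codes, grouped by strategy in enum order."""
        out = np.empty(self.n, dtype=np.int8)
        pos = 0
        for s in sorted(self.composition):
            m = self.composition[s]
            out[pos : pos + m] = int(s)
            pos += m
        return out

    def model_params(self) -> ModelParams:
        return ModelParams(r=self.r, temperature=self.temperature, k=self.k)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["composition"] = {Strategy(s).name: m for s, m in self.composition.items()}
        if self.mutation_pool is not None:
            d["mutation_pool"] = [Strategy(s).name for s in self.mutation_pool]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["composition"] = {
            Strategy[name] if isinstance(name, str) else Strategy(name): m
            for name, m in dict(d["composition"]).items()
        }
        if d.get("mutation_pool") is not None:
            d["mutation_pool"] = [
                Strategy[s] if isinstance(s, str) else Strategy(s)
                for s in d["mutation_pool"]
            ]
        return cls(**d)


@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    S: np.ndarray
    strategies: np.ndarray
    payoffs: np.ndarray
    iteration: int = 0

    @classmethod
    def initial(cls, config: SimulationConfig) -> "SimulationState":
        return cls(
            S=core_model.init_reputation(config.n),
            strategies=config.strategy_vector(),
            payoffs=np.zeros(config.n),
            iteration=0,
        )

    def strategy_counts(self) -> dict[Strategy, int]:
        return {
            s: int((self.strategies == int(s)).sum()) for s in Strategy
        }


@dataclass
class Trajectory:
    """Per-generation records plus the final reputation matrix.

    ``records`` has one row per measurement stride with strategy counts,
    the cooperation rate over the window, and per-strategy mean payoffs.
    ``snapshots`` (optional) holds copies of the reputation matrix at a
    fixed iteration stride for network-trajectory analyses.
    """

    records: pd.DataFrame
    final_matrix: np.ndarray
    config: SimulationConfig
    snapshots: np.ndarray | None = None
    snapshot_iterations: np.ndarray | None = None

    def strategy_count_matrix(self) -> np.ndarray:
        """(n_records, 5) strategy counts in Strategy code order."""
        return self.records[
            ["n_heider", "n_friend", "n_defector", "n_enemy", "n_incomplete"]
        ].to_numpy()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def random_pairing(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniformly random disjoint pairs covering the population.

    For even ``n`` this is a uniform perfect matching; for odd ``n`` one
    uniformly chosen agent sits out the iteration.
    """
    if n < 2:
        raise InvalidPopulationError(f"need at least 2 agents to pair, got n={n}")
    perm = rng.permutation(n)
    half = n // 2
    return [(int(perm[j]), int(perm[half + j])) for j in range(half)]


def run_iteration(
    state: SimulationState,
    params: ModelParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[SimulationState, np.ndarray, list[tuple[int, int]]]:
    """One three-stage iteration over explicit state (reference path).

    Decisions are computed for every paired agent from the matrix snapshot
    at iteration start; defectors always play D.  Returns the mutated
    state, the per-agent action array (-1 for an idle agent), and the
    pairing.  This is the uncompiled counterpart of the kernel loop, kept
    for transparency and testing; long runs should use
    :func:`run_simulation`.
    """
    n = config.n
    pairs = random_pairing(n, rng)
    S0 = state.S.copy()  # decision snapshot
    actions = np.full(n, -1, dtype=np.int8)
    for x, y in pairs:
        for focal, other in ((x, y), (y, x)):
            if state.strategies[focal] == Strategy.DEFECTOR:
                actions[focal] = int(Action.D)
            else:
                rs = core_model.relationship_score(
                    S0,
                    focal,
                    other,
                    Strategy(int(state.strategies[focal])),
                    normalize=config.normalize_rs,
                )
                p = core_model.decision_probability(rs, config.temperature)
                actions[focal] = int(Action.C) if rng.random() < p else int(Action.D)
    payoff_params = evolution.PayoffParams(b=config.b, c=config.c)
    for x, y in pairs:
        dx, dy = evolution.accrue_payoff(
            Action(actions[x]), Action(actions[y]), payoff_params
        )
        state.payoffs[x] += dx
        state.payoffs[y] += dy
        core_model.update_relationships(
            state.S,
            x,
            y,
            Action(actions[x]),
            Action(actions[y]),
            params.r,
            x_is_defector=state.strategies[x] == Strategy.DEFECTOR,
            y_is_defector=state.strategies[y] == Strategy.DEFECTOR,
            out=state.S,
        )
    if config.effective_k < n - 1:
        for x in range(n):
            core_model.apply_memory_limit(
                state.S, x, config.effective_k, rng, out=state.S
            )
    state.iteration += 1
    return state, actions, pairs


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run the full schedule and return the trajectory.

    Executes ``config.iterations`` pairing iterations in the compiled
    kernel, with a Moran strategy update every
    ``interactions_per_generation`` iterations when ``config.evolve`` is
    set, and one record per ``record_every`` iterations.
    """
    S = core_model.init_reputation(config.n)
    strat = config.strategy_vector()
    record_every = config.effective_record_every
    n_rec = config.iterations // record_every
    records = np.full((n_rec, _kernel.N_REC_COLS), np.nan)
    if config.snapshot_every > 0:
        n_snap = config.iterations // config.snapshot_every
        snaps = np.zeros((n_snap, config.n, config.n))
    else:
        snaps = np.zeros((0, config.n, config.n))
    pool = np.array([int(s) for s in config.effective_pool], dtype=np.int8)

    rec_filled, snap_filled = _kernel.run_kernel(
        S,
        strat,
        float(config.r),
        float(config.temperature),
        float(config.b),
        float(config.c),
        int(config.interactions_per_generation),
        float(config.u),
        int(config.effective_k),
        int(config.iterations),
        int(config.seed),
        int(record_every),
        pool,
        _RESET_MODES[config.reset_on_adoption],
        bool(config.evolve),
        bool(config.normalize_rs),
        records,
        int(config.snapshot_every),
        snaps,
    )
    df = pd.DataFrame(records[:rec_filled], columns=RECORD_COLUMNS)
    df["iteration"] = df["iteration"].astype(int)
    for col in RECORD_COLUMNS[1:6]:
        df[col] = df[col].astype(int)
    snapshots = snaps[:snap_filled] if config.snapshot_every > 0 else None
    snap_iters = (
        (np.arange(1, snap_filled + 1) * config.snapshot_every)
        if config.snapshot_every > 0
        else None
    )
    return Trajectory(
        records=df,
        final_matrix=S,
        config=config,
        snapshots=snapshots,
        snapshot_iterations=snap_iters,
    )
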