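"""Preset experiments, parameter sweeps, and replicate orchestration.

Each preset reproduces one of the model's headline analyses at either
``full`` scale (the original problem sizes) or ``desk`` scale (reduced
replicate counts and iteration budgets for a single workstation; the
reduction factors are written into the output manifest).  All replicate
seeds are spawned deterministically from the base seed, so a manifest is
sufficient to reproduce every output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io, network_analysis as na
from .core_model import Strategy
from .simulation_engine import SimulationConfig, Trajectory, run_simulation

__all__ = [
    "SweepSpec",
    "aggregate_sweep",
    "evolution_run",
    "final_community_count",
    "heider_gradient_experiment",
    "decay_tau_from_gradient",
    "memory_connection_experiment",
    "memory_cycle_experiment",
    "pairwise_run",
    "polarization_experiment",
    "run_preset",
    "run_sweep",
    "PRESETS",
]

_SEED_MOD = 2**31


def spawn_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed (collision-free counter rule)."""
    return int((base_seed + index) % _SEED_MOD)


# ---------------------------------------------------------------------------
# building blocks


def final_community_count(traj: Trajectory, *, seed: int = 0) -> int:
    """Louvain community count of the final mutual-positive network."""
    G = na.mutual_positive_graph(traj.final_matrix)
    _, count = na.count_communities(G, seed=seed)
    return count


def polarization_experiment(
    sizes: Sequence[int],
    replicates: int,
    *,
    iterations: int = 100_000,
    r: float = 0.3,
    strategy: Strategy = Strategy.HEIDER,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Single-strategy populations: final community count per replicate.

    One row per (population size, replicate) with the community count of
    the final mutual-positive graph and the cooperation rate over the last
    tenth of the run.
    """
    rows = []
    counter = 0
    for n in sizes:
        for rep in range(replicates):
            seed = spawn_seed(base_seed, counter)
            counter += 1
            cfg = SimulationConfig(
                n=n,
                composition={strategy: n},
                r=r,
                iterations=iterations,
                seed=seed,
                record_every=max(1, iterations // 100),
            )
            traj = run_simulation(cfg)
            tail = traj.records["coop_rate"].iloc[-10:].mean()
            rows.append(
                {
                    "n": n,
                    "replicate": rep,
                    "seed": seed,
                    "n_communities": final_community_count(traj),
                    "coop_rate": float(tail),
                }
            )
    return pd.DataFrame(rows)


def heider_gradient_experiment(
    sizes: Sequence[int],
    heider_counts: Sequence[int],
    replicates: int,
    *,
    iterations: int = 100_000,
    r: float = 0.3,
    k: int | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Friend-focused populations seeded with 0..m full-Heider agents.

    The community count of the final mutual-positive network falls as the
    number of Heider agents rises — the polarization gradient.
    """
    rows = []
    counter = 0
    for n in sizes:
        for h in heider_counts:
            for rep in range(replicates):
                seed = spawn_seed(base_seed, counter)
                counter += 1
                cfg = SimulationConfig(
                    n=n,
                    composition={Strategy.HEIDER: h, Strategy.FRIEND: n - h},
                    r=r,
                    k=k,
                    iterations=iterations,
                    seed=seed,
                    record_every=max(1, iterations // 100),
                )
                traj = run_simulation(cfg)
                tail = traj.records["coop_rate"].iloc[-10:].mean()
                rows.append(
                    {
                        "n": n,
                        "n_heider": h,
                        "replicate": rep,
                        "seed": seed,
                        "n_communities": final_community_count(traj),
                        "coop_rate": float(tail),
                    }
                )
    return pd.DataFrame(rows)


def decay_tau_from_gradient(
    gradient: pd.DataFrame, *, model_form: str = "exponential"
) -> na.DecayFit:
    """Decay constant of community count vs. number of Heider agents.

    Averages the community count per (population size, Heider count) cell
    and regresses the cell means on the Heider count across all sizes.
    """
    cells = (
        gradient.groupby(["n", "n_heider"])["n_communities"].mean().reset_index()
    )
    return na.fit_exponential_decay(
        cells["n_heider"], cells["n_communities"], model_form=model_form
    )


def evolution_run(
    *,
    n: int = 100,
    iterations: int = 400_000,
    composition: Mapping[Strategy, int] | None = None,
    b: float = 4.0,
    c: float = 1.0,
    i: int = 10,
    u: float = 0.01,
    r: float = 0.3,
    k: int | None = None,
    seed: int = 0,
    reset_on_adoption: str = "change",
    mutation_pool: Sequence[Strategy] | None = None,
) -> Trajectory:
    """Three-strategy (by default) evolutionary run at the headline parameters."""
    if composition is None:
        base, extra = divmod(n, 3)
        composition = {
            Strategy.HEIDER: base + (extra > 0),
            Strategy.FRIEND: base + (extra > 1),
            Strategy.DEFECTOR: base,
        }
    cfg = SimulationConfig(
        n=n,
        composition=composition,
        r=r,
        b=b,
        c=c,
        interactions_per_generation=i,
        u=u,
        k=k,
        iterations=iterations,
        seed=seed,
        evolve=True,
        mutation_pool=mutation_pool,
        reset_on_adoption=reset_on_adoption,
    )
    return run_simulation(cfg)


def pairwise_run(
    pair: tuple[Strategy, Strategy],
    *,
    n: int = 100,
    iterations: int = 400_000,
    split: tuple[int, int] | None = None,
    seed: int = 0,
    **kwargs,
) -> Trajectory:
    """Two-strategy invasion run (mutation pool restricted to the pair)."""
    a, b_ = pair
    if split is None:
        split = (n // 2, n - n // 2)
    comp = {a: split[0], b_: split[1]}
    return evolution_run(
        n=n,
        iterations=iterations,
        composition=comp,
        mutation_pool=[a, b_],
        seed=seed,
        **kwargs,
    )


def memory_connection_experiment(
    *,
    n: int = 20,
    heider_count: int = 2,
    memory_fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    replicates: int = 10,
    iterations: int = 100_000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Cooperative connectivity of reputation-sensitive populations vs. memory.

    For each memory capacity (a fraction of the population size) runs
    non-evolutionary mixed populations and reports the mean number of
    mutual-positive connections per agent in the final network.
    """
    rows = []
    counter = 0
    for frac in memory_fractions:
        k = max(1, min(n - 1, round(frac * n)))
        for rep in range(replicates):
            seed = spawn_seed(base_seed, counter)
            counter += 1
            cfg = SimulationConfig(
                n=n,
                composition={
                    Strategy.HEIDER: heider_count,
                    Strategy.FRIEND: n - heider_count,
                },
                k=k,
                iterations=iterations,
                seed=seed,
                record_every=max(1, iterations // 100),
            )
            traj = run_simulation(cfg)
            G = na.mutual_positive_graph(traj.final_matrix)
            rows.append(
                {
                    "memory_fraction": frac,
                    "k": k,
                    "replicate": rep,
                    "seed": seed,
                    "mean_degree": 2.0 * G.number_of_edges() / n,
                    "coop_rate": float(traj.records["coop_rate"].iloc[-10:].mean()),
                }
            )
    return pd.DataFrame(rows)


def memory_cycle_experiment(
    *,
    n: int = 100,
    memory_sizes: Sequence[int | None] = (33, 66, None),
    iterations: int = 100_000,
    replicates: int = 3,
    base_seed: int = 0,
    **evo_kwargs,
) -> pd.DataFrame:
    """Fission-fusion cycle frequency under memory constraints.

    Runs the three-strategy evolutionary simulation at each memory level
    and counts completed defection -> community building -> polarization
    cycles in the plurality-state sequence, per 1000 generations.
    """
    rows = []
    counter = 0
    for k in memory_sizes:
        for rep in range(replicates):
            seed = spawn_seed(base_seed, counter)
            counter += 1
            traj = evolution_run(
                n=n, iterations=iterations, k=k, seed=seed, **evo_kwargs
            )
            states = na.majority_state_sequence(traj)
            rows.append(
                {
                    "k": n - 1 if k is None else k,
                    "replicate": rep,
                    "seed": seed,
                    "generations": len(states),
                    "cycles": na.count_cycles(states, per=None),
                    "cycles_per_1000": na.count_cycles(states, per=1000.0),
                    "coop_rate": float(traj.records["coop_rate"].mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweeps


@dataclasses.dataclass
class SweepSpec:
    """A parameter-grid sweep over :class:`SimulationConfig` fields.

    ``axes`` maps config field names to value lists; every grid cell is run
    ``replicates`` times with seeds spawned from ``base_seed``.
    """

    base: dict
    axes: dict[str, list]
    replicates: int = 1
    base_seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(SimulationConfig)}
        for name in self.axes:
            if name not in valid:
                raise ValueError(f"unknown sweep parameter {name!r}")


def _grid(axes: dict[str, list]):
    names = list(axes)
    if not names:
        yield {}
        return
    head, *rest = names
    for value in axes[head]:
        for combo in _grid({k: axes[k] for k in rest}):
            yield {head: value, **combo}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """One row per (grid cell, replicate): parameters and summary outcomes.

    Failed cells are preserved with an ``error`` marker instead of aborting
    the sweep.
    """
    rows = []
    counter = 0
    for cell in _grid(spec.axes):
        for rep in range(spec.replicates):
            seed = spawn_seed(spec.base_seed, counter)
            counter += 1
            params = {**spec.base, **cell, "seed": seed}
            row = {**cell, "replicate": rep, "seed": seed, "error": ""}
            try:
                cfg = (
                    SimulationConfig.from_dict(params)
                    if "composition" in params
                    else SimulationConfig(**params)
                )
                traj = run_simulation(cfg)
                rec = traj.records
                tail = rec.iloc[-max(1, len(rec) // 4):]
                for s in Strategy:
                    col = f"n_{s.name.lower()}" if s != Strategy.INCOMPLETE_HEIDER else "n_incomplete"
                    row[f"prop_{s.name.lower()}"] = float(
                        tail[col].mean() / cfg.n
                    )
                row["coop_rate"] = float(tail["coop_rate"].mean())
                row["n_communities"] = final_community_count(traj)
            except Exception as err:  # noqa: BLE001 — sweep must not abort
                row["error"] = f"{type(err).__name__}: {err}"
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(table: pd.DataFrame, axes: Sequence[str]) -> pd.DataFrame:
    """Per-cell mean and standard error over replicates."""
    numeric = [
        c
        for c in table.columns
        if c not in (*axes, "replicate", "seed", "error")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    grouped = table.groupby(list(axes))[numeric]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()


# ---------------------------------------------------------------------------
# presets


def _preset_polarization(scale: str, seed: int, out: Path) -> dict:
    sizes = [10, 20, 40] if scale == "desk" else [10, 20, 40, 60, 120]
    reps = 20 if scale == "desk" else 50
    pure = polarization_experiment(sizes, reps, base_seed=seed)
    pure.to_csv(out / "pure_heider_communities.csv", index=False)
    grad_sizes = [20, 40] if scale == "desk" else [20, 40, 60, 120]
    grad = heider_gradient_experiment(
        grad_sizes, range(6), reps, base_seed=seed + 10_000
    )
    grad.to_csv(out / "heider_gradient.csv", index=False)
    fit = decay_tau_from_gradient(grad)
    io.write_json(dataclasses.asdict(fit), out / "decay_fit.json")
    frac2 = float((pure["n_communities"] == 2).mean())
    return {
        "sizes": sizes,
        "replicates": reps,
        "iterations": 100_000,
        "fraction_two_communities": frac2,
        "decay_tau": fit.tau,
    }


def _preset_evolution(scale: str, seed: int, out: Path) -> dict:
    iterations = 40_000 if scale == "desk" else 400_000
    traj = evolution_run(iterations=iterations, seed=seed)
    traj.to_csv(out / "trajectory.csv")
    io.write_matrix_csv(traj.final_matrix, out / "final_matrix.csv")
    states = na.majority_state_sequence(traj)
    tm = na.estimate_transition_matrix(states, drop_mixed=True)
    tm.to_csv(out / "transition_matrix.csv")
    return {
        "iterations": iterations,
        "cycles_per_1000": na.count_cycles(states),
        "majority_states_visited": sorted({s.value for s in states}),
    }


def _preset_paramspace(scale: str, seed: int, out: Path) -> dict:
    if scale == "desk":
        i_vals, b_vals, factor = [1, 4, 16], [2, 4, 8], 10_000
    else:
        i_vals, b_vals, factor = list(range(1, 33)), list(range(1, 9)), 500_000
    spec = SweepSpec(
        base={
            "n": 100,
            "composition": {"HEIDER": 34, "FRIEND": 33, "DEFECTOR": 33},
            "u": 0.01,
            "evolve": True,
        },
        axes={"interactions_per_generation": i_vals, "b": b_vals},
        replicates=1 if scale == "desk" else 2,
        base_seed=seed,
    )
    # iteration budget scales with interaction frequency, as in the grid design
    rows = []
    for i in i_vals:
        sub = SweepSpec(
            base={**spec.base, "iterations": i * factor,
                  "interactions_per_generation": i},
            axes={"b": b_vals},
            replicates=spec.replicates,
            base_seed=seed + i,
        )
        part = run_sweep(sub)
        part["interactions_per_generation"] = i
        part["rapoport_K"] = [
            na.rapoport_index(b, 1.0) if b >= 1 else np.nan for b in part["b"]
        ]
        rows.append(part)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "paramspace.csv", index=False)
    agg = aggregate_sweep(table, ["interactions_per_generation", "b"])
    agg.to_csv(out / "paramspace_cells.csv", index=False)
    return {"i_values": i_vals, "b_values": b_vals, "iteration_factor": factor}


def _preset_pairwise(scale: str, seed: int, out: Path) -> dict:
    iterations = 100_000 if scale == "desk" else 1_000_000
    summary = {}
    pairs = {
        "heider_vs_defector": (Strategy.HEIDER, Strategy.DEFECTOR),
        "friend_vs_defector": (Strategy.FRIEND, Strategy.DEFECTOR),
        "heider_vs_friend": (Strategy.HEIDER, Strategy.FRIEND),
    }
    for idx, (name, pair) in enumerate(pairs.items()):
        traj = pairwise_run(pair, iterations=iterations, seed=spawn_seed(seed, idx))
        traj.to_csv(out / f"{name}.csv")
        rec = traj.records
        tail = rec.iloc[-max(1, len(rec) // 4):]
        cols = {Strategy.HEIDER: "n_heider", Strategy.FRIEND: "n_friend",
                Strategy.DEFECTOR: "n_defector"}
        summary[name] = {
            "prop_first": float(tail[cols[pair[0]]].mean() / 100),
            "prop_second": float(tail[cols[pair[1]]].mean() / 100),
            "coop_rate": float(tail["coop_rate"].mean()),
        }
    summary["iterations"] = iterations
    return summary


def _preset_memory(scale: str, seed: int, out: Path) -> dict:
    reps_a = 5 if scale == "desk" else 20
    conn = memory_connection_experiment(
        n=20, replicates=reps_a, base_seed=seed,
        memory_fractions=(0.1, 0.3, 0.5, 0.7, 0.9),
    )
    conn.to_csv(out / "memory_connections.csv", index=False)
    reps_c = 2 if scale == "desk" else 10
    cyc = memory_cycle_experiment(
        memory_sizes=(33, 66, None), replicates=reps_c, base_seed=seed + 999
    )
    cyc.to_csv(out / "memory_cycles.csv", index=False)
    return {
        "connection_replicates": reps_a,
        "cycle_replicates": reps_c,
        "mean_degree_by_fraction": conn.groupby("memory_fraction")["mean_degree"]
        .mean()
        .to_dict(),
        "cycles_per_1000_by_k": cyc.groupby("k")["cycles_per_1000"].mean().to_dict(),
    }


PRESETS = {
    "polarization": _preset_polarization,
    "evolution": _preset_evolution,
    "paramspace": _preset_paramspace,
    "pairwise": _preset_pairwise,
    "memory": _preset_memory,
}


def run_preset(name: str, scale: str = "desk", seed: int = 0, out_dir=None) -> Path:
    """Run a named preset; writes outputs and a manifest, returns the directory."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if scale not in ("desk", "full"):
        raise ValueError(f"scale must be 'desk' or 'full', got {scale!r}")
    out = Path(out_dir) if out_dir is not None else Path(f"{name}_{scale}")
    out.mkdir(parents=True, exist_ok=True)
    summary = PRESETS[name](scale, int(seed), out)
    manifest = {
        "preset": name,
        "scale": scale,
        "base_seed": int(seed),
        "seed_rule": "replicate seeds = (base_seed + counter) mod 2^31",
        "summary": summary,
    }
    io.write_json(manifest, out / "manifest.json")
    return out
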