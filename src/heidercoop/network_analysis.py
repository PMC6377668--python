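"""Measurement layer: community structure, cooperation, fits, Markov analysis.

Polarization is measured on the *mutual-positive graph* — the undirected
network linking pairs whose relationship is positive in both directions —
via the Louvain community count: many small communities mean a scattered,
unpolarized population; one or two large communities mean a (maximally)
polarized one.  The evolutionary dynamic is summarized by the per-generation
plurality strategy, its maximum-likelihood Markov transition matrix, and
the number of completed defection -> community-building -> polarization
cycles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_model import Strategy

__all__ = [
    "CommunityPartition",
    "DecayFit",
    "FitError",
    "MajorityState",
    "classify_majority_state",
    "cooperation_rate",
    "count_communities",
    "count_cycles",
    "estimate_transition_matrix",
    "fit_exponential_decay",
    "majority_state_sequence",
    "mutual_positive_graph",
    "outgoing_positive_connections",
    "rapoport_index",
]


class FitError(RuntimeError):
    """Regression did not converge or the input is degenerate."""


@dataclass(frozen=True)
class CommunityPartition:
    """Agent -> community labels from Louvain on the mutual-positive graph."""

    labels: dict[int, int]
    n_communities: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["agent", "community"]
        )


@dataclass(frozen=True)
class DecayFit:
    """Result of an exponential decay/growth regression.

    ``model_form`` records the parameterization actually fitted:
    ``"exponential"`` is ``y = amplitude * exp(-x / tau)``; ``"offset"``
    adds a free asymptote ``y = offset + amplitude * exp(-x / tau)``.
    Growth fits carry ``amplitude < 0``.
    """

    tau: float
    amplitude: float
    offset: float
    model_form: str


class MajorityState(str, enum.Enum):
    """Plurality strategy of a generation (MIXED on ties)."""

    HEIDER_MAJ = "HEIDER_MAJ"
    FRIEND_MAJ = "FRIEND_MAJ"
    DEFECTOR_MAJ = "DEFECTOR_MAJ"
    ENEMY_MAJ = "ENEMY_MAJ"
    INCOMPLETE_HEIDER_MAJ = "INCOMPLETE_HEIDER_MAJ"
    MIXED = "MIXED"


_STRATEGY_TO_STATE = {
    Strategy.HEIDER: MajorityState.HEIDER_MAJ,
    Strategy.FRIEND: MajorityState.FRIEND_MAJ,
    Strategy.DEFECTOR: MajorityState.DEFECTOR_MAJ,
    Strategy.ENEMY: MajorityState.ENEMY_MAJ,
    Strategy.INCOMPLETE_HEIDER: MajorityState.INCOMPLETE_HEIDER_MAJ,
}


def mutual_positive_graph(S: np.ndarray, threshold: float = 0.0) -> nx.Graph:
    """Undirected graph of mutually positive relationships.

    Edge ``(x, y)`` exists iff both ``S[x, y]`` and ``S[y, x]`` exceed
    ``threshold`` (strictly — a forgotten/neutral relationship is not a
    link); its weight is the mean of the two directed values.  All agents
    appear as nodes, so isolated agents are preserved.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    mutual = (S > threshold) & (S.T > threshold)
    xs, ys = np.nonzero(np.triu(mutual, k=1))
    G.add_weighted_edges_from(
        (int(x), int(y), float((S[x, y] + S[y, x]) / 2.0)) for x, y in zip(xs, ys)
    )
    return G


def count_communities(
    G: nx.Graph, *, seed: int = 0, resolution: float = 1.0
) -> tuple[CommunityPartition, int]:
    """Louvain community detection; isolated nodes are singleton communities."""
    comms = nx.community.louvain_communities(
        G, weight="weight", seed=seed, resolution=resolution
    )
    labels: dict[int, int] = {}
    for cid, members in enumerate(comms):
        for node in members:
            labels[node] = cid
    part = CommunityPartition(labels=labels, n_communities=len(comms))
    return part, part.n_communities


def cooperation_rate(actions: Iterable[int]) -> float:
    """Fraction of C actions in a window of realized actions."""
    acts = np.asarray(list(actions))
    if acts.size == 0:
        raise ValueError("cooperation rate undefined for an empty window")
    return float((acts == 1).mean())


def outgoing_positive_connections(S: np.ndarray, x: int) -> int:
    """Number of strictly positive off-diagonal entries in row ``x``."""
    S = np.asarray(S)
    row = S[x].copy()
    row[x] = 0.0
    return int((row > 0).sum())


def _exp_model(x, amplitude, tau):
    return amplitude * np.exp(-x / tau)


def _exp_offset_model(x, offset, amplitude, tau):
    return offset + amplitude * np.exp(-x / tau)


def fit_exponential_decay(
    xs: Sequence[float],
    ys: Sequence[float],
    *,
    model_form: str = "exponential",
) -> DecayFit:
    """Nonlinear least-squares fit of an exponential decay.

    ``model_form="exponential"`` (default) fits ``y = A * exp(-x / tau)``:
    every unit increase of the predictor multiplies the response by
    ``exp(-1/tau)``.  ``model_form="offset"`` adds a free asymptote; note
    that with few distinct predictor values the offset and ``tau`` trade
    off and the decay constant is weakly identified.  Growth data can be
    fitted with the same forms (the amplitude comes out negative with an
    offset, or ``tau`` is reported from a decay of the negated series).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        raise FitError("need at least 3 points to fit a decay")
    if np.unique(xs).size < (3 if model_form == "offset" else 2):
        raise FitError("predictor values must be distinct")
    if np.allclose(ys, ys[0]):
        raise FitError("response is constant: decay constant unidentified (tau -> inf)")

    span = xs.max() - xs.min()
    tau0 = span / 2.0 if span > 0 else 1.0
    try:
        if model_form == "exponential":
            p0 = [ys[np.argmin(xs)], tau0]
            popt, _ = curve_fit(_exp_model, xs, ys, p0=p0, maxfev=20_000)
            amplitude, tau = popt
            offset = 0.0
        elif model_form == "offset":
            p0 = [ys[np.argmax(xs)], ys[np.argmin(xs)] - ys[np.argmax(xs)], tau0]
            popt, _ = curve_fit(_exp_offset_model, xs, ys, p0=p0, maxfev=20_000)
            offset, amplitude, tau = popt
        else:
            raise ValueError(f"unknown model_form {model_form!r}")
    except RuntimeError as err:  # curve_fit non-convergence
        raise FitError(f"decay regression did not converge: {err}") from err
    if not np.isfinite(tau) or tau <= 0:
        raise FitError(f"fit produced non-positive decay constant tau={tau}")
    return DecayFit(
        tau=float(tau),
        amplitude=float(amplitude),
        offset=float(offset),
        model_form=model_form,
    )


def rapoport_index(b: float, c: float) -> float:
    """Rapoport cooperation index ``K = (R - P) / (T - S)`` of the PD.

    With reward ``R = b - c``, punishment ``P = 0``, temptation ``T = b``
    and sucker payoff ``S = -c`` this reduces to ``(b - c) / (b + c)``.
    Defined for ``b >= c`` (the ``b = c`` boundary gives ``K = 0``).
    """
    if b <= 0 or c < 0 or b < c:
        raise ValueError(f"need b >= c >= 0 and b > 0, got b={b}, c={c}")
    return float((b - c) / (b + c))


def classify_majority_state(
    counts: Mapping[Strategy, int] | Sequence[int],
) -> MajorityState:
    """Plurality strategy of a composition; MIXED when the top count ties."""
    if isinstance(counts, Mapping):
        items = [(Strategy(s), int(m)) for s, m in counts.items()]
    else:
        items = [(Strategy(i), int(m)) for i, m in enumerate(counts)]
    top = max(m for _, m in items)
    leaders = [s for s, m in items if m == top]
    if len(leaders) != 1:
        return MajorityState.MIXED
    return _STRATEGY_TO_STATE[leaders[0]]


def majority_state_sequence(trajectory) -> list[MajorityState]:
    """Per-record plurality states of a :class:`Trajectory`."""
    return [
        classify_majority_state(row)
        for row in trajectory.strategy_count_matrix().astype(int)
    ]


def estimate_transition_matrix(
    states: Sequence[MajorityState | str],
    *,
    drop_mixed: bool = False,
) -> pd.DataFrame:
    """Maximum-likelihood Markov transition matrix of a state sequence.

    Entry ``(a, b)`` is the number of observed ``a -> b`` transitions
    divided by the number of visits to ``a`` that have a successor.  Rows
    of states never visited (with a successor) are NaN.  With
    ``drop_mixed=True``, MIXED generations are removed before counting, so
    transitions connect successive decided majorities.
    """
    seq = [MajorityState(s) for s in states]
    if drop_mixed:
        seq = [s for s in seq if s is not MajorityState.MIXED]
    if len(seq) < 2:
        raise ValueError("need at least 2 states to estimate transitions")
    labels = sorted({s.value for s in seq})
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[idx[a.value], idx[b.value]] += 1
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rowsum > 0, counts / rowsum, np.nan)
    return pd.DataFrame(probs, index=labels, columns=labels)


#: Phase order of a complete fission-fusion cycle.
_CYCLE_ORDER = (
    MajorityState.DEFECTOR_MAJ,
    MajorityState.FRIEND_MAJ,
    MajorityState.HEIDER_MAJ,
)


def count_cycles(
    states: Sequence[MajorityState | str], *, per: float | None = 1000.0
) -> float:
    """Completed defection -> community-building -> polarization cycles.

    Counts ordered traversals DEFECTOR_MAJ -> FRIEND_MAJ -> HEIDER_MAJ ->
    DEFECTOR_MAJ through the majority-state sequence.  MIXED generations
    are transparent (they neither advance nor reset the tracker); a
    DEFECTOR_MAJ generation restarts progress (and completes a cycle when
    the polarization phase had been reached); other out-of-order states
    leave the tracker unchanged.  Returns cycles per ``per`` generations
    (the raw count if ``per`` is None).
    """
    seq = [MajorityState(s) for s in states]
    if not seq:
        raise ValueError("empty state sequence")
    phase = 0  # 0: waiting for D; 1: D seen; 2: D,F seen; 3: D,F,H seen
    cycles = 0
    for s in seq:
        if s is MajorityState.MIXED:
            continue
        if phase == 0:
            if s is MajorityState.DEFECTOR_MAJ:
                phase = 1
        elif s is _CYCLE_ORDER[phase % 3]:
            # expected next phase state (phase 3 expects DEFECTOR_MAJ)
            if phase == 3:
                cycles += 1
                phase = 1
            else:
                phase += 1
        elif s is MajorityState.DEFECTOR_MAJ:
            phase = 1
    if per is None:
        return float(cycles)
    return float(cycles) * per / len(seq)
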