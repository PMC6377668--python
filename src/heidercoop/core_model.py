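"""Reputation matrix, relationship scoring, decisions, updating, and memory.

The social state of the model is a signed ``n x n`` reputation matrix ``S``:
``S[x, y]`` is agent *x*'s relationship with (opinion of) agent *y*, a real
number in ``[-1, 1]``.  The diagonal is fixed at 1 — an agent trusts its own
opinion maximally, and no third party can be trusted more than oneself.
Rows are an agent's outgoing opinions; columns are the population's opinions
about an agent (its reputation).

Before deciding whether to cooperate with a partner *y*, a reputation-
sensitive agent *x* aggregates the population's opinions about *y*, each
weighted by *x*'s own relationship with the opinion holder.  The weighting
rule is the agent's strategy: a full-Heider agent uses all four structural-
balance heuristics (friend of a friend, enemy of a friend, friend of an
enemy, enemy of an enemy), a friend-focused agent discards opinions of
agents it dislikes, an enemy-focused agent discards opinions of agents it
likes, and an incomplete-Heider agent suppresses only the
enemy-of-an-enemy product.  The aggregate score feeds a logistic decision
function; actions then feed back into the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Action",
    "Strategy",
    "ModelParams",
    "InvalidPopulationError",
    "SelfInteractionError",
    "init_reputation",
    "validate_reputation",
    "relationship_score",
    "decision_probability",
    "update_relationships",
    "apply_memory_limit",
]


class Strategy(IntEnum):
    """Agent decision rules.

    Integer values are the codes used by the compiled simulation kernel and
    by the trajectory records; do not reorder.
    """

    HEIDER = 0
    FRIEND = 1
    DEFECTOR = 2
    ENEMY = 3
    INCOMPLETE_HEIDER = 4


#: Strategies that compute relationship scores (everyone but the free-rider).
REPUTATION_SENSITIVE = (
    Strategy.HEIDER,
    Strategy.FRIEND,
    Strategy.ENEMY,
    Strategy.INCOMPLETE_HEIDER,
)


class Action(IntEnum):
    D = 0
    C = 1


class InvalidPopulationError(ValueError):
    """Population too small to simulate (needs at least one pair)."""


class SelfInteractionError(ValueError):
    """An agent cannot be paired with, score, or update itself."""


@dataclass(frozen=True)
class ModelParams:
    """Relationship-dynamics parameters.

    Parameters
    ----------
    r
        Relationship increment per interaction (dimensionless).  After one
        mutual cooperation from a neutral start the own-opinion term alone
        moves the cooperation probability from 0.5 to ``logistic(r / temperature)``.
    temperature
        Scale of the logistic decision function.  The model fixes this at
        0.2; steepness is tuned through ``r`` instead (the two are
        interchangeable up to rescaling).
    k
        Memory capacity: number of off-diagonal relationships an agent can
        store.  ``None`` means unlimited (``n - 1``).
    """

    r: float = 0.3
    temperature: float = 0.2
    k: int | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"relationship increment r must be > 0, got {self.r}")
        if self.temperature <= 0:
            raise ValueError(
                f"logistic temperature must be > 0, got {self.temperature}"
            )
        if self.k is not None and self.k < 1:
            raise ValueError(f"memory capacity k must be >= 1, got {self.k}")


def init_reputation(n: int) -> np.ndarray:
    """Return the initial reputation matrix: the ``n x n`` identity.

    At the start of a simulation no agent knows any other (all off-diagonal
    relationships neutral at 0) while self-trust is 1.
    """
    if n < 2:
        raise InvalidPopulationError(f"need at least 2 agents, got n={n}")
    return np.eye(n)


def validate_reputation(S: np.ndarray) -> None:
    """Assert the structural invariants of a reputation matrix.

    Off-diagonal entries in ``[-1, 1]``, diagonal exactly 1, square shape.
    Raises ``ValueError`` on violation.
    """
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"reputation matrix must be square, got shape {S.shape}")
    if not np.all(np.diag(S) == 1.0):
        raise ValueError("reputation matrix diagonal must be exactly 1")
    off = S[~np.eye(S.shape[0], dtype=bool)]
    if off.size and (off.min() < -1.0 or off.max() > 1.0):
        raise ValueError("off-diagonal relationships must lie in [-1, 1]")


def relationship_score(
    S: np.ndarray,
    x: int,
    y: int,
    strategy: Strategy,
    *,
    normalize: bool = False,
) -> float:
    """Aggregated, weighted opinion of agent ``x`` about partner ``y``.

    The score is ``sum_i w(S[x, i]) * S[i, y]`` over all opinion holders
    ``i != y``; the partner's (fixed, uninformative) self-opinion is
    excluded so that the focal agent's own opinion enters exactly once,
    through the ``i = x`` term ``S[x, x] * S[x, y] = S[x, y]``.

    Strategy-specific weighting of third-party opinions:

    ``HEIDER``
        ``w(s) = s`` — all four balance heuristics.
    ``FRIEND``
        ``w(s) = max(0, s)`` — opinions of disliked agents discarded.
    ``ENEMY``
        ``w(s) = min(0, s)`` for third parties, but the agent's own direct
        experience (``i = x``) is always counted with weight 1.
    ``INCOMPLETE_HEIDER``
        As ``HEIDER`` except products of two negatives (the
        enemy-of-an-enemy inference) are suppressed to 0.

    With ``normalize=True`` the score is divided by the number of summed
    terms (``n - 1``); off by default — the model is defined on raw sums.
    """
    if x == y:
        raise SelfInteractionError(f"agent {x} cannot score itself")
    strategy = Strategy(strategy)
    if strategy == Strategy.DEFECTOR:
        raise ValueError("defectors never compute relationship scores")
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    m = S[x].copy()  # relationship (weight) vector of the focal agent
    opinions = S[:, y]

    if strategy == Strategy.HEIDER:
        terms = m * opinions
    elif strategy == Strategy.FRIEND:
        terms = np.maximum(0.0, m) * opinions
    elif strategy == Strategy.ENEMY:
        w = np.minimum(0.0, m)
        w[x] = 1.0  # own experience always counts
        terms = w * opinions
    else:  # INCOMPLETE_HEIDER
        terms = m * opinions
        terms[(m < 0) & (opinions < 0)] = 0.0

    terms[y] = 0.0  # partner's self-opinion excluded
    rs = float(terms.sum())
    if normalize:
        rs /= n - 1
    return rs


def decision_probability(rs: float, temperature: float = 0.2) -> float:
    """Probability of playing C given a relationship score.

    ``p(C) = 1 / (1 + exp(-rs / temperature))``; the complement is the
    probability of defecting.  Strictly inside (0, 1) for finite scores.
    """
    if temperature <= 0:
        raise ValueError(f"logistic temperature must be > 0, got {temperature}")
    from scipy.special import expit  # numerically stable logistic

    return float(expit(float(rs) / temperature))


def update_relationships(
    S: np.ndarray,
    x: int,
    y: int,
    a_x: Action,
    a_y: Action,
    r: float,
    *,
    x_is_defector: bool = False,
    y_is_defector: bool = False,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Update the two directed relationships of a pair after their actions.

    Mutual cooperation raises both ``s_xy`` and ``s_yx`` by ``r``; an agent
    whose partner defected lowers its opinion of the partner by ``r``; a
    defecting agent whose partner cooperated leaves its own opinion
    untouched (this asymmetry prevents the pair's opinions from
    anti-correlating and flip-flopping across rounds).  Results are clipped
    to ``[-1, 1]``.  Always-defect agents never update their own row;
    partners still update their opinion of them.

    Returns a new matrix unless ``out`` is given (which may alias ``S``).
    """
    if x == y:
        raise SelfInteractionError(f"agent {x} cannot update itself")
    a_x, a_y = Action(a_x), Action(a_y)
    if out is None:
        out = np.array(S, dtype=float, copy=True)
    elif out is not S:
        out[...] = S

    # s_xy moves only on x's grievance (partner defected) or mutual cooperation
    if not x_is_defector:
        if a_x == Action.C and a_y == Action.C:
            out[x, y] = min(1.0, out[x, y] + r)
        elif a_y == Action.D and a_x == Action.D:
            out[x, y] = max(-1.0, out[x, y] - r)
        elif a_y == Action.D and a_x == Action.C:
            out[x, y] = max(-1.0, out[x, y] - r)
        # (a_x=D, a_y=C): x exploited a cooperator; x's opinion unchanged
    if not y_is_defector:
        if a_x == Action.C and a_y == Action.C:
            out[y, x] = min(1.0, out[y, x] + r)
        elif a_x == Action.D and a_y == Action.D:
            out[y, x] = max(-1.0, out[y, x] - r)
        elif a_x == Action.D and a_y == Action.C:
            out[y, x] = max(-1.0, out[y, x] - r)
    return out


def apply_memory_limit(
    S: np.ndarray,
    x: int,
    k: int,
    rng: np.random.Generator,
    *,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Forget all but the ``k`` most extreme relationships in row ``x``.

    The ``k`` off-diagonal entries with the largest absolute value (closest
    to -1 or 1: best friends and worst enemies) are kept; the rest — the
    weakest memory traces, closest to zero — are reset to the neutral value
    0.  Exact ties in absolute value at the retention boundary are resolved
    uniformly at random from ``rng``.  The diagonal is untouched.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"memory capacity must satisfy 1 <= k <= n-1, got k={k}")
    if out is None:
        out = S.copy()
    elif out is not S:
        out[...] = S
    if k == n - 1:
        return out

    others = np.delete(np.arange(n), x)
    mag = np.abs(out[x, others])
    thr = np.partition(mag, len(others) - k)[len(others) - k]  # k-th largest
    keep_sure = mag > thr
    ties = np.flatnonzero(mag == thr)
    n_tie_keep = k - int(keep_sure.sum())
    kept_ties = rng.choice(ties, size=n_tie_keep, replace=False) if n_tie_keep else []
    forget = np.ones(len(others), dtype=bool)
    forget[keep_sure] = False
    forget[kept_ties] = False
    out[x, others[forget]] = 0.0
    return out
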