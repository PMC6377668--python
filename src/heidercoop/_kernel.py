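"""Compiled inner loop of the simulator.

Everything here mirrors the reference implementations in
:mod:`heidercoop.core_model` and :mod:`heidercoop.evolution`; the test suite
asserts agreement between the two.  The kernel exists because the model is
measured over hundreds of runs of 1e5 pairing iterations, which a
per-iteration Python loop cannot sustain.

All randomness inside a run draws from numba's ``np.random`` state, seeded
once at kernel entry, so a (config, seed) pair fully determines the output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Strategy codes — must match core_model.Strategy values.
HEIDER = 0
FRIEND = 1
DEFECTOR = 2
ENEMY = 3
INCOMPLETE_HEIDER = 4
N_STRATEGIES = 5

# reset_on_adoption codes
RESET_NEVER = 0
RESET_ALWAYS = 1
RESET_ON_CHANGE = 2

# Record layout: iteration, 5 strategy counts, cooperation rate in window,
# 5 per-strategy mean payoffs (NaN where the strategy is absent).
REC_ITER = 0
REC_COUNTS = 1  # ..5
REC_COOP = 6
REC_PAYOFF = 7  # ..11
N_REC_COLS = 12


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's np.random state (separate from NumPy's global state)."""
    np.random.seed(seed)


@njit(cache=True)
def score(S, x, y, strat_code, normalize):
    """Relationship score of focal ``x`` toward partner ``y``.

    Same weighting rules as ``core_model.relationship_score``; the
    partner's self-opinion (i == y) is skipped.
    """
    n = S.shape[0]
    rs = 0.0
    if strat_code == HEIDER:
        for i in range(n):
            if i != y:
                rs += S[x, i] * S[i, y]
    elif strat_code == FRIEND:
        for i in range(n):
            if i != y and S[x, i] > 0.0:
                rs += S[x, i] * S[i, y]
    elif strat_code == ENEMY:
        rs = S[x, y]  # own experience, weight S[x, x] = 1
        for i in range(n):
            if i != y and i != x and S[x, i] < 0.0:
                rs += S[x, i] * S[i, y]
    else:  # INCOMPLETE_HEIDER
        for i in range(n):
            if i != y and not (S[x, i] < 0.0 and S[i, y] < 0.0):
                rs += S[x, i] * S[i, y]
    if normalize:
        rs /= n - 1
    return rs


@njit(cache=True)
def prune_row(S, x, k):
    """Keep the k largest-|s| off-diagonal entries of row x, zero the rest.

    Ties at the retention boundary are kept with uniform probability
    (sequential sampling without replacement).
    """
    n = S.shape[0]
    if k >= n - 1:
        return
    mag = np.empty(n)
    nonzero = 0
    for i in range(n):
        mag[i] = abs(S[x, i])
        if mag[i] > 0.0:
            nonzero += 1
    if nonzero - 1 <= k:  # at most k off-diagonal traces stored: nothing to forget
        return
    mag[x] = 2.0  # diagonal always kept, never competes
    # threshold = (k+1)-th largest including the sentinel diagonal
    thr = np.partition(mag, n - 1 - k)[n - 1 - k]
    nbig = 0
    ntie = 0
    for i in range(n):
        if i == x:
            continue
        if mag[i] > thr:
            nbig += 1
        elif mag[i] == thr:
            ntie += 1
    keep_ties = k - nbig
    for i in range(n):
        if i == x:
            continue
        if mag[i] < thr:
            S[x, i] = 0.0
        elif mag[i] == thr:
            if ntie > 0 and np.random.random() < keep_ties / ntie:
                keep_ties -= 1
            else:
                S[x, i] = 0.0
            ntie -= 1


@njit(cache=True)
def moran_step(S, strat, pay, u, pool, reset_mode):
    """One frequency-dependent Moran update with mutation.

    A uniformly chosen focal agent adopts, with probability ``u``, a uniform
    strategy from ``pool`` (mutation); otherwise it adopts the strategy of
    an agent drawn proportionally to ``exp(payoff)`` (itself included).
    Exponentials are max-shifted, which leaves the adoption distribution
    unchanged and avoids overflow at large benefit * interaction products.
    Depending on ``reset_mode`` the focal agent's relationships (row and
    column) are reset to neutral.
    """
    n = strat.shape[0]
    focal = np.random.randint(n)
    old = strat[focal]
    if np.random.random() < u:
        strat[focal] = pool[np.random.randint(pool.shape[0])]
    else:
        m = pay[0]
        for a in range(1, n):
            if pay[a] > m:
                m = pay[a]
        total = 0.0
        cum = np.empty(n)
        for a in range(n):
            total += np.exp(pay[a] - m)
            cum[a] = total
        z = np.searchsorted(cum, np.random.random() * total)
        if z >= n:
            z = n - 1
        strat[focal] = strat[z]
    if reset_mode == RESET_ALWAYS or (
        reset_mode == RESET_ON_CHANGE and strat[focal] != old
    ):
        for i in range(n):
            S[focal, i] = 0.0
            S[i, focal] = 0.0
        S[focal, focal] = 1.0
    return focal


@njit(cache=True)
def run_kernel(
    S,
    strat,
    r,
    temperature,
    b,
    c,
    i_per_gen,
    u,
    k,
    iterations,
    seed,
    record_every,
    pool,
    reset_mode,
    evolve,
    normalize_rs,
    records,
    snap_every,
    snaps,
):
    """Full simulation loop: pair, decide, pay, update, forget, evolve.

    Mutates ``S`` and ``strat`` in place; fills ``records`` (one row per
    ``record_every`` iterations) and optionally ``snaps`` (matrix snapshots
    every ``snap_every`` iterations).
    """
    np.random.seed(seed)
    n = S.shape[0]
    half = n // 2
    partner = np.full(n, -1, np.int64)
    acts = np.zeros(n, np.uint8)
    pay = np.zeros(n)
    coop_actions = 0
    total_actions = 0
    rec_i = 0
    snap_i = 0

    for it in range(iterations):
        # (1) random matching: a uniform perfect matching; for odd n one
        # uniformly chosen agent sits out this iteration
        perm = np.random.permutation(n)
        for j in range(half):
            partner[perm[j]] = perm[half + j]
            partner[perm[half + j]] = perm[j]

        # (2) simultaneous action choice from the iteration-start snapshot
        for j in range(2 * half):
            x = perm[j]
            y = partner[x]
            if strat[x] == DEFECTOR:
                acts[x] = 0
            else:
                rs = score(S, x, y, strat[x], normalize_rs)
                p = 1.0 / (1.0 + np.exp(-rs / temperature))
                acts[x] = 1 if np.random.random() < p else 0

        # (3) payoffs and relationship updating
        for j in range(half):
            x = perm[j]
            y = partner[x]
            ax = acts[x]
            ay = acts[y]
            coop_actions += ax + ay
            total_actions += 2
            pay[x] += b * ay - c * ax
            pay[y] += b * ax - c * ay
            if ax == 1 and ay == 1:
                if strat[x] != DEFECTOR:
                    S[x, y] = min(1.0, S[x, y] + r)
                if strat[y] != DEFECTOR:
                    S[y, x] = min(1.0, S[y, x] + r)
            else:
                if ay == 0 and strat[x] != DEFECTOR:
                    S[x, y] = max(-1.0, S[x, y] - r)
                if ax == 0 and strat[y] != DEFECTOR:
                    S[y, x] = max(-1.0, S[y, x] - r)

        # memory constraint: every agent forgets its weakest traces
        if k < n - 1:
            for x in range(n):
                prune_row(S, x, k)

        if snap_every > 0 and (it + 1) % snap_every == 0 and snap_i < snaps.shape[0]:
            for a in range(n):
                for bb in range(n):
                    snaps[snap_i, a, bb] = S[a, bb]
            snap_i += 1

        if (it + 1) % record_every == 0 and rec_i < records.shape[0]:
            records[rec_i, REC_ITER] = it + 1
            for s in range(N_STRATEGIES):
                records[rec_i, REC_COUNTS + s] = 0.0
                records[rec_i, REC_PAYOFF + s] = 0.0
            for a in range(n):
                records[rec_i, REC_COUNTS + strat[a]] += 1.0
                records[rec_i, REC_PAYOFF + strat[a]] += pay[a]
            for s in range(N_STRATEGIES):
                cnt = records[rec_i, REC_COUNTS + s]
                if cnt > 0:
                    records[rec_i, REC_PAYOFF + s] /= cnt
                else:
                    records[rec_i, REC_PAYOFF + s] = np.nan
            records[rec_i, REC_COOP] = (
                coop_actions / total_actions if total_actions > 0 else 0.0
            )
            coop_actions = 0
            total_actions = 0
            rec_i += 1

        # Moran generation boundary: one strategy adoption, payoffs reset
        if evolve and (it + 1) % i_per_gen == 0:
            moran_step(S, strat, pay, u, pool, reset_mode)
            for a in range(n):
                pay[a] = 0.0

    return rec_i, snap_i
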