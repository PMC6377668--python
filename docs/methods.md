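# Methods

## The model

A population of `n` agents interacts in discrete iterations, each with
three stages:

1. **Random matching.** Every agent is paired uniformly at random with
   another agent (a uniform perfect matching; with odd `n` one uniformly
   chosen agent sits out). Meeting probability is deliberately *not*
   biased by relationship strength, so group structure cannot be an
   artifact of assortative meeting.
2. **Action choice.** Each paired agent plays C (cooperate) or D (defect)
   in a Prisoner's Dilemma. Decisions are simultaneous: every agent
   decides from the reputation matrix as it stood at the start of the
   iteration.
3. **Relationship updating.** Action pairs update the signed relationship
   matrix (below), after which memory-constrained agents forget their
   weakest relationships.

### The reputation matrix

The social state is an `n x n` matrix `S` with `S[x, y]` in `[-1, 1]`:
agent `x`'s relationship with (opinion of) agent `y`. The diagonal is
fixed at 1 and the matrix starts as the identity — nobody knows anybody,
everybody trusts themselves. The bounds give self-trust an interpretable
role: no third party's opinion can be weighted more than one's own. The
matrix is directed and generally asymmetric.

Updates, with increment `r` per interaction (default 0.3):

| actions (x, y) | `S[x, y]` | `S[y, x]` |
|----------------|-----------|-----------|
| C, C           | `+r`      | `+r`      |
| C, D           | `-r`      | unchanged |
| D, C           | unchanged | `-r`      |
| D, D           | `-r`      | `-r`      |

An agent whose partner defected lowers its opinion; an agent that
exploited a cooperator leaves its own opinion unchanged (otherwise the two
directed opinions would anti-correlate and flip-flop). Results are clipped
to `[-1, 1]`; increments past the bound are truncated rather than
rejected, since more extreme values would barely change the decision
probabilities anyway. Always-defect agents never update their own row.

### Relationship scoring and decisions

Before acting, a reputation-sensitive agent `x` scores its partner `y` by
aggregating everyone's opinion of `y`, each weighted by `x`'s relationship
with the opinion holder:

    rs(x, y) = sum_{i != y} w(S[x, i]) * S[i, y]

The partner's own (fixed, uninformative) self-opinion `S[y, y] = 1` is
excluded; including it would add `S[x, y]` a second time and would break
the worked decision-probability values below. The focal agent's own
opinion enters exactly once, through the `i = x` term
`S[x, x] * S[x, y] = S[x, y]`.

The weight function `w` is the agent's strategy:

- **Full Heider** (`w(s) = s`): all four structural-balance heuristics — a
  friend of a friend is a friend, an enemy of a friend is an enemy, a
  friend of an enemy is an enemy, an enemy of an enemy is a friend.
- **Friend-focused** (`w(s) = max(0, s)`): opinions of disliked agents are
  discarded; only the two friendship heuristics operate.
- **Enemy-focused** (`w(s) = min(0, s)` for third parties, own opinion
  kept at weight 1): only the two enmity heuristics operate. Own direct
  experience is not "the opinion of a friend", so it is retained —
  dropping it would make these agents blind to their own history.
- **Incomplete Heider**: as full Heider but the product of two negatives
  (the enemy-of-an-enemy inference) is suppressed to zero.
- **Always-defect**: no scoring, no updating, always D.

The score feeds a logistic decision: `p(C) = 1 / (1 + exp(-rs / T))` with
temperature `T = 0.2`. From a neutral start, one mutual cooperation at
`r = 0.1` moves `p(C)` from 0.5 to 0.62; at `r = 0.5`, to 0.92. `r` and
`T` are interchangeable up to rescaling: both set how many interactions
build or destroy a relationship.

Scores are raw sums, not means: in a dense population `|rs|` grows with
`n` and saturates the logistic, making decisions near-deterministic. That
is the model as defined; a `normalize_rs` switch (divide by `n - 1`)
exists for exploration only and is off everywhere.

### Memory constraints

With capacity `k < n - 1`, after every iteration each agent keeps only the
`k` off-diagonal entries of its row with the largest absolute value — best
friends and worst enemies, the strongest memory traces — and forgets the
rest to the neutral value 0 (not removal: a forgotten relationship is
indistinguishable from "never met", matching the identity
initialization). Exact ties at the retention boundary are broken uniformly
at random from the simulation's single RNG stream.

### Evolution

Cooperating costs `c` and gives the partner `b > c`; defection is free and
gives nothing. Payoffs accumulate over the `i` iterations of a generation
(defaults `b = 4`, `c = 1`, `i = 10`). At each generation boundary one
uniformly chosen agent revises its strategy: with probability `u`
(default 0.01) it mutates to a uniformly random strategy from the
scenario's pool; otherwise it adopts the strategy of an agent drawn with
probability proportional to `exp(payoff)` — itself included, so it may
re-adopt its own strategy. Summed over strategies this is exactly the
frequency-dependent Moran process with exponential fitness. Payoffs then
reset: fitness reflects only the current generation. Exponentials are
max-shifted before normalization — algebraically identical and safe up to
the `b * i = 256` corner of the parameter grid.

**Relationships on adoption** (`reset_on_adoption`, default `"change"`):
an agent whose strategy actually changes re-enters the population socially
blank — its row and column reset to 0, as under a birth-death reading of
the Moran process in which the revising agent is replaced by an unrelated
newcomer. This choice is load-bearing. Negative relationships are
absorbing: only mutual cooperation raises an opinion, an agent with a
negative score defects, and a defecting agent facing a cooperator does not
update — so without any reset a population's web of mutual dislike hardens
permanently, full-Heider agents can never re-invade a settled
friend-focused population (their broad cooperative overtures are never
reciprocated and only subsidize the residents), and the fission–fusion
cycling the model is built to exhibit never recurs. With reset-on-change
the cycle runs: defector phases dissolve structure, friend-focused cliques
rebuild, Heider agents bridge and polarize, defectors invade the polarized
whole. `"never"` (pure social learning, relationships kept) and
`"always"` (reset even on re-adoption) are available as config options.

## Measurement layer

- **Mutual-positive graph**: undirected edge `(x, y)` iff `S[x, y] > 0`
  and `S[y, x] > 0` (strictly — neutral is not a link), weighted by the
  mean of the two directions.
- **Polarization**: Louvain community count of that graph
  (`networkx.community.louvain_communities`, resolution 1.0, fixed seed;
  isolated agents are singletons). Fewer, larger communities = more
  polarized; two communities is the maximally polarized balanced state.
- **Decay regression**: community count vs. number of full-Heider agents
  is fitted by nonlinear least squares. The default form is the pure
  exponential `y = A * exp(-x / tau)` — each added Heider agent multiplies
  the expected community count by `exp(-1/tau)`. A three-parameter form
  with a free asymptote is available (`model_form="offset"`), but with
  only six predictor values the asymptote and `tau` trade off strongly and
  the decay constant is weakly identified, so the two-parameter form is
  the headline analysis.
- **Majority states and cycles**: each generation is classified by its
  strict plurality strategy (MIXED on ties). The transition matrix is the
  maximum-likelihood estimate from transition counts. A fission–fusion
  cycle is a completed ordered traversal defector-majority →
  friend-majority → Heider-majority → defector-majority; MIXED generations
  are transparent (neither advance nor reset the tracker), a
  defector-majority generation restarts progress, and other out-of-order
  states leave the tracker unchanged. This is the minimal
  operationalization consistent with the narrative sequence
  defection → community building → polarization; absolute cycle counts
  depend on it (see limitations).
- **Rapoport index**: `K = (R - P) / (T - S) = (b - c) / (b + c)`, a
  normalized measure of how conducive the dilemma is to cooperation.
  Defined for `b >= c`; the printed unit-cost grid omits `b = 4`
  (`K = 3/5`), an apparent typo that the formula, not the list, governs.

## What the simulations emulate, and what they do not

All inputs are generated by the simulator itself from a seed; there is no
empirical data. The model abstracts real gossip-based cooperation heavily:
agents meet uniformly at random (no space, no assortment), reputation
information is exchanged instantly and truthfully, opinions are scalar,
and strategy revision touches one agent per generation. Passing tests
therefore show that the *mechanism* — balance-theoretic gossip weighting
producing parochial, cyclically reforming cooperation networks — behaves
as described, not that any empirical network will.

## Problem sizes and numerical choices

Long-run analyses use 1e5 pairing iterations (the scale at which
polarization outcomes are measured) and populations of 10–120 for network
formation, or `n = 100` with `4e4`–`4e5` iterations for evolutionary runs;
replicate counts are 14–20 per cell. These sizes keep the full acceptance
recomputation under ~3 minutes and the test suite under ~4 minutes on one
CPU while leaving Monte-Carlo error well inside the tolerances checked.
The iteration loop runs in a numba-compiled kernel; plain-numpy reference
implementations of every operation live in `core_model`/`evolution`, and
the suite asserts the two paths agree. Reproducibility is exact: a
(config, seed) pair determines every trajectory bit-for-bit. Louvain and
tie-breaking randomness are seeded. The logistic is evaluated with a
numerically stable implementation; it saturates to exactly 0/1 in double
precision for `|rs|/T` beyond ~37, which the dense-network regime reaches
by design.

## Known limitations

- The one-large-group outcome for pure-Heider populations (reported
  probability 0.07) did not occur in ~300 runs across `n = 10..120`; runs
  end in two factions (~95%) or occasionally three Louvain communities.
  The two-faction fraction (~0.97) is close to, but slightly above, the
  reported 0.93.
- Absolute fission–fusion cycle counts are sensitive to the (unstated)
  cycle-detection rule and to what "generation" denotes. Counted per
  Moran update, our three-strategy full-memory dynamic completes far
  fewer cycles than the published 24 per 1000; per `n` updates (the other
  common convention) the rate is the same order as the published 6–24
  range. Directional claims (faster cycling with full memory) reproduce.
- The decay constant of community count vs. Heider-agent number depends
  on the regression form (pure exponential: ~3.5; free-asymptote: ~1.5,
  weakly identified); the published 4.9 lies within the pure-exponential
  fit's uncertainty at these problem sizes.
- With `reset_on_adoption="never"` the evolutionary layer loses Heider
  re-invasion entirely (see above); results in that mode are provided for
  sensitivity analysis, not as the model proper.
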