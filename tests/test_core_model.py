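"""Core model: scoring rules, decisions, updating, memory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heidercoop.core_model import (
    Action,
    InvalidPopulationError,
    ModelParams,
    SelfInteractionError,
    Strategy,
    apply_memory_limit,
    decision_probability,
    init_reputation,
    relationship_score,
    update_relationships,
    validate_reputation,
)

from conftest import random_reputation

# The four structural-balance heuristics each strategy is allowed to use.
_CASE_SETS = {
    Strategy.HEIDER: {"fof", "eof", "foe", "eoe"},
    Strategy.FRIEND: {"fof", "eof"},
    Strategy.ENEMY: {"foe", "eoe"},
    Strategy.INCOMPLETE_HEIDER: {"fof", "eof", "foe"},
}


def oracle_score(S, x, y, strategy):
    """Brute-force scorer: sum case-labelled heuristic products one by one."""
    cases = _CASE_SETS[strategy]
    rs = 0.0
    for i in range(S.shape[0]):
        if i == y:
            continue
        w, o = S[x, i], S[i, y]
        if i == x:
            rs += w * o  # own opinion, self-trust weight 1, always counts
        elif w > 0 and o > 0 and "fof" in cases:
            rs += w * o
        elif w > 0 and o < 0 and "eof" in cases:
            rs += w * o
        elif w < 0 and o > 0 and "foe" in cases:
            rs += w * o
        elif w < 0 and o < 0 and "eoe" in cases:
            rs += w * o
    return rs


class TestInitReputation:
    @pytest.mark.parametrize("n", [2, 3, 7])
    def test_identity_at_start(self, n):
        assert np.array_equal(init_reputation(n), np.eye(n))

    @pytest.mark.parametrize("n", [0, 1, -3])
    def test_too_small_population_rejected(self, n):
        with pytest.raises(InvalidPopulationError):
            init_reputation(n)


class TestRelationshipScore:
    def test_single_own_relationship_is_the_score(self):
        # one mutual cooperation at r=0.1 from a neutral start: rs = 0.1
        S = init_reputation(4)
        S[0, 1] = 0.1
        assert relationship_score(S, 0, 1, Strategy.HEIDER) == pytest.approx(0.1)

    def test_enemy_of_enemy_is_a_friend(self):
        S = init_reputation(4)
        S[0, 2] = -1.0
        S[2, 1] = -1.0
        assert relationship_score(S, 0, 1, Strategy.HEIDER) == pytest.approx(1.0)

    def test_friend_focused_discards_enemy_opinion(self):
        S = init_reputation(4)
        S[0, 2] = -1.0
        S[2, 1] = -1.0
        assert relationship_score(S, 0, 1, Strategy.FRIEND) == pytest.approx(0.0)

    def test_incomplete_heider_suppresses_enemy_of_enemy(self):
        S = init_reputation(4)
        S[0, 2] = -1.0
        S[2, 1] = -1.0
        assert relationship_score(S, 0, 1, Strategy.INCOMPLETE_HEIDER) == pytest.approx(0.0)

    def test_enemy_focused_keeps_own_opinion(self):
        S = init_reputation(4)
        S[0, 1] = 0.6  # positive own experience
        S[0, 2] = 0.9  # friend's opinion must be ignored
        S[2, 1] = 1.0
        assert relationship_score(S, 0, 1, Strategy.ENEMY) == pytest.approx(0.6)

    @pytest.mark.parametrize("strategy", list(_CASE_SETS))
    def test_matches_bruteforce_heuristic_oracle(self, strategy, rng):
        for n in (3, 4, 5):
            for _ in range(20):
                S = random_reputation(n, rng, sparsity=0.3)
                for x in range(n):
                    for y in range(n):
                        if x == y:
                            continue
                        assert relationship_score(S, x, y, strategy) == pytest.approx(
                            oracle_score(S, x, y, strategy), abs=1e-12
                        )

    @pytest.mark.parametrize(
        "strategy",
        [Strategy.HEIDER, Strategy.INCOMPLETE_HEIDER, Strategy.ENEMY, Strategy.FRIEND],
    )
    def test_single_nonzero_entry_reduces_to_own_opinion(self, strategy):
        S = init_reputation(5)
        S[1, 3] = 0.4
        assert relationship_score(S, 1, 3, strategy) == pytest.approx(0.4)

    def test_heider_equals_friend_on_nonnegative_matrix(self, rng):
        S = np.abs(random_reputation(6, rng))
        np.fill_diagonal(S, 1.0)
        for x in range(6):
            for y in range(6):
                if x != y:
                    assert relationship_score(S, x, y, Strategy.HEIDER) == pytest.approx(
                        relationship_score(S, x, y, Strategy.FRIEND)
                    )

    def test_self_scoring_and_defector_rejected(self, small_matrix):
        with pytest.raises(SelfInteractionError):
            relationship_score(small_matrix, 2, 2, Strategy.HEIDER)
        with pytest.raises(ValueError):
            relationship_score(small_matrix, 0, 1, Strategy.DEFECTOR)


class TestDecisionProbability:
    @pytest.mark.parametrize(
        "rs,expected",
        [(0.0, 0.5), (0.1, 0.6225), (0.5, 0.9241), (-0.1, 0.3775)],
    )
    def test_logistic_values(self, rs, expected):
        assert decision_probability(rs, 0.2) == pytest.approx(expected, abs=5e-5)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-30, 30), st.floats(0.05, 5.0))
    def test_symmetry(self, ratio, temperature):
        # |rs/temperature| <= 30 keeps the logistic strictly inside (0, 1)
        # in double precision; beyond ~37 it saturates to exactly 1.0
        rs = ratio * temperature
        p = decision_probability(rs, temperature)
        q = decision_probability(-rs, temperature)
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            decision_probability(0.3, 0.0)


class TestUpdateRelationships:
    def test_mutual_cooperation_raises_both(self):
        S = init_reputation(3)
        out = update_relationships(S, 0, 1, Action.C, Action.C, 0.3)
        assert out[0, 1] == pytest.approx(0.3)
        assert out[1, 0] == pytest.approx(0.3)

    def test_defecting_on_cooperator_leaves_own_opinion(self):
        S = init_reputation(3)
        out = update_relationships(S, 0, 1, Action.D, Action.C, 0.3)
        assert out[0, 1] == 0.0  # x exploited y: x's opinion unchanged
        assert out[1, 0] == pytest.approx(-0.3)  # y downgrades x

    def test_mutual_defection_lowers_both(self):
        S = init_reputation(3)
        out = update_relationships(S, 0, 1, Action.D, Action.D, 0.3)
        assert out[0, 1] == pytest.approx(-0.3)
        assert out[1, 0] == pytest.approx(-0.3)

    def test_clipping_at_bounds(self):
        S = init_reputation(3)
        S[0, 1] = 0.9
        S[1, 0] = -0.9
        out = update_relationships(S, 0, 1, Action.C, Action.C, 0.3)
        assert out[0, 1] == 1.0
        out2 = update_relationships(S, 0, 1, Action.D, Action.D, 0.3)
        assert out2[1, 0] == -1.0

    def test_defector_row_frozen_but_partner_updates(self):
        S = init_reputation(3)
        out = update_relationships(
            S, 0, 1, Action.D, Action.D, 0.3, x_is_defector=True
        )
        assert out[0, 1] == 0.0
        assert out[1, 0] == pytest.approx(-0.3)

    def test_invariants_preserved_under_random_sequences(self, rng):
        S = init_reputation(6)
        for _ in range(500):
            x, y = rng.choice(6, size=2, replace=False)
            update_relationships(
                S, int(x), int(y),
                Action(int(rng.integers(2))), Action(int(rng.integers(2))),
                0.3, out=S,
            )
            validate_reputation(S)


class TestMemoryLimit:
    def test_capacity_at_least_stored_is_noop(self, rng):
        S = init_reputation(4)
        S[0, 1:] = [0.9, -0.8, 0.1]
        out = apply_memory_limit(S, 0, 3, rng)
        assert np.array_equal(out, S)

    def test_weakest_trace_forgotten(self, rng):
        S = init_reputation(4)
        S[0, 1:] = [0.9, -0.8, 0.1]
        out = apply_memory_limit(S, 0, 2, rng)
        assert list(out[0]) == [1.0, 0.9, -0.8, 0.0]

    def test_boundary_ties_forgotten_uniformly(self):
        rng = np.random.default_rng(99)
        forgotten = np.zeros(3)
        for _ in range(10_000):
            S = init_reputation(4)
            S[0, 1:] = [0.5, -0.5, 0.5]
            out = apply_memory_limit(S, 0, 2, rng)
            (zeroed,) = np.nonzero(out[0, 1:] == 0.0)
            assert len(zeroed) == 1
            forgotten[zeroed[0]] += 1
        assert np.all(np.abs(forgotten / 10_000 - 1 / 3) < 0.02)

    def test_idempotent_without_boundary_ties(self, rng):
        S = random_reputation(8, rng)
        once = apply_memory_limit(S, 2, 3, rng)
        twice = apply_memory_limit(once, 2, 3, rng)
        assert np.array_equal(once, twice)

    def test_out_of_range_capacity_rejected(self, rng):
        S = init_reputation(4)
        for k in (0, 4):
            with pytest.raises(ValueError):
                apply_memory_limit(S, 0, k, rng)


class TestModelParams:
    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ModelParams(r=0.0)
        with pytest.raises(ValueError):
            ModelParams(temperature=-1.0)
        with pytest.raises(ValueError):
            ModelParams(k=0)
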