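"""Measurement layer: graphs, communities, fits, Markov state analysis."""

import networkx as nx
import numpy as np
import pytest

from heidercoop.core_model import Strategy, init_reputation
from heidercoop.network_analysis import (
    FitError,
    MajorityState,
    classify_majority_state,
    cooperation_rate,
    count_communities,
    count_cycles,
    estimate_transition_matrix,
    fit_exponential_decay,
    mutual_positive_graph,
    outgoing_positive_connections,
    rapoport_index,
)

D = MajorityState.DEFECTOR_MAJ
F = MajorityState.FRIEND_MAJ
H = MajorityState.HEIDER_MAJ
MIX = MajorityState.MIXED


class TestMutualPositiveGraph:
    def test_identity_matrix_has_no_edges(self):
        G = mutual_positive_graph(init_reputation(6))
        assert G.number_of_nodes() == 6
        assert G.number_of_edges() == 0

    def test_mutuality_required(self):
        S = init_reputation(3)
        S[0, 1], S[1, 0] = 0.5, -0.2
        assert mutual_positive_graph(S).number_of_edges() == 0

    def test_edge_weight_is_mean_of_directions(self):
        S = init_reputation(3)
        S[0, 1], S[1, 0] = 0.5, 0.3
        G = mutual_positive_graph(S)
        assert G[0][1]["weight"] == pytest.approx(0.4)

    def test_threshold_is_strict(self):
        S = init_reputation(3)
        S[0, 1] = S[1, 0] = 0.5
        assert mutual_positive_graph(S, threshold=0.5).number_of_edges() == 0


class TestCommunities:
    def test_disjoint_cliques_match_connected_components(self, rng):
        # Louvain must agree with the connected-components oracle here
        for sizes in ([5, 5], [4, 6, 3], [10]):
            G = nx.Graph()
            offset = 0
            for m in sizes:
                G.add_edges_from(
                    (offset + a, offset + b) for a in range(m) for b in range(a + 1, m)
                )
                offset += m
            nx.set_edge_attributes(G, 1.0, "weight")
            _, count = count_communities(G)
            assert count == nx.number_connected_components(G) == len(sizes)

    def test_empty_graph_gives_singletons(self):
        G = nx.Graph()
        G.add_nodes_from(range(6))
        part, count = count_communities(G)
        assert count == 6
        assert sorted(part.labels) == list(range(6))

    def test_partition_covers_all_agents(self):
        G = mutual_positive_graph(init_reputation(4))
        part, _ = count_communities(G)
        assert set(part.labels) == {0, 1, 2, 3}
        assert len(part.to_frame()) == 4


class TestSimpleStatistics:
    def test_cooperation_rate(self):
        assert cooperation_rate([0, 0, 0]) == 0.0
        assert cooperation_rate([1, 1]) == 1.0
        assert cooperation_rate([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            cooperation_rate([])

    def test_outgoing_positive_connections(self):
        S = init_reputation(4)
        assert outgoing_positive_connections(S, 0) == 0
        S[1, [0, 2, 3]] = [0.2, -0.3, 0.7]
        assert outgoing_positive_connections(S, 1) == 2
        S2 = np.ones((100, 100))
        assert outgoing_positive_connections(S2, 5) == 99


class TestDecayFit:
    def test_exact_recovery_on_noiseless_decay(self):
        for tau in (0.5, 5.0, 40.0):
            x = np.arange(10, dtype=float)
            fit = fit_exponential_decay(x, 10 * np.exp(-x / tau))
            assert fit.tau == pytest.approx(tau, abs=1e-6)
            assert fit.model_form == "exponential"

    def test_offset_form_recovery(self):
        x = np.arange(12, dtype=float)
        y = 2.0 + 8.0 * np.exp(-x / 3.0)
        fit = fit_exponential_decay(x, y, model_form="offset")
        assert fit.tau == pytest.approx(3.0, abs=1e-6)
        assert fit.offset == pytest.approx(2.0, abs=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 15, 50)
        taus = []
        for _ in range(100):
            y = 2.0 + 8.0 * np.exp(-x / 3.0) + rng.normal(0, 0.05, x.size)
            taus.append(fit_exponential_decay(x, y, model_form="offset").tau)
        assert abs(np.mean(taus) - 3.0) / 3.0 < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_exponential_decay([0, 1, 2], [4.0, 4.0, 4.0])
        with pytest.raises(FitError):
            fit_exponential_decay([0, 1], [3.0, 1.0])


class TestRapoportIndex:
    @pytest.mark.parametrize(
        "b,expected",
        [(1, 0.0), (2, 1 / 3), (3, 1 / 2), (4, 3 / 5), (5, 2 / 3),
         (6, 5 / 7), (7, 3 / 4), (8, 7 / 9)],
    )
    def test_unit_cost_grid(self, b, expected):
        assert rapoport_index(b, 1.0) == pytest.approx(expected)

    def test_strictly_increasing_in_benefit(self):
        ks = [rapoport_index(b, 1.0) for b in np.linspace(1, 20, 50)]
        assert np.all(np.diff(ks) > 0)

    def test_invalid_games_rejected(self):
        with pytest.raises(ValueError):
            rapoport_index(1.0, 2.0)
        with pytest.raises(ValueError):
            rapoport_index(0.0, 0.0)


class TestMajorityStates:
    def test_plurality_classification(self):
        counts = {Strategy.FRIEND: 60, Strategy.HEIDER: 30, Strategy.DEFECTOR: 10}
        assert classify_majority_state(counts) == F
        assert classify_majority_state([40, 40, 20, 0, 0]) == MIX
        assert classify_majority_state([0, 0, 100, 0, 0]) == D

    def test_transition_matrix_counts_and_normalizes(self):
        tm = estimate_transition_matrix([D, D, F, F])
        assert tm.loc[D.value, D.value] == pytest.approx(0.5)
        assert tm.loc[D.value, F.value] == pytest.approx(0.5)
        assert tm.loc[F.value, F.value] == pytest.approx(1.0)

    def test_alternating_chain(self):
        tm = estimate_transition_matrix([D, F, D, F, D])
        assert tm.loc[D.value, F.value] == 1.0
        assert tm.loc[F.value, D.value] == 1.0

    def test_defined_rows_are_stochastic(self):
        tm = estimate_transition_matrix([D, F, MIX, H, D, F], drop_mixed=True)
        sums = tm.sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 1.0)

    def test_mle_recovers_known_chain(self):
        rng = np.random.default_rng(4)
        p_ab, p_ba = 0.1, 0.3
        states, s = [], 0
        for _ in range(10_000):
            states.append([D, F][s])
            s = (1 - s) if rng.random() < (p_ab if s == 0 else p_ba) else s
        tm = estimate_transition_matrix(states)
        assert tm.loc[D.value, F.value] == pytest.approx(p_ab, abs=0.02)
        assert tm.loc[F.value, D.value] == pytest.approx(p_ba, abs=0.02)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition_matrix([D])


class TestCycleCounting:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([D, F, H, D], 1.0),
            ([D, F, D, F, D], 0.0),
            ([D, F, MIX, H, D, F, H, D], 2.0),
            ([F, H, D, F, H, D], 1.0),  # no initial defection phase: first
            # cycle starts at the first DEFECTOR_MAJ generation
            ([H, H, H], 0.0),
        ],
    )
    def test_phase_tracker(self, states, expected):
        assert count_cycles(states, per=None) == expected

    def test_normalization_per_thousand(self):
        assert count_cycles([D, F, H, D], per=1000.0) == pytest.approx(250.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            count_cycles([])
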