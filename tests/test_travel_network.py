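import io

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import firewoodnet as fw
from helpers import brute_quarantine_selection, random_stochastic_network


def star_network(n):
    """Hub-and-spoke: every leaf sends all trips to the hub, hub splits evenly."""
    P = np.zeros((n, n))
    P[0, 1:] = 1.0
    P[1:, 0] = 1.0 / (n - 1)
    return fw.TravelNetwork(list(range(n)), P)


def path_network(ids):
    """Bidirectional path with equal trip counts on every edge."""
    n = len(ids)
    C = np.zeros((n, n))
    for i in range(n - 1):
        C[i, i + 1] = C[i + 1, i] = 1.0
    return fw.TravelNetwork(ids, fw.normalize_trip_fractions(C))


class TestNormalize:
    @pytest.mark.parametrize(
        "column, expected",
        [((2.0, 2.0), (0.5, 0.5)), ((9.0, 1.0), (0.9, 0.1))],
    )
    def test_hand_normalization(self, column, expected):
        C = np.array([[column[0], 1.0], [column[1], 1.0]])
        P = fw.normalize_trip_fractions(C)
        np.testing.assert_allclose(P[:, 0], expected)

    def test_identity_counts_already_stochastic(self):
        np.testing.assert_array_equal(
            fw.normalize_trip_fractions(np.eye(4)), np.eye(4)
        )

    def test_zero_column_error_policy(self):
        C = np.array([[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(fw.NetworkError, match="zero outgoing"):
            fw.normalize_trip_fractions(C, zero_column_policy="error")

    def test_zero_column_self_loop_policy(self):
        C = np.array([[0.0, 3.0], [0.0, 1.0]])
        P = fw.normalize_trip_fractions(C, zero_column_policy="self_loop")
        np.testing.assert_allclose(P[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(P[:, 1], [0.75, 0.25])

    def test_negative_counts_rejected(self):
        with pytest.raises(fw.NetworkError, match="nonnegative"):
            fw.normalize_trip_fractions(np.array([[1.0, -1.0], [1.0, 2.0]]))

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 6), st.integers(2, 6)).map(
                lambda ab: (ab[0], ab[0])
            ),
            elements=st.floats(0, 1000),
        )
    )
    def test_columns_sum_to_one(self, C):
        P = fw.normalize_trip_fractions(C, zero_column_policy="self_loop")
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)


class TestLoadTripTable:
    def test_two_node_single_edges(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("origin,destination,trips\na,b,10\nb,a,10\n")
        net = fw.load_trip_table(f)
        ia, ib = net.index_of("a"), net.index_of("b")
        assert net.trip_fraction[ib, ia] == 1.0
        assert net.trip_fraction[ia, ib] == 1.0

    def test_three_node_self_loop_policy(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("origin,destination,trips\na,b,3\na,c,1\n")
        net = fw.load_trip_table(f, zero_trip_policy="self_loop")
        assert net.node_ids == ["a", "b", "c"]
        np.testing.assert_allclose(net.trip_fraction[:, 0], [0.0, 0.75, 0.25])
        np.testing.assert_allclose(net.trip_fraction[:, 1], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(net.trip_fraction[:, 2], [0.0, 0.0, 1.0])

    def test_negative_trips_rejected_with_line(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("origin,destination,trips\na,b,5\na,b,-1\nb,a,2\n")
        with pytest.raises(fw.NetworkError, match="line 3"):
            fw.load_trip_table(f)

    def test_malformed_row_names_line(self):
        src = io.StringIO("origin,destination,trips\na,b,5\nb,a,oops\n")
        with pytest.raises(fw.EdgeListParseError, match="line 3"):
            fw.load_trip_table(src)

    def test_duplicate_pairs_summed_with_warning(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("origin,destination,trips\na,b,3\na,b,1\nb,a,4\n")
        with pytest.warns(UserWarning, match="duplicate"):
            net = fw.load_trip_table(f)
        assert net.trip_fraction[net.index_of("b"), net.index_of("a")] == 1.0

    def test_drop_policy_removes_trip_less_origins(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("origin,destination,trips\na,b,3\nb,a,1\na,c,2\n")
        net = fw.load_trip_table(f, zero_trip_policy="drop")
        assert net.node_ids == ["a", "b"]

    def test_node_table_must_cover_edge_ids(self, tmp_path):
        e = tmp_path / "e.csv"
        e.write_text("origin,destination,trips\na,b,1\nb,a,1\n")
        nt = tmp_path / "n.csv"
        nt.write_text("id,x,y,population,is_focal\na,0,0,1,True\n")
        with pytest.raises(fw.NetworkError, match="absent"):
            fw.load_trip_table(e, nt)

    def test_csv_round_trip(self, tmp_path, small_network):
        edge, node = tmp_path / "edges.csv", tmp_path / "nodes.csv"
        small_network.to_csv(edge, node)
        back = fw.load_trip_table(edge, node)
        assert back.node_ids == small_network.node_ids
        np.testing.assert_allclose(
            back.trip_fraction, small_network.trip_fraction, atol=1e-12
        )
        assert back.focal_node == small_network.focal_node


class TestKCore:
    def test_complete_graph_is_its_own_core(self):
        n = 12
        C = np.ones((n, n)) - np.eye(n)
        net = fw.TravelNetwork(list(range(n)), fw.normalize_trip_fractions(C))
        reduced = fw.k_core_reduce(net, 10)
        assert reduced.node_ids == net.node_ids

    def test_star_two_core_is_empty(self):
        with pytest.raises(fw.NetworkError, match="empty"):
            fw.k_core_reduce(star_network(20), 2)

    def test_path_one_core_unchanged(self):
        net = path_network(["a", "b", "c", "d"])
        assert fw.k_core_reduce(net, 1).node_ids == ["a", "b", "c", "d"]

    def test_idempotent(self, medium_network):
        once = fw.k_core_reduce(medium_network, 5)
        twice = fw.k_core_reduce(once, 5)
        assert twice.node_ids == once.node_ids

    def test_columns_stay_stochastic(self, medium_network):
        reduced = fw.k_core_reduce(medium_network, 5)
        np.testing.assert_allclose(
            reduced.trip_fraction.sum(axis=0), 1.0, atol=1e-9
        )

    def test_invalid_k(self, small_network):
        with pytest.raises(fw.NetworkError):
            fw.k_core_reduce(small_network, 0)


class TestQuarantineSelection:
    def test_star_hub_selected(self):
        assert fw.quarantine_node_selection(star_network(8), 1) == [0]

    def test_path_middle_selected(self):
        net = path_network(["a", "b", "c", "d", "e"])
        assert fw.quarantine_node_selection(net, 1) == ["c"]
        assert fw.quarantine_node_selection(net, 1) == brute_quarantine_selection(
            net, 1
        )

    def test_empty_selection(self, small_network):
        assert fw.quarantine_node_selection(small_network, 0) == []

    def test_oversized_selection_rejected(self, small_network):
        with pytest.raises(fw.NetworkError):
            fw.quarantine_node_selection(small_network, small_network.n + 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        net = random_stochastic_network(rng)
        n_sel = net.n // 3 + 1
        assert fw.quarantine_node_selection(net, n_sel) == brute_quarantine_selection(
            net, n_sel
        )


class TestSyntheticGenerator:
    def test_seed_determinism(self):
        a = fw.generate_synthetic_network(50, seed=1)
        b = fw.generate_synthetic_network(50, seed=1)
        np.testing.assert_array_equal(a.trip_fraction, b.trip_fraction)
        assert a.node_ids == b.node_ids
        assert a.focal_node == b.focal_node

    def test_different_seeds_differ(self):
        a = fw.generate_synthetic_network(50, seed=1)
        b = fw.generate_synthetic_network(50, seed=2)
        assert not np.array_equal(a.trip_fraction, b.trip_fraction)

    def test_flat_gravity_equal_populations_uniform(self):
        net = fw.generate_synthetic_network(
            20, seed=3, gravity_exponent=0.0, population_spread=0.0, focal_boost=1.0
        )
        off = net.trip_fraction[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 19.0, atol=1e-12)

    def test_focal_boost_dominates_incoming_fractions(self):
        net = fw.generate_synthetic_network(40, seed=5, focal_boost=100.0)
        incoming = net.trip_fraction.sum(axis=1)
        assert net.node_ids[int(np.argmax(incoming))] == net.focal_node

    def test_column_stochastic(self, medium_network):
        np.testing.assert_allclose(
            medium_network.trip_fraction.sum(axis=0), 1.0, atol=1e-9
        )

    def test_too_few_nodes_rejected(self):
        with pytest.raises(fw.NetworkError):
            fw.generate_synthetic_network(1, seed=0)


class TestTravelNetworkInvariants:
    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(fw.NetworkError, match="stochastic"):
            fw.TravelNetwork([0, 1], np.array([[0.3, 1.0], [0.3, 0.0]]))

    def test_single_node_rejected(self):
        with pytest.raises(fw.NetworkError, match="at least 2"):
            fw.TravelNetwork([0], np.array([[1.0]]))

    def test_unknown_node_lookup(self, small_network):
        with pytest.raises(fw.NetworkError, match="unknown"):
            small_network.index_of("nope")
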