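"""Network construction: Pearson matrix, reciprocal distances, density views."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainph import (
    CorrelationMatrix,
    DistanceMatrix,
    MultichannelRecording,
    max_threshold,
    pearson_matrix,
    reciprocal_distance,
    threshold_by_density,
    write_edge_weights,
)


def rec_from_rows(*rows):
    return MultichannelRecording(np.array(rows, dtype=float), 100.0)


class TestPearson:
    def test_duplicated_channel_gives_unit_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        r = pearson_matrix(rec_from_rows(x, x)).values
        assert r[0, 1] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        r = pearson_matrix(rec_from_rows(x, -x)).values
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r((1,2,3),(1,2,4)) = 9 / (2*sqrt(21))
        r = pearson_matrix(rec_from_rows([1, 2, 3], [1, 2, 4])).values
        assert r[0, 1] == pytest.approx(9 / (2 * math.sqrt(21)))

    def test_zero_variance_channel_named_in_error(self):
        rec = MultichannelRecording(
            np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]), 100.0,
            ["good", "flatline"])
        with pytest.raises(ValueError, match="flatline"):
            pearson_matrix(rec)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_matrix(rec_from_rows([1, 2], [3, 1]))

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, a, b):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((3, 50))
        scaled = base.copy()
        scaled[0] = a * scaled[0] + b
        r1 = pearson_matrix(MultichannelRecording(base, 100.0)).values
        r2 = pearson_matrix(MultichannelRecording(scaled, 100.0)).values
        assert np.allclose(r1, r2, atol=1e-10)


class TestReciprocalDistance:
    def corr(self, r01):
        m = np.array([[1.0, r01], [r01, 1.0]])
        return CorrelationMatrix(m)

    def test_unit_correlation_distance_one(self):
        d = reciprocal_distance(self.corr(1.0))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        r = 9 / (2 * math.sqrt(21))
        d = reciprocal_distance(self.corr(r))
        assert d.values[0, 1] == pytest.approx(1 / r)
        assert d.values[0, 1] == pytest.approx(1.01835, abs=1e-5)

    def test_zero_correlation_hits_cap(self):
        d = reciprocal_distance(self.corr(0.0), cap=100.0)
        assert d.values[0, 1] == 100.0

    def test_anticorrelation_treated_as_coupling(self):
        assert reciprocal_distance(self.corr(-0.5)).values[0, 1] == pytest.approx(2.0)

    def test_cap_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            reciprocal_distance(self.corr(0.5), cap=1.0)

    @given(ra=st.floats(0.05, 1.0), rb=st.floats(0.05, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_antitone_in_correlation_magnitude(self, ra, rb):
        da = reciprocal_distance(self.corr(ra), cap=1e6).values[0, 1]
        db = reciprocal_distance(self.corr(rb), cap=1e6).values[0, 1]
        if ra > rb:
            assert da < db or math.isclose(da, db)


class TestDensityThreshold:
    def four_node_corr(self):
        m = np.eye(4)
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        return CorrelationMatrix(m)

    def test_full_density_complete_graph(self):
        adj = threshold_by_density(self.four_node_corr(), 1.0)
        assert adj.sum() // 2 == 6

    def test_zero_density_empty_graph(self):
        assert threshold_by_density(self.four_node_corr(), 0.0).sum() == 0

    def test_half_density_keeps_three_strongest(self):
        adj = threshold_by_density(self.four_node_corr(), 0.5)
        expected = {(0, 1), (0, 2), (0, 3)}
        edges = {(i, j) for i in range(4) for j in range(i + 1, 4) if adj[i, j]}
        assert edges == expected

    def test_tie_group_kept_whole(self):
        m = np.eye(4)
        for i in range(4):
            for j in range(i + 1, 4):
                m[i, j] = m[j, i] = 0.5  # all tied
        adj = threshold_by_density(CorrelationMatrix(m), 0.5)
        assert adj.sum() // 2 == 6  # target 3, tie group pulls in all 6

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            threshold_by_density(self.four_node_corr(), 1.2)

    @given(density=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_edge_count_matches_floor_without_ties(self, density):
        rng = np.random.default_rng(8)
        # distinct |r| values -> no tie groups
        n = 8
        vals = rng.permutation(np.linspace(0.1, 0.95, n * (n - 1) // 2))
        m = np.eye(n)
        iu = np.triu_indices(n, k=1)
        m[iu] = vals
        m += np.triu(m, 1).T
        adj = threshold_by_density(CorrelationMatrix(m), density)
        assert adj.sum() // 2 == int(math.floor(density * len(vals)))


class TestEdgeWeights:
    def test_three_node_matrix_gives_three_rows(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        assert len(write_edge_weights(d)) == 3

    def test_sixty_nodes_give_1770_rows(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(1, 5, (60, 60))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        assert len(write_edge_weights(DistanceMatrix(m))) == 1770

    def test_round_trip_through_text(self, tmp_path):
        rng = np.random.default_rng(1)
        m = rng.uniform(1, 5, (7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = DistanceMatrix(m)
        edges = write_edge_weights(d)
        p = tmp_path / "edges.txt"
        edges.to_text(p)
        from brainph import EdgeWeightList
        back = EdgeWeightList.from_text(p)
        assert np.array_equal(back.to_distance_matrix().values, d.values)

    def test_rows_in_lexicographic_order(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        e = write_edge_weights(d)
        pairs = list(zip(e.i, e.j))
        assert pairs == sorted(pairs)


class TestMaxThreshold:
    def test_returns_max_off_diagonal(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        assert max_threshold(d) == 3.0

    def test_constant_matrix(self):
        m = np.full((4, 4), 2.5)
        np.fill_diagonal(m, 0)
        assert max_threshold(DistanceMatrix(m)) == 2.5

    def test_cap_dominates_when_correlation_vanishes(self):
        m = np.eye(4)
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.0}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        d = reciprocal_distance(CorrelationMatrix(m), cap=100.0)
        assert max_threshold(d) == 100.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="2 nodes"):
            max_threshold(DistanceMatrix(np.zeros((1, 1))))
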