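"""Persistence: known-homology fixtures, oracle equivalence, Betti accounting."""

import math

import numpy as np
import pytest

from brainph import (
    GeometricFixture,
    betti_numbers_at,
    brute_force_oracle,
    classify_intervals,
    generate_fixture,
    persistent_homology,
    rips_filtration,
)
from brainph.persist import PersistenceDiagram, PersistenceInterval
from brainph.rips import Filtration, Simplex, count_by_dimension

from .conftest import random_distance_matrix

SQRT2 = math.sqrt(2)


def diagram_of(points: np.ndarray, max_dim: int = 2, eps_max: float | None = None):
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    f = rips_filtration(d, max_dim=max_dim, eps_max=eps_max)
    return persistent_homology(f)


class TestKnownHomology:
    def test_single_point_one_essential_component(self):
        f = rips_filtration(np.zeros((1, 1)), max_dim=2, eps_max=1.0)
        diag = persistent_homology(f)
        assert len(diag) == 1
        (iv,) = diag.intervals
        assert iv.dimension == 0 and iv.birth == 0.0 and iv.essential

    def test_unit_square(self, square_cloud):
        diag = diagram_of(square_cloud.coordinates, max_dim=2, eps_max=2.0)
        dim0 = diag.in_dimension(0)
        assert len(dim0) == 4
        finite0 = [iv for iv in dim0 if not iv.essential]
        assert all(iv.birth == 0.0 and iv.death == 1.0 for iv in finite0)
        assert sum(iv.essential for iv in dim0) == 1
        (loop,) = diag.in_dimension(1)
        assert loop.birth == pytest.approx(1.0)
        assert loop.death == pytest.approx(SQRT2)

    def test_equilateral_triangle_loop_is_invisible(self):
        pts = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        diag = diagram_of(pts, max_dim=2, eps_max=1.5)
        assert diag.in_dimension(1) == []
        dim0 = diag.in_dimension(0)
        assert len(dim0) == 3 and sum(iv.essential for iv in dim0) == 1

    def test_circle_single_dominant_loop(self, circle20):
        diag = diagram_of(circle20.coordinates, max_dim=2)
        loops = sorted(diag.in_dimension(1), key=lambda iv: -iv.length)
        assert len(loops) >= 1
        main = loops[0]
        assert main.birth == pytest.approx(2 * math.sin(math.pi / 20))
        if len(loops) > 1:
            assert main.length >= 5 * loops[1].length
        assert sum(iv.essential for iv in diag.in_dimension(0)) == 1

    def test_sphere_single_dominant_void(self):
        pc = generate_fixture(GeometricFixture("sphere", n_points=24))
        diag = diagram_of(pc.coordinates, max_dim=3, eps_max=2.0)
        voids = sorted(diag.in_dimension(2), key=lambda iv: -iv.length)
        assert len(voids) >= 1
        if len(voids) > 1:
            assert voids[0].length >= 5 * voids[1].length
        assert sum(iv.essential for iv in diag.in_dimension(0)) == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", ["square", "circle", "line"])
    def test_fixtures_match_oracle(self, fixture):
        n = {"square": 4, "circle": 12, "line": 5}[fixture]
        pc = generate_fixture(GeometricFixture(fixture, n_points=n))
        d = pc.distance_matrix()
        f = rips_filtration(d, max_dim=2, eps_max=float(d.max()) * 1.01)
        assert persistent_homology(f).as_multiset() == brute_force_oracle(f).as_multiset()

    def test_fifty_random_clouds_match_oracle(self):
        rng = np.random.default_rng(123)
        for trial in range(50):
            n = int(rng.integers(4, 9))
            dist = random_distance_matrix(rng, n)
            eps = float(rng.uniform(0.3, 1.0)) * float(dist.max())
            f = rips_filtration(dist, max_dim=3, eps_max=eps)
            a = persistent_homology(f).as_multiset()
            b = brute_force_oracle(f).as_multiset()
            assert a == b, f"trial {trial}: diagrams differ"

    def test_empty_filtration(self):
        f = Filtration([], max_dimension=2, eps_max=1.0)
        assert len(brute_force_oracle(f)) == 0
        assert len(persistent_homology(f)) == 0

    def test_oracle_refuses_large_input(self):
        d = np.ones((40, 40)) - np.eye(40)
        f = rips_filtration(d, max_dim=3, eps_max=2.0)
        with pytest.raises(ValueError, match="2000"):
            brute_force_oracle(f)


class TestBettiAccounting:
    def test_dim0_interval_count_equals_vertices(self):
        rng = np.random.default_rng(9)
        for n in (3, 6, 10):
            dist = random_distance_matrix(rng, n)
            f = rips_filtration(dist, max_dim=2, eps_max=float(dist.max()))
            diag = persistent_homology(f)
            assert len(diag.in_dimension(0)) == n
            assert betti_numbers_at(diag, 0.0)[0] == n

    def test_betti_beyond_all_deaths(self):
        rng = np.random.default_rng(10)
        dist = random_distance_matrix(rng, 8)
        f = rips_filtration(dist, max_dim=2, eps_max=float(dist.max()))
        diag = persistent_homology(f)
        betti = betti_numbers_at(diag, diag.eps_max)
        assert betti[0] == 1  # fully connected at the max distance

    def test_square_betti_at_mid_scale(self, square_cloud):
        diag = diagram_of(square_cloud.coordinates, max_dim=2, eps_max=2.0)
        betti = betti_numbers_at(diag, 1.2)
        assert betti[0] == 1 and betti[1] == 1

    def test_circle_betti_at_mid_scale(self, circle20):
        diag = diagram_of(circle20.coordinates, max_dim=2)
        betti = betti_numbers_at(diag, 1.0)
        assert betti[0] == 1 and betti[1] == 1

    def test_out_of_range_eps_rejected(self, circle20):
        diag = diagram_of(circle20.coordinates, max_dim=2)
        with pytest.raises(ValueError, match="outside"):
            betti_numbers_at(diag, diag.eps_max * 2)

    def test_euler_characteristic_consistency(self):
        # chi from simplex counts equals alternating betti sum when the
        # complex dimension bounds the homology actually present
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for eps in (0.5, 1.0, 1.2, SQRT2):
            f = rips_filtration(d, max_dim=3, eps_max=eps)
            counts = count_by_dimension(f)
            chi_simplices = sum((-1) ** k * counts.get(k, 0) for k in range(4))
            diag = persistent_homology(f)
            betti = betti_numbers_at(diag, eps)
            chi_homology = sum((-1) ** k * betti.get(k, 0) for k in betti)
            assert chi_simplices == chi_homology


class TestClassification:
    def diag(self):
        return PersistenceDiagram(
            [PersistenceInterval(0, 0.0, math.inf),
             PersistenceInterval(0, 0.0, 1.0),
             PersistenceInterval(1, 1.0, SQRT2)],
            max_dimension=1, eps_max=2.0)

    def test_zero_min_length_everything_persistent(self):
        persistent, noise = classify_intervals(self.diag(), 0.0)
        assert len(persistent) == 3 and noise == []

    def test_square_loop_is_noise_at_half_unit(self):
        persistent, noise = classify_intervals(self.diag(), 0.5)
        assert any(iv.dimension == 1 for iv in noise)  # length ~0.414 < 0.5

    def test_only_essential_survive_huge_min_length(self):
        persistent, _ = classify_intervals(self.diag(), 10.0)
        assert all(iv.essential for iv in persistent)

    def test_negative_min_length_rejected(self):
        with pytest.raises(ValueError):
            classify_intervals(self.diag(), -1.0)


class TestDiagramIO:
    def test_round_trip_with_essential_classes(self, tmp_path, square_cloud):
        diag = diagram_of(square_cloud.coordinates, max_dim=2, eps_max=2.0)
        p = tmp_path / "diagram.tsv"
        diag.to_text(p)
        back = PersistenceDiagram.from_text(p)
        assert back.as_multiset() == diag.as_multiset()
        assert back.eps_max == diag.eps_max

    def test_closure_violation_rejected_with_offender(self):
        bad = Filtration([(Simplex((0,)), 0.0), (Simplex((0, 1)), 1.0),
                          (Simplex((1,)), 0.0)], max_dimension=1, eps_max=2.0)
        bad.simplices.append((Simplex((1, 2)), 1.0))  # vertex 2 missing
        with pytest.raises(ValueError, match=r"\(2,\)"):
            persistent_homology(bad)
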