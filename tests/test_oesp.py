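import numpy as np
import pytest

from morphpro import (
    ascore,
    brute_force_oesp,
    escore,
    line_angle,
    proteinize,
    proteinize_advanced,
    proteinize_basic,
    proteinize_simplified,
    vertex_angle,
    vscore,
)
from .conftest import random_tiny_instance

INF = float("inf")

# Instance (found by seeded search, reproduced verbatim) on which the greedy
# per-vertex angle history of the simplified strategy dead-ends while the
# exact pairwise-state recurrence still finds a feasible path.
SIMPLIFIED_BLIND_SPOT = np.array([
    [0.0, 0.0, 0.0],
    [-0.78532101, 3.80710709, 0.62359752],
    [0.11516556, 7.05448149, 2.98213002],
    [-3.33142172, 5.35688912, 3.09468824],
])


class TestScorePrimitives:
    @pytest.mark.parametrize(
        "distance,broken,expected",
        [(3.8, False, 0.0), (3.7, False, 0.0), (3.9, False, 0.0),
         (3.65, False, INF), (3.95, False, INF), (10.0, True, 0.0)],
    )
    def test_escore_distance_window(self, distance, broken, expected):
        assert escore([0, 0, 0], [distance, 0, 0], broken=broken) == expected

    def test_vscore_is_squared_displacement(self):
        assert vscore([0.5, 0, 0], [0, 0, 0]) == pytest.approx(0.25)
        assert vscore([0, 0, 0], [0, 0, 0]) == 0.0

    def test_vscore_steric_penalty_near_earlier_center(self):
        # one earlier centre 1.0 A away (inside z = 2.0): d^2 + 100 / 1.0^2
        value = vscore([0.5, 0, 0], [0, 0, 0], earlier_centers=[[1.5, 0, 0]])
        assert value == pytest.approx(0.25 + 100.0)

    def test_vscore_no_penalty_when_clear(self):
        value = vscore([0.5, 0, 0], [0, 0, 0], earlier_centers=[[10.0, 0, 0]])
        assert value == pytest.approx(0.25)

    def test_vscore_coincident_with_earlier_center_is_infinite(self):
        assert vscore([1.5, 0, 0], [0, 0, 0], earlier_centers=[[1.5, 0, 0]]) == INF

    @pytest.mark.parametrize(
        "q3,expected_vertex,expected_line",
        [((2.0, 0, 0), 180.0, 0.0),
         ((1.0, 1.0, 0), 90.0, 90.0),
         ((1.5, 0.866, 0), 120.0, 60.0)],
    )
    def test_both_angle_readings(self, q3, expected_vertex, expected_line):
        assert vertex_angle([0, 0, 0], [1, 0, 0], q3) == pytest.approx(expected_vertex, abs=1e-3)
        assert line_angle([0, 0, 0], [1, 0, 0], q3) == pytest.approx(expected_line, abs=1e-3)

    def test_degenerate_angle_arm_rejected(self):
        with pytest.raises(ValueError):
            vertex_angle([1, 0, 0], [1, 0, 0], [2, 0, 0])

    @pytest.mark.parametrize(
        "q3,broken,expected",
        [((1.0, 1.0, 0.0), False, 0.0),       # 90 deg
         ((2.0, 0.0, 0.0), False, INF),       # collinear, 180 deg
         ((1.5, np.sqrt(3) / 2, 0.0), False, 0.0),  # exactly 120 deg (closed boundary)
         ((0.5, 0.866, 0.0), False, INF),     # 60 deg
         ((0.5, 0.866, 0.0), True, 0.0)],     # gap angles are free
    )
    def test_ascore_angle_window(self, q3, broken, expected):
        assert ascore([0, 0, 0], [1, 0, 0], q3, broken=broken) == expected


class TestProteinizeBasic:
    def test_valid_chain_unchanged_with_zero_score(self, valid_chain):
        result = proteinize_basic(valid_chain.coords)
        assert result.feasible and result.total_score == 0.0
        np.testing.assert_allclose(result.points, valid_chain.coords, atol=1e-12)

    def test_stretched_line_corrected_into_window(self, params):
        pts = np.array([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]], float)
        result = proteinize_basic(pts, density=2)
        assert result.feasible
        spacing = np.linalg.norm(np.diff(result.points, axis=0), axis=1)
        assert np.all(spacing >= params.dist_low - 1e-9)
        assert np.all(spacing <= params.dist_high + 1e-9)
        oracle = brute_force_oesp(pts, density=2, include_angles=False, include_steric=False)
        assert result.total_score == pytest.approx(oracle.total_score, abs=1e-9)

    def test_unbridgeable_gap_is_infeasible(self):
        pts = np.array([[0, 0, 0], [50.0, 0, 0]], float)
        result = proteinize_basic(pts, edge_length=2.0)
        assert not result.feasible and result.total_score == INF and result.points is None

    def test_broken_edge_frees_the_distance_window(self):
        pts = np.array([[0, 0, 0], [50.0, 0, 0]], float)
        result = proteinize_basic(pts, edge_length=2.0, broken_edge=[True])
        assert result.feasible and result.total_score == 0.0


class TestProteinizeAdvanced:
    def test_valid_chain_unchanged(self, small_chain):
        result = proteinize_advanced(small_chain.coords)
        assert result.feasible and result.total_score == 0.0
        np.testing.assert_allclose(result.points, small_chain.coords, atol=1e-12)

    def test_collinear_instance_feasible_only_without_angles(self):
        # The only equidistant corrections of a straight 4.0 A chain stay
        # nearly collinear, violating the 120-degree angle ceiling.
        pts = np.array([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]], float)
        assert proteinize_basic(pts, density=2).feasible
        assert not proteinize_advanced(pts, density=2).feasible
        assert not brute_force_oesp(pts, density=2).feasible

    def test_matches_oracle_on_random_tiny_instances(self):
        rng = np.random.default_rng(10)
        checked = 0
        for _ in range(40):
            pts = random_tiny_instance(rng)
            adv = proteinize_advanced(pts, density=2)
            oracle = brute_force_oesp(pts, density=2)
            assert adv.feasible == oracle.feasible
            if adv.feasible:
                assert adv.total_score == pytest.approx(oracle.total_score, abs=1e-9)
                checked += 1
        assert checked >= 10

    def test_two_points_reduce_to_basic(self):
        pts = np.array([[0, 0, 0], [4.0, 0, 0]], float)
        adv = proteinize_advanced(pts, density=2)
        bas = proteinize_basic(pts, density=2)
        assert adv.feasible == bas.feasible
        assert adv.total_score == pytest.approx(bas.total_score, abs=1e-12)


class TestProteinizeSimplified:
    def test_valid_chain_unchanged(self, valid_chain):
        result = proteinize_simplified(valid_chain.coords)
        assert result.feasible and result.total_score == 0.0
        np.testing.assert_allclose(result.points, valid_chain.coords, atol=1e-12)

    def test_never_beats_the_exact_strategy(self):
        rng = np.random.default_rng(11)
        compared = 0
        for _ in range(30):
            pts = random_tiny_instance(rng)
            simp = proteinize_simplified(pts, density=2)
            if not simp.feasible:
                continue
            adv = proteinize_advanced(pts, density=2)
            assert adv.feasible
            assert simp.total_score >= adv.total_score - 1e-9
            compared += 1
        assert compared >= 10

    def test_blind_spot_instance_fails_where_advanced_succeeds(self):
        simp = proteinize_simplified(SIMPLIFIED_BLIND_SPOT, density=2)
        adv = proteinize_advanced(SIMPLIFIED_BLIND_SPOT, density=2)
        assert not simp.feasible and adv.feasible

    def test_output_satisfies_all_constraints(self, params):
        from morphpro import check_protein_like

        rng = np.random.default_rng(12)
        produced = 0
        for _ in range(20):
            pts = random_tiny_instance(rng, n=4)
            simp = proteinize_simplified(pts, density=2)
            if simp.feasible:
                assert check_protein_like(simp.points, params).all_pass
                produced += 1
        assert produced >= 5


class TestStrategyRelations:
    def test_basic_never_scores_above_advanced(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pts = random_tiny_instance(rng)
            bas = proteinize_basic(pts, density=2)
            adv = proteinize_advanced(pts, density=2)
            if bas.feasible and adv.feasible:
                assert bas.total_score <= adv.total_score + 1e-9

    @pytest.mark.parametrize("strategy", ["basic", "advanced", "simplified"])
    def test_idempotence(self, strategy, small_chain):
        first = proteinize(small_chain.coords, strategy=strategy)
        again = proteinize(first.points, strategy=strategy)
        assert again.total_score == 0.0
        np.testing.assert_allclose(again.points, first.points, atol=1e-12)

    def test_unknown_strategy_rejected(self, small_chain):
        with pytest.raises(ValueError, match="unknown strategy"):
            proteinize(small_chain.coords, strategy="bogus")


class TestBruteForceOracle:
    def test_refuses_large_instances(self, valid_chain):
        with pytest.raises(ValueError, match="too large"):
            brute_force_oesp(valid_chain.coords, density=6)

    def test_two_point_enumeration_matches_basic(self):
        pts = np.array([[0, 0, 0], [4.1, 0, 0]], float)
        oracle = brute_force_oesp(pts, density=2, include_angles=False, include_steric=False)
        bas = proteinize_basic(pts, density=2)
        assert oracle.feasible == bas.feasible
        assert oracle.total_score == pytest.approx(bas.total_score, abs=1e-12)

    def test_all_infeasible_instance(self):
        pts = np.array([[0, 0, 0], [50.0, 0, 0]], float)
        assert not brute_force_oesp(pts, density=2).feasible
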