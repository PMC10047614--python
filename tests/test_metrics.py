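import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fidescape.geometry import Point
from fidescape.metrics import (pcq_perch_density, route_connectivity)
from fidescape.raster import PerchSet, VegetationRaster


def brute_force_pcq(bird, points, max_radius=100.0):
    """Independent oracle: scan every perch, classify its quadrant by angle,
    take the per-quadrant minimum distance."""
    dists = [max_radius] * 4
    for x, y in points:
        dx, dy = x - bird.x, y - bird.y
        r = math.hypot(dx, dy)
        if r == 0:
            r, dx, dy = 0.1, 1.0, 1.0  # floored, arbitrary NE
        if dx >= 0 and dy > 0:
            q = 0
        elif dx > 0 and dy <= 0:
            q = 1
        elif dx <= 0 and dy < 0:
            q = 2
        else:
            q = 3
        dists[q] = min(dists[q], max(r, 0.1))
    return 1.0 / (sum(dists) / 4.0), dists


class TestPCQDensity:
    def test_uniform_two_metre_perches(self):
        pts = np.array([(1.9, 0.6), (0.6, -1.9), (-1.9, -0.6), (-0.6, 1.9)])
        pts = 2.0 * pts / np.hypot(pts[:, 0], pts[:, 1])[:, None]  # one per quadrant, 2 m out
        m = pcq_perch_density(Point(0, 0), PerchSet(points=pts))
        assert m.perch_density == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(m.quadrant_distances, 2.0)

    def test_mean_of_1_2_3_4_gives_0_4(self):
        perches = PerchSet(points=[(0.5, 0.5 * math.sqrt(3)),    # NE at 1 m
                                   (math.sqrt(2), -math.sqrt(2)),  # SE at 2 m
                                   (-1.5, -1.5 * math.sqrt(3)),  # SW at 3 m
                                   (-4.0, 0.0)])                 # NW (west axis) at 4 m
        m = pcq_perch_density(Point(0, 0), perches)
        assert np.allclose(sorted(m.quadrant_distances), [1, 2, 3, 4])
        assert m.perch_density == pytest.approx(1 / 2.5, abs=1e-12)

    def test_matches_brute_force_on_random_layout(self, rng):
        pts = rng.uniform(-40, 40, size=(200, 2))
        bird = Point(rng.uniform(-5, 5), rng.uniform(-5, 5))
        m = pcq_perch_density(bird, PerchSet(points=pts))
        oracle_density, oracle_dists = brute_force_pcq(bird, pts)
        assert np.allclose(np.sort(m.quadrant_distances), np.sort(oracle_dists))
        assert m.perch_density == pytest.approx(oracle_density, rel=1e-12)

    def test_axis_points_go_to_clockwise_next_quadrant(self):
        # one perch due north, nothing else: N axis belongs to NE (index 0)
        m = pcq_perch_density(Point(0, 0), PerchSet(points=[(0.0, 3.0)]))
        assert m.quadrant_distances[0] == 3.0
        assert all(d == 100.0 for d in m.quadrant_distances[1:])
        # due east -> SE (index 1)
        m = pcq_perch_density(Point(0, 0), PerchSet(points=[(3.0, 0.0)]))
        assert m.quadrant_distances[1] == 3.0

    def test_empty_quadrants_substitute_max_radius_and_flag(self):
        m = pcq_perch_density(Point(0, 0), PerchSet(points=[(1.0, 1.0)]),
                              max_radius_m=50.0)
        assert m.quadrant_distances[0] == pytest.approx(math.sqrt(2))
        assert sum(d == 50.0 for d in m.quadrant_distances) == 3
        assert sum(f.startswith("empty_quadrant") for f in m.flags) == 3

    def test_perch_on_bird_is_floored_and_flagged(self):
        m = pcq_perch_density(Point(0, 0), PerchSet(points=[(0.0, 0.0)]))
        assert "perch_coincident_with_bird" in m.flags
        assert m.quadrant_distances.min() == pytest.approx(0.1)

    @given(scale=st.floats(0.1, 50.0))
    def test_density_scales_inversely_with_distance(self, scale):
        pts = np.array([(1.0, 2.0), (3.0, -1.0), (-2.0, -2.0), (-1.0, 4.0)])
        base = pcq_perch_density(Point(0, 0), PerchSet(points=pts),
                                 max_radius_m=math.inf)
        scaled = pcq_perch_density(Point(0, 0), PerchSet(points=pts * scale),
                                   max_radius_m=math.inf)
        assert scaled.perch_density == pytest.approx(
            base.perch_density / scale, rel=1e-9)

    def test_pd_invariant_under_translation_and_quarter_turns(self, rng):
        pts = rng.uniform(-30, 30, size=(50, 2))
        bird = Point(1.3, -2.7)
        base = pcq_perch_density(bird, PerchSet(points=pts)).perch_density
        shifted = pcq_perch_density(
            Point(bird.x + 11, bird.y - 4),
            PerchSet(points=pts + [11, -4])).perch_density
        assert shifted == pytest.approx(base, rel=1e-12)
        # 90-degree rotation permutes the cardinal quadrants, so the mean
        # nearest-perch distance (hence PD) is unchanged
        rot = np.column_stack([-(pts[:, 1] - bird.y), pts[:, 0] - bird.x])
        turned = pcq_perch_density(Point(0, 0),
                                   PerchSet(points=rot)).perch_density
        assert turned == pytest.approx(base, rel=1e-12)

    def test_classical_toggle_returns_areal_density(self):
        pts = np.array([(2.0, 0.1), (0.1, -2.0), (-2.0, -0.1), (-0.1, 2.0)])
        lit = pcq_perch_density(Point(0, 0), PerchSet(points=pts))
        cls = pcq_perch_density(Point(0, 0), PerchSet(points=pts), classical=True)
        assert cls.perch_density == pytest.approx(lit.perch_density ** 2, rel=1e-9)


class TestRouteConnectivity:
    @pytest.mark.parametrize("dist", [0.5, 3.0, 4.9, 5.0])
    def test_short_flights_are_fully_connected(self, all_open_raster, dist):
        m = route_connectivity(Point(30, 30), Point(30 + dist, 30), all_open_raster)
        assert m.route_connectivity == 1.0
        assert m.n_grid_points == 0
        assert "short_flight_rc_1" in m.flags

    def test_saturated_rasters(self, all_cover_raster, all_open_raster):
        a, b = Point(10, 30), Point(40, 30)
        assert route_connectivity(a, b, all_cover_raster).route_connectivity == 1.0
        assert route_connectivity(a, b, all_open_raster).route_connectivity == 0.0

    def test_halfplane_axis_route_is_half_connected(self, halfplane_raster):
        m = route_connectivity(Point(0, 30), Point(30, 30), halfplane_raster)
        # analytic vegetated area fraction is 0.5; allow one grid column
        assert abs(m.route_connectivity - 0.5) <= 1.0 / 30.0 + 1e-12
        assert m.n_grid_points == 300

    @pytest.mark.parametrize("angle_deg", [0, 17, 45, 90, 133])
    def test_halfplane_area_fraction_oracle(self, angle_deg):
        # big raster so rotated routes stay inside; cover on x >= 100
        cells = np.zeros((200, 200), dtype=bool)
        cells[:, 100:] = True
        raster = VegetationRaster(origin=Point(0, 0), cell_size=1.0, cells=cells)
        th = math.radians(angle_deg)
        start = Point(100 - 15 * math.cos(th), 100 - 15 * math.sin(th))
        end = Point(100 + 15 * math.cos(th), 100 + 15 * math.sin(th))
        m = route_connectivity(start, end, raster)
        # the rectangle straddles the boundary symmetrically: area fraction 1/2
        tol = 2.0 / math.sqrt(m.n_grid_points)
        assert abs(m.route_connectivity - 0.5) <= tol

    def test_monotone_in_added_vegetation(self, rng):
        cells = rng.uniform(size=(60, 60)) < 0.3
        raster = VegetationRaster(origin=Point(0, 0), cell_size=1.0, cells=cells)
        a, b = Point(5, 20), Point(50, 45)
        base = route_connectivity(a, b, raster).route_connectivity
        open_cells = np.argwhere(~cells)
        pick = open_cells[rng.integers(0, len(open_cells), 25)]
        grown = cells.copy()
        grown[pick[:, 0], pick[:, 1]] = True
        grown_rc = route_connectivity(
            a, b, VegetationRaster(origin=Point(0, 0), cell_size=1.0,
                                   cells=grown)).route_connectivity
        assert grown_rc >= base - 1e-12

    def test_grid_refinement_converges_to_area_fraction(self, halfplane_raster):
        a, b = Point(5, 30), Point(35, 30)
        # analytic vegetated fraction of the rectangle [5,35] x [25,35]: x >= 15
        exact = 20.0 / 30.0
        for spacing in (1.0, 0.5, 0.25):
            m = route_connectivity(a, b, halfplane_raster, grid_spacing_m=spacing)
            assert abs(m.route_connectivity - exact) <= 2.0 / math.sqrt(m.n_grid_points)

    def test_translation_invariance_on_whole_cells(self, rng):
        cells = rng.uniform(size=(80, 80)) < 0.4
        r1 = VegetationRaster(origin=Point(0, 0), cell_size=1.0, cells=cells)
        r2 = VegetationRaster(origin=Point(-13, 7), cell_size=1.0, cells=cells)
        a, b = Point(10, 20), Point(44, 61)
        shift = lambda p: Point(p.x - 13, p.y + 7)
        m1 = route_connectivity(a, b, r1)
        m2 = route_connectivity(shift(a), shift(b), r2)
        assert m1.route_connectivity == m2.route_connectivity

    def test_points_outside_raster_count_unvegetated_and_flag(self, all_cover_raster):
        m = route_connectivity(Point(2, 2), Point(-20, 2), all_cover_raster)
        assert "grid_points_outside_raster" in m.flags
        assert m.route_connectivity < 1.0

    def test_world_frame_overlay_agrees_with_route_frame(self, halfplane_raster):
        a, b = Point(3.2, 28.7), Point(41.6, 37.3)
        route = route_connectivity(a, b, halfplane_raster)
        world = route_connectivity(a, b, halfplane_raster, frame="world")
        assert world.n_grid_points > 0
        # same rectangle, same raster: the two overlays agree to discretisation
        assert world.route_connectivity == pytest.approx(
            route.route_connectivity, abs=2.0 / math.sqrt(route.n_grid_points))

    def test_rejects_non_positive_spacing(self, all_cover_raster):
        with pytest.raises(ValueError):
            route_connectivity(Point(0, 30), Point(30, 30), all_cover_raster,
                               grid_spacing_m=0.0)
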