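"""Demand aggregation, coverage matrices, greedy/exact MCLP and curves."""

import itertools

import numpy as np
import pytest

from ohca_coverage.mclp import (
    CoverageMatrix,
    aed_travel_times,
    aggregate_demand,
    build_coverage,
    coverage_curve,
    fixture_coverage_76,
    solve_exact,
    solve_greedy,
)
from ohca_coverage.synth_city import KMH, CandidateSite
from tests.helpers import make_event as _record


def _events_at(points):
    return [_record(event_id=f"P{i}", location=p) for i, p in enumerate(points)]


def _matrix(a, weights=None):
    a = np.asarray(a, dtype=bool)
    return CoverageMatrix(
        cell_ids=tuple(f"c{i}" for i in range(a.shape[0])),
        site_ids=tuple(f"s{j:02d}" for j in range(a.shape[1])),
        a=a, radius_m=1.0, cutoff_s=1.0, speed=1.0,
    )


class TestAggregateDemand:
    def test_three_events_one_cell(self):
        grid = aggregate_demand(_events_at([(10.0, 10.0), (20.0, 5.0), (499.0, 499.0)]))
        assert len(grid.active_cells) == 1
        assert grid.active_cells[0].event_count == 3
        assert grid.total_events == 3

    def test_half_open_edge_convention(self):
        # event exactly on a shared edge goes to the upper cell
        evs = _events_at([(0.0, 0.0), (500.0, 0.0)])
        grid = aggregate_demand(evs, 500.0, bbox=(0.0, 0.0, 1000.0, 500.0))
        counts = {c.cell_id: c.event_count for c in grid.cells}
        assert counts["0_0"] == 1 and counts["1_0"] == 1

    def test_centroid_is_cell_centre(self):
        grid = aggregate_demand(_events_at([(10.0, 10.0)]), 500.0,
                                bbox=(0.0, 0.0, 500.0, 500.0))
        assert grid.cells[0].centroid == (250.0, 250.0)

    def test_mean_response_per_cell(self):
        evs = [_record(event_id="A", location=(1.0, 1.0), response_time_s=600.0),
               _record(event_id="B", location=(2.0, 2.0), response_time_s=800.0)]
        grid = aggregate_demand(evs)
        assert grid.active_cells[0].mean_response_s == 700.0

    def test_every_event_counted_once(self, events):
        grid = aggregate_demand(events, 500.0)
        assert grid.total_events == len(events)

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregate_demand([])
        with pytest.raises(ValueError):
            aggregate_demand(_events_at([(0.0, 0.0)]), cell_size_m=0.0)


class TestBuildCoverage:
    def test_candidate_at_centroid_covers(self):
        grid = aggregate_demand(_events_at([(250.0, 250.0)]), 500.0,
                                bbox=(0.0, 0.0, 500.0, 500.0))
        cov = build_coverage(grid, [CandidateSite("S0", (250.0, 250.0))])
        assert cov.a[0, 0]

    @pytest.mark.parametrize("dist,covered", [(416.0, True), (417.0, False)])
    def test_radius_is_speed_times_cutoff(self, dist, covered):
        # 10 km/h * 150 s = 416.67 m
        grid = aggregate_demand(_events_at([(250.0, 250.0)]), 500.0,
                                bbox=(0.0, 0.0, 500.0, 500.0))
        cov = build_coverage(grid, [CandidateSite("S0", (250.0 + dist, 250.0))])
        assert cov.radius_m == pytest.approx(416.667, abs=0.01)
        assert bool(cov.a[0, 0]) is covered

    def test_monotone_in_cutoff(self, events, city):
        grid = aggregate_demand(events, 500.0)
        a1 = build_coverage(grid, list(city.candidates), cutoff_s=150.0).a
        a2 = build_coverage(grid, list(city.candidates), cutoff_s=300.0).a
        assert (a2 >= a1).all()

    def test_no_candidates_error(self):
        grid = aggregate_demand(_events_at([(0.0, 0.0)]))
        with pytest.raises(ValueError):
            build_coverage(grid, [])


class TestSolvers:
    def test_greedy_picks_heavier_disjoint_site(self):
        cov = _matrix([[1, 0], [0, 1]])
        sol = solve_greedy(cov, [10.0, 3.0], p=1)
        assert sol.selected == ("s00",)
        assert sol.covered_demand == 10.0

    def test_greedy_saturation(self):
        cov = _matrix([[1, 0], [0, 1], [0, 0]])
        with pytest.warns(UserWarning, match="clamping"):
            sol = solve_greedy(cov, np.ones(3), p=5)
        assert sol.n_covered == 2  # third cell uncoverable
        assert len(sol.selected) == 2  # stops early

    def test_clamp_warning(self):
        cov = _matrix([[1, 1]])
        with pytest.warns(UserWarning):
            sol = solve_greedy(cov, [1.0], p=9)
        assert sol.n_covered == 1

    def test_exact_all_cover_all(self):
        cov = _matrix(np.ones((4, 3)))
        sol = solve_exact(cov, [1.0, 2.0, 3.0, 4.0], p=1)
        assert sol.covered_demand == 10.0
        assert sol.objective_is_optimal
        assert sol.selected == ("s00",)  # lexicographic tie-break

    def test_exact_p_zero(self):
        cov = _matrix(np.ones((2, 2)))
        sol = solve_exact(cov, np.ones(2), p=0)
        assert sol.covered_demand == 0.0 and sol.selected == ()

    def test_oracle_suite(self):
        """Exact solver matches brute-force enumeration and greedy achieves
        the (1 - 1/e) submodularity bound on 50 random instances."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_sites = int(rng.integers(3, 13))
            n_cells = int(rng.integers(3, 26))
            p = int(rng.integers(1, min(5, n_sites + 1)))
            a = rng.random((n_cells, n_sites)) < 0.3
            w = rng.integers(1, 10, n_cells).astype(float)
            cov = _matrix(a)
            best = max(
                w[a[:, list(sub)].any(axis=1)].sum()
                for sub in itertools.combinations(range(n_sites), p)
            )
            assert solve_exact(cov, w, p).covered_demand == pytest.approx(best)
            assert solve_greedy(cov, w, p).covered_demand >= (1 - 1 / np.e) * best - 1e-9

    def test_weighted_equals_unweighted_for_unit_counts(self):
        rng = np.random.default_rng(3)
        a = rng.random((10, 6)) < 0.4
        cov = _matrix(a)
        s = solve_exact(cov, np.ones(10), p=2)
        assert s.covered_demand == s.n_covered


class TestCurve:
    def test_flat_beyond_saturation(self):
        cov = _matrix([[1, 0], [0, 1], [0, 0]])
        sols, sat = coverage_curve(cov, np.ones(3), [1, 2, 3])
        assert sat == 2
        assert sols[1].covered_demand == sols[2].covered_demand == 2.0

    def test_monotone_and_concave_gains(self, events, city):
        grid = aggregate_demand(events, 500.0)
        cov = build_coverage(grid, list(city.candidates))
        w = np.array([c.event_count for c in grid.active_cells], dtype=float)
        ps = list(range(20, 201, 20))
        sols, _ = coverage_curve(cov, w, ps)
        vals = [s.covered_demand for s in sols]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        gains = np.diff([0.0] + vals)
        assert all(b <= a + 1e-9 for a, b in zip(gains, gains[1:]))

    def test_requires_increasing_p(self):
        with pytest.raises(ValueError):
            coverage_curve(_matrix([[1]]), [1.0], [2, 2])


class TestAedTravelTimes:
    def test_event_at_selected_site_and_round_trip(self):
        cands = [CandidateSite("S0", (0.0, 0.0))]
        grid = aggregate_demand(_events_at([(0.0, 0.0)]))
        cov = build_coverage(grid, cands)
        sol = solve_greedy(cov, [1.0], p=1)
        evs = _events_at([(0.0, 0.0), (416.67, 0.0)])
        t = aed_travel_times(sol, evs, cands)
        assert t[0] == 0.0
        assert t[1] == pytest.approx(300.0, abs=0.01)  # 2 x 150 s
        one_way = aed_travel_times(sol, evs, cands, round_trip=False)
        np.testing.assert_allclose(t, 2 * one_way)

    def test_removing_site_never_decreases_times(self, events, city):
        grid = aggregate_demand(events, 500.0)
        cov = build_coverage(grid, list(city.candidates))
        w = np.array([c.event_count for c in grid.active_cells], dtype=float)
        full = solve_greedy(cov, w, p=20)
        part = solve_greedy(cov, w, p=10)
        t_full = aed_travel_times(full, events, list(city.candidates))
        t_part = aed_travel_times(part, events, list(city.candidates))
        assert (t_part >= t_full - 1e-9).all()


def test_engineered_fixture_covers_127_of_167():
    events, candidates, bbox = fixture_coverage_76()
    grid = aggregate_demand(events, 500.0, bbox=bbox)
    assert len(grid.active_cells) == 167
    assert len(candidates) == 624
    cov = build_coverage(grid, candidates)
    w = np.ones(cov.n_cells)
    sol = solve_greedy(cov, w, p=100)
    assert sol.n_covered == 127
    assert round(sol.coverage_fraction_cells, 2) == 0.76
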