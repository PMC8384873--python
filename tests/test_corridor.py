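"""Suitability, connectivity, bisection and the maximin bottleneck."""

import networkx as nx
import numpy as np
import pytest

from climwindows.corridor import (
    BisectionResult,
    RouteSpec,
    bottleneck_oracle,
    critical_threshold,
    path_exists,
    suitable_set,
    window_fractions,
)
from climwindows.synthetic import _smooth_field


def open_route(exit_lon=48.5):
    """Route spec for the small test grid: exit to the east, no lat exit."""
    return RouteSpec(route="unrestricted", exit_lon=exit_lon, exit_lat=1e6,
                     nile_delta_box=(0, 0, 0, 0), strait_radius_km=0.0)


def nx_connected(grid, mask, start, exit_mask):
    """Independent flood-fill oracle via networkx."""
    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(mask))
    coo = grid.adjacency.tocoo()
    for u, v in zip(coo.row, coo.col):
        if mask[u] and mask[v]:
            g.add_edge(int(u), int(v))
    if not mask[start]:
        return False
    comp = nx.node_connected_component(g, int(start))
    return any(exit_mask[n] for n in comp)


class TestSuitability:
    def test_zero_tolerance_gives_all_land(self, small_grid):
        route = open_route()
        values = np.zeros(small_grid.n_nodes)
        land = np.ones(small_grid.n_nodes, bool)
        mask = suitable_set(values, land, route, 0.0, small_grid)
        assert mask.all()

    def test_above_maximum_leaves_only_zones(self, world):
        g = world.hex_grid
        route = RouteSpec(route="southern")
        values = world.corridor_fields[0]
        land = world.elevation.values > 0
        mask = suitable_set(values, land, route, values.max() + 1, g)
        expected = (route.exemption_mask(g) | route.always_suitable_mask(g)) & ~route.barrier_mask(g)
        assert np.array_equal(mask, expected)

    def test_value_equal_to_threshold_included(self, small_grid):
        route = open_route()
        values = np.full(small_grid.n_nodes, 90.0)
        land = np.ones(small_grid.n_nodes, bool)
        assert suitable_set(values, land, route, 90.0, small_grid).all()
        assert not suitable_set(values, land, route, 90.0 + 1e-9, small_grid).any()

    def test_negative_tolerance_raises(self, small_grid):
        with pytest.raises(ValueError):
            suitable_set(np.zeros(small_grid.n_nodes), np.ones(small_grid.n_nodes, bool),
                         open_route(), -1.0, small_grid)


class TestPathExists:
    def test_matches_floodfill_oracle_on_random_masks(self, small_grid):
        route = open_route()
        start = route.start_node(small_grid)
        exit_mask = route.exit_mask(small_grid)
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(100):
            mask = rng.random(small_grid.n_nodes) < rng.uniform(0.3, 0.8)
            ours = path_exists(mask, route, small_grid)
            theirs = nx_connected(small_grid, mask, start, exit_mask)
            assert ours == theirs
            agree += 1
        assert agree == 100

    def test_unsuitable_start_is_false(self, small_grid):
        route = open_route()
        mask = np.ones(small_grid.n_nodes, bool)
        mask[route.start_node(small_grid)] = False
        assert not path_exists(mask, route, small_grid)

    def test_barrier_row_blocks(self, small_grid):
        route = open_route()
        mask = np.ones(small_grid.n_nodes, bool)
        mask[(small_grid.lons > 40) & (small_grid.lons < 42)] = False
        assert not path_exists(mask, route, small_grid)


class TestBisection:
    def _random_field(self, grid, seed):
        rng = np.random.default_rng(seed)
        return np.clip(150.0 + 120.0 * _smooth_field(rng, grid.lons, grid.lats, min_wavelength_deg=4.0), 0.0, None)

    def test_bracket_width_halves(self, small_grid):
        route = open_route()
        land = np.ones(small_grid.n_nodes, bool)
        res = critical_threshold(self._random_field(small_grid, 0), land, route, small_grid)
        widths = res.p_upper - res.p_lower
        np.testing.assert_allclose(widths, 1000.0 / 2 ** np.arange(widths.size))

    def test_tracks_oracle_within_bracket(self, small_grid):
        route = open_route()
        land = np.ones(small_grid.n_nodes, bool)
        for seed in range(10):
            f = self._random_field(small_grid, seed)
            res = critical_threshold(f, land, route, small_grid)
            oracle = bottleneck_oracle(f, land, route, small_grid)
            assert abs(res.p_crit - oracle) <= 1000.0 / 2**10

    def test_connectivity_iff_below_oracle(self, small_grid):
        route = open_route()
        land = np.ones(small_grid.n_nodes, bool)
        f = self._random_field(small_grid, 3)
        oracle = bottleneck_oracle(f, land, route, small_grid)
        assert path_exists(suitable_set(f, land, route, oracle, small_grid), route, small_grid)
        assert not path_exists(suitable_set(f, land, route, oracle + 1e-6, small_grid), route, small_grid)

    def test_connected_at_upper_bound(self, small_grid):
        route = open_route()
        land = np.ones(small_grid.n_nodes, bool)
        res = critical_threshold(np.full(small_grid.n_nodes, 2000.0), land, route, small_grid)
        assert res.p_crit >= 999.0

    def test_blocked_sentinel(self, small_grid):
        route = open_route()
        land = np.zeros(small_grid.n_nodes, bool)
        res = critical_threshold(np.full(small_grid.n_nodes, 500.0), land, route, small_grid)
        assert res.blocked and np.isnan(res.p_crit)
        assert np.isnan(bottleneck_oracle(np.full(small_grid.n_nodes, 500.0), land, route, small_grid))

    def test_monotone_in_node_values(self, small_grid):
        """Raising one node's precipitation never lowers the critical tolerance."""
        route = open_route()
        land = np.ones(small_grid.n_nodes, bool)
        f = self._random_field(small_grid, 5)
        base = critical_threshold(f, land, route, small_grid).p_crit
        rng = np.random.default_rng(11)
        for node in rng.integers(0, small_grid.n_nodes, 10):
            f2 = f.copy()
            f2[node] += 200.0
            assert critical_threshold(f2, land, route, small_grid).p_crit >= base - 1e-12


class TestPlantedWorld:
    def test_planted_bottlenecks_recovered(self, world):
        g = world.hex_grid
        for t in world.analysis_times_ka:
            land = world.elevation.values > world.sea_level.at(t)
            truth = {
                r["route"]: r["value"]
                for _, r in world.truth.query(f"kind=='corridor' and time_ka=={t}").iterrows()
            }
            for route_name in ("northern", "southern"):
                spec = RouteSpec(route=route_name)
                oracle = bottleneck_oracle(world.corridor_fields[t], land, spec, g)
                assert oracle == pytest.approx(truth[route_name], abs=1e-9)
                res = critical_threshold(world.corridor_fields[t], land, spec, g)
                assert abs(res.p_crit - truth[route_name]) <= 1.0

    def test_union_route_identity(self, world):
        """p_crit(unrestricted) equals max of the two route-specific values."""
        g = world.hex_grid
        for t in world.analysis_times_ka:
            land = world.elevation.values > world.sea_level.at(t)
            vals = {
                r: critical_threshold(world.corridor_fields[t], land, RouteSpec(route=r), g).p_crit
                for r in ("northern", "southern", "unrestricted")
            }
            assert vals["unrestricted"] == pytest.approx(max(vals["northern"], vals["southern"]))


class TestWindowFractions:
    def test_monotone_and_full_at_zero(self, world):
        g = world.hex_grid
        t = 0
        land = world.elevation.values > world.sea_level.at(t)
        decs = world.decade_multipliers[t][:20, None] * world.corridor_fields[t][None, :]
        tol = np.array([0.0, 50.0, 120.0, 200.0, 400.0])
        for route_name in ("northern", "southern"):
            frac = window_fractions(decs, land, RouteSpec(route=route_name), g, tol)
            assert frac[0] == 100.0
            assert np.all(np.diff(frac) <= 0)
            assert np.all((frac >= 0) & (frac <= 100))

    def test_fraction_matches_planted_multipliers(self, world):
        """#connected decades at p = # multipliers with scaled bottleneck ≥ p."""
        g = world.hex_grid
        t = 2
        land = world.elevation.values > world.sea_level.at(t)
        b = float(world.truth.query("kind=='corridor' and time_ka==2 and route=='northern'")["value"].iloc[0])
        mult = world.decade_multipliers[t][:20]
        decs = mult[:, None] * world.corridor_fields[t][None, :]
        p = b  # exactly the unscaled bottleneck
        frac = window_fractions(decs, land, RouteSpec(route="northern"), g, [p])
        expected = 100.0 * np.mean(mult * b >= p)
        assert frac[0] == pytest.approx(expected)
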