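"""Corridor connectivity and critical-tolerance estimation.

For a decadal climate field on the hexagonal grid, a tolerance ``p``
defines the suitability set: land nodes (elevation strictly above the
time's sea level) whose value is at least ``p``, minus route barriers,
plus zones exempt from both sea-level and climate constraints.  An exit
from Africa is feasible at tolerance ``p`` when the start node
(32.6°E, 10.2°N) connects, through chains of adjacent suitable nodes,
to any node outside Africa (λ > 65°E or φ > 37°N).

The critical tolerance — the largest ``p`` for which a connected path
still exists — is found by bisection: starting from the bracket
[0, 1000] mm y⁻¹ (or [0, 4.0] for the Köppen aridity index), ten
halvings give an estimate within 1 mm y⁻¹ (≈0.001 aridity units) of the
true value, which equals the maximin (widest-path) bottleneck: the
maximum over start→exit paths of the minimum node value along the path.
:func:`bottleneck_oracle` computes that bottleneck exactly with a
union-find sweep over nodes sorted by value and serves as the exact
reference for the bisection.

Route isolation: the northern analysis removes the nodes of the strait
exemption zone (blocking the southern crossing), the southern analysis
removes a band of nodes across the Sinai land bridge (blocking the
northern crossing).  On the southern route, nodes within ~40 km of the
Bab al-Mandab strait centre are exempt from all constraints (the strait
is assumed crossable); the Nile delta is assumed crossable at all times
on every route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from climwindows.hexgrid import HexGrid

PRECIP_UPPER_MM = 1000.0
ARIDITY_UPPER = 4.0
N_BISECTION_ITERS = 10

START_POINT = (32.6, 10.2)
EXIT_LON_DEG = 65.0
EXIT_LAT_DEG = 37.0
STRAIT_CENTRE = (43.4, 12.6)
STRAIT_EXEMPTION_RADIUS_KM = 40.0
NILE_DELTA_BOX = (30.5, 32.5, 29.5, 31.6)  # lon0, lon1, lat0, lat1
SINAI_BARRIER_BOX = (32.8, 36.0, 28.5, 33.0)

BLOCKED = float("nan")
"""Sentinel critical tolerance when no path exists even at p = 0."""


@dataclass
class RouteSpec:
    """Start/exit definition and per-route masking for one analysis.

    ``route`` is ``northern``, ``southern`` or ``unrestricted``.  Barrier
    nodes are removed from every suitability set; exemption nodes
    (southern route only, around the strait centre) and always-suitable
    nodes (Nile delta) are added regardless of sea level and climate.
    """

    route: str = "unrestricted"
    start: tuple = START_POINT
    exit_lon: float = EXIT_LON_DEG
    exit_lat: float = EXIT_LAT_DEG
    strait_centre: tuple = STRAIT_CENTRE
    strait_radius_km: float = STRAIT_EXEMPTION_RADIUS_KM
    nile_delta_box: tuple = NILE_DELTA_BOX
    sinai_barrier_box: tuple = SINAI_BARRIER_BOX

    def __post_init__(self):
        if self.route not in ("northern", "southern", "unrestricted"):
            raise ValueError(f"unknown route {self.route!r}")

    # node masks on a given grid -------------------------------------
    def start_node(self, grid: HexGrid):
        return grid.nearest_node(*self.start)

    def exit_mask(self, grid: HexGrid):
        return (grid.lons > self.exit_lon) | (grid.lats > self.exit_lat)

    def barrier_mask(self, grid: HexGrid):
        n = grid.n_nodes
        barrier = np.zeros(n, dtype=bool)
        if self.route == "southern":
            barrier |= grid.nodes_in_box(*self.sinai_barrier_box)
        elif self.route == "northern":
            barrier |= grid.nodes_within(*self.strait_centre, self.strait_radius_km)
        return barrier

    def exemption_mask(self, grid: HexGrid):
        if self.route in ("southern", "unrestricted"):
            return grid.nodes_within(*self.strait_centre, self.strait_radius_km)
        return np.zeros(grid.n_nodes, dtype=bool)

    def always_suitable_mask(self, grid: HexGrid):
        lon0, lon1, lat0, lat1 = self.nile_delta_box
        return grid.nodes_in_box(lon0, lon1, lat0, lat1)

    def validate(self, grid: HexGrid):
        start = self.start_node(grid)
        if self.exit_mask(grid)[start]:
            raise ValueError("start node lies in the exit region")
        if (self.barrier_mask(grid) & self.exemption_mask(grid)).any():
            raise ValueError("barrier and exemption sets overlap")


def _values_of(field):
    return np.asarray(getattr(field, "values", field), dtype=float)


def suitable_set(field, land, route: RouteSpec, p, grid: HexGrid):
    """Suitability mask at tolerance ``p``: land nodes with value ≥ p.

    Barrier nodes are removed; exemption and always-suitable zones are
    added irrespective of both sea level and climate.
    """
    if p < 0:
        raise ValueError("tolerance must be non-negative")
    values = _values_of(field)
    land = np.asarray(getattr(land, "values", land), dtype=bool)
    if values.shape != (grid.n_nodes,) or land.shape != (grid.n_nodes,):
        raise ValueError("field/mask shape does not match the grid")
    mask = land & (values >= p)
    mask |= route.exemption_mask(grid)
    mask |= route.always_suitable_mask(grid)
    mask &= ~route.barrier_mask(grid)
    return mask


def _reachable(grid: HexGrid, mask, start):
    """Nodes reachable from ``start`` within ``mask`` (BFS on adjacency)."""
    indptr, indices = grid.adjacency.indptr, grid.adjacency.indices
    seen = np.zeros(grid.n_nodes, dtype=bool)
    if not mask[start]:
        return seen
    seen[start] = True
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in indices[indptr[u] : indptr[u + 1]]:
                if mask[v] and not seen[v]:
                    seen[v] = True
                    nxt.append(v)
        frontier = nxt
    return seen


def path_exists(mask, route: RouteSpec, grid: HexGrid):
    """True iff the start node and the exit region share a connected
    component of the suitability subgraph."""
    mask = np.asarray(getattr(mask, "values", mask), dtype=bool)
    start = route.start_node(grid)
    if not mask[start]:
        return False
    reach = _reachable(grid, mask, start)
    return bool((reach & route.exit_mask(grid)).any())


@dataclass
class BisectionResult:
    """Bracketing sequences and the critical tolerance of one decade."""

    p_upper: np.ndarray         # p̂_k, k = 0..10
    p_lower: np.ndarray         # p̌_k
    p_crit: float               # (p̂₁₀ + p̌₁₀)/2, or NaN when blocked
    variable: str = "precip"

    @property
    def blocked(self):
        return not np.isfinite(self.p_crit)


def critical_threshold(field, land, route: RouteSpec, grid: HexGrid, variable="precip",
                       upper=None, lower=0.0, n_iters=N_BISECTION_ITERS):
    """Critical tolerance by bisection on path connectivity.

    The initial bracket is [0, 1000] mm y⁻¹ for precipitation and
    [0, 4.0] for aridity.  If no path exists even at the lower bound the
    result carries the blocked sentinel (NaN) instead of a bisection.
    """
    if upper is None:
        upper = PRECIP_UPPER_MM if variable == "precip" else ARIDITY_UPPER
    values = _values_of(field)
    if values.shape != (grid.n_nodes,):
        raise ValueError("field is missing nodes of the grid")
    if not path_exists(suitable_set(values, land, route, lower, grid), route, grid):
        k = n_iters + 1
        return BisectionResult(np.full(k, upper), np.full(k, lower), BLOCKED, variable)
    p_up = [float(upper)]
    p_lo = [float(lower)]
    for _ in range(n_iters):
        mid = 0.5 * (p_up[-1] + p_lo[-1])
        if path_exists(suitable_set(values, land, route, mid, grid), route, grid):
            p_lo.append(mid)
            p_up.append(p_up[-1])
        else:
            p_lo.append(p_lo[-1])
            p_up.append(mid)
    p_crit = 0.5 * (p_up[-1] + p_lo[-1])
    return BisectionResult(np.array(p_up), np.array(p_lo), p_crit, variable)


def bottleneck_oracle(field, land, route: RouteSpec, grid: HexGrid):
    """Exact maximin bottleneck: max over start→exit paths of the min
    node value on the path.

    Nodes are activated in order of decreasing value and merged with
    active neighbours (union-find); the value at which the start first
    connects to the exit region is the bottleneck.  Exempt and
    always-suitable nodes ignore climate and are active from the start.
    Returns the blocked sentinel (NaN) when no path exists at p = 0.
    """
    values = _values_of(field)
    land = np.asarray(getattr(land, "values", land), dtype=bool)
    n = grid.n_nodes
    eligible = (land | route.exemption_mask(grid) | route.always_suitable_mask(grid)) & ~route.barrier_mask(grid)
    eff = np.where(route.exemption_mask(grid) | route.always_suitable_mask(grid), np.inf, values)
    eff = np.where(eligible, eff, -np.inf)
    start = route.start_node(grid)
    exit_mask = route.exit_mask(grid) & eligible
    if not eligible[start] or not exit_mask.any():
        return BLOCKED

    parent = np.arange(n)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    indptr, indices = grid.adjacency.indptr, grid.adjacency.indices
    active = np.zeros(n, dtype=bool)
    # component roots that contain an exit node / the start node
    has_exit = np.zeros(n, dtype=bool)
    order = np.argsort(-eff, kind="stable")
    for u in order:
        if not np.isfinite(eff[u]) and eff[u] < 0:
            break  # remaining nodes are ineligible
        active[u] = True
        has_exit[u] = exit_mask[u]
        for v in indices[indptr[u] : indptr[u + 1]]:
            if active[v]:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[rv] = ru
                    has_exit[ru] = has_exit[ru] or has_exit[rv]
        if active[start] and has_exit[find(start)]:
            # +inf when the connection is carried entirely by exempt /
            # always-suitable nodes: a path then exists at any tolerance
            return float(eff[u])
    return BLOCKED


def window_fractions(decadal_fields, land, route: RouteSpec, grid: HexGrid, tolerances):
    """Percentage of decades with a connected path, per tolerance.

    ``decadal_fields`` is an array (n_decades, n_nodes).  Returns an
    array of percentages in [0, 100], one per tolerance, non-increasing
    in the tolerance.
    """
    fields = _values_of(decadal_fields)
    if fields.ndim != 2 or fields.shape[1] != grid.n_nodes:
        raise ValueError("decadal fields must have shape (n_decades, n_nodes)")
    tolerances = np.asarray(tolerances, dtype=float)
    out = np.empty(tolerances.size)
    for i, p in enumerate(tolerances):
        ok = sum(
            path_exists(suitable_set(f, land, route, p, grid), route, grid)
            for f in fields
        )
        out[i] = 100.0 * ok / fields.shape[0]
    return out
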