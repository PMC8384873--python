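"""Self-consistent synthetic world with planted, analytically known truth.

The generator emulates every input of the pipeline on a desk scale: a
3.75° × 2.5°-style coarse grid with per-millennium climatological
normals, a 1.25° × 0.83°-style fine grid at a small set of snapshot
times, 1000-year annual series per millennium, present-day observed
climatology on the hexagonal analysis grid, a stylised geography with a
"Red Sea" strip separating an African and an Arabian land mass (joined
by a Sinai land bridge in the north and a narrow strait in the south),
an oscillating sea-level curve, a CO₂ curve, a high-resolution strait
bathymetry with a known saddle depth and analytically known channel
width per sea level, and an ethnographic population table with a
planted precipitation floor.

Climate fields are sums of band-limited smooth random modes (seeded),
so interpolation behaves meaningfully; precipitation is clipped at 0.
On the hexagonal grid, corridor fields carry *planted* northern and
southern corridors: along each planted path the values stay above a
known bottleneck with exactly one node equal to it, while every
off-path node is clipped to a low barrier value, so the maximin
bottleneck of each route is known exactly.  No attempt is made to mimic
real HadCM3 statistics or actual palaeoclimate values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from climwindows.corridor import RouteSpec
from climwindows.fields import GridSpec, climate_field
from climwindows.geo import haversine_km
from climwindows.hexgrid import HexGrid, build_hex_grid
from climwindows.series import CO2Series, SeaLevelSeries
from climwindows.variability import YEARS_PER_MILLENNIUM


# ---------------------------------------------------------------------------
# configuration

@dataclass
class WorldConfig:
    """Grid extents, schedules and planted ground truth of the world."""

    # analysis window and grids
    window: tuple = (15.0, 70.0, 5.0, 43.0)      # lon0, lon1, lat0, lat1
    coarse_dlon: float = 3.75
    coarse_dlat: float = 2.5
    fine_dlon: float = 1.25
    fine_dlat: float = 0.8333333333333334
    hex_spacing_km: float = 55.0
    # time axes (ka before present)
    n_millennia: int = 10
    snapshot_times_ka: tuple = (0, 1, 2, 3, 4, 5, 6, 7, 9)
    # scalar curves
    co2_base_ppm: float = 230.0
    co2_amp_ppm: float = 50.0
    co2_period_ka: float = 7.0
    sea_level_amp_m: float = 120.0
    # planted corridors (per-route bottleneck range, mm y⁻¹) and barrier
    bottleneck_range_mm: tuple = (40.0, 300.0)
    barrier_value_mm: float = 10.0
    # stylised strait bathymetry: piecewise-linear V profile giving a
    # channel 4 km wide at the −120 m lowstand and 20 km wide at present
    # sea level, with the saddle at −130 m
    strait_saddle_m: float = -130.0
    strait_halfwidth_at_lowstand_km: float = 2.0
    strait_halfwidth_at_present_km: float = 10.0
    strait_lowstand_m: float = -120.0
    strait_raster_res_deg: float = 0.01
    strait_raster_window: tuple = (42.4, 44.4, 11.0, 14.2)
    # population table
    n_populations: int = 52
    precip_floor_mm: float = 90.0
    aridity_floor: float = 1.7
    n_freshwater: int = 3

    def __post_init__(self):
        if self.n_millennia <= 0:
            raise ValueError("n_millennia must be positive")
        for d in (self.coarse_dlon, self.coarse_dlat, self.fine_dlon, self.fine_dlat,
                  self.hex_spacing_km, self.strait_raster_res_deg):
            if d <= 0:
                raise ValueError("grid sizes and spacings must be positive")
        lo, hi = self.bottleneck_range_mm
        if not (0.0 <= lo <= hi <= 1000.0):
            raise ValueError("planted bottlenecks must lie in [0, 1000] mm y⁻¹")
        if max(self.snapshot_times_ka) > self.n_millennia - 1:
            raise ValueError("snapshot times exceed the analysis coverage")

    @property
    def analysis_times_ka(self):
        return tuple(range(self.n_millennia))

    # analytic strait truth ------------------------------------------
    def strait_width_km(self, sea_level_m):
        """Planted channel width (km) at a given sea level (m)."""
        s = float(sea_level_m)
        if s <= self.strait_saddle_m:
            return 0.0
        w1 = self.strait_halfwidth_at_lowstand_km
        w2 = self.strait_halfwidth_at_present_km
        slope1 = (self.strait_lowstand_m - self.strait_saddle_m) / w1      # m per km
        slope2 = -self.strait_lowstand_m / (w2 - w1)
        if s <= self.strait_lowstand_m:
            return 2.0 * (s - self.strait_saddle_m) / slope1
        if s <= 0.0:
            return 2.0 * (w1 + (s - self.strait_lowstand_m) / slope2)
        return 2.0 * (w2 + s / 20.0)  # shores rise at 20 m/km above present sea level

    def strait_profile_m(self, halfwidth_km):
        """Elevation (m) of the strait cross-section at |distance| from axis."""
        d = np.asarray(halfwidth_km, dtype=float)
        w1 = self.strait_halfwidth_at_lowstand_km
        w2 = self.strait_halfwidth_at_present_km
        slope1 = (self.strait_lowstand_m - self.strait_saddle_m) / w1
        slope2 = -self.strait_lowstand_m / (w2 - w1)
        return np.where(
            d <= w1,
            self.strait_saddle_m + slope1 * d,
            np.where(
                d <= w2,
                self.strait_lowstand_m + slope2 * (d - w1),
                20.0 * (d - w2),
            ),
        )


# ---------------------------------------------------------------------------
# smooth random fields

def _smooth_field(rng, lons, lats, n_modes=8, min_wavelength_deg=8.0):
    """Band-limited random field (≈ unit variance) on broadcastable coords."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    out = np.zeros(np.broadcast(lons, lats).shape)
    for _ in range(n_modes):
        wavelength = rng.uniform(min_wavelength_deg, 60.0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.normal(0.0, 1.0)
        k = 2.0 * np.pi / wavelength
        out = out + amp * np.cos(k * (np.cos(theta) * lons + np.sin(theta) * lats) + phase)
    return out / np.sqrt(n_modes / 2.0)


# ---------------------------------------------------------------------------
# stylised geography (hex-grid elevation)

_RED_SEA_SEGMENTS = (((33.5, 28.5), (43.4, 12.6)), ((43.4, 12.6), (45.2, 11.2)))
_STRAIT_CENTRE = (43.4, 12.6)


def _dist_to_segment_deg(lons, lats, a, b):
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    tt = np.clip(((lons - ax) * vx + (lats - ay) * vy) / (vx * vx + vy * vy), 0.0, 1.0)
    px, py = ax + tt * vx, ay + tt * vy
    return np.hypot(lons - px, lats - py)


def synthetic_elevation(lons, lats):
    """Stylised elevation (m) of the analysis window.

    Land at ~300 m with gentle relief; a Red-Sea strip (−300 m) from the
    Sinai land bridge down to a narrow strait at Bab al-Mandab, a
    Mediterranean in the northwest, and an Indian Ocean in the
    southeast.  The strip is ~130 km wide except within ~30 km of the
    strait centre, where it narrows to ~50 km so that the strait — deep
    below every synthetic sea-level lowstand — stays a water gap that
    only the exemption zone can bridge.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    elev = 300.0 + 120.0 * np.sin(np.radians(6.0 * lons)) * np.cos(np.radians(5.0 * lats))
    dc = np.hypot(lons - _STRAIT_CENTRE[0], lats - _STRAIT_CENTRE[1])
    halfwidth = 0.225 + np.clip((dc - 0.3) / 0.4, 0.0, 1.0) * (0.6 - 0.225)
    sea = np.zeros(np.broadcast(lons, lats).shape, dtype=bool)
    for a, b in _RED_SEA_SEGMENTS:
        sea |= _dist_to_segment_deg(lons, lats, a, b) <= halfwidth
    sea |= (lats > 32.2) & (lons < 34.0)         # Mediterranean
    sea |= (lons > 45.0) & (lats < 12.0)         # Indian Ocean / Gulf of Aden
    # Sinai land bridge stays land
    bridge = (lons >= 32.5) & (lons <= 35.0) & (lats >= 29.0) & (lats <= 31.6)
    sea &= ~bridge
    return np.where(sea, -300.0, elev)


# ---------------------------------------------------------------------------
# corridor planting

def _validate_chain(grid: HexGrid, path_nodes):
    path_nodes = np.asarray(path_nodes, dtype=int)
    if path_nodes.size < 2:
        raise ValueError("a planted path needs at least two nodes")
    adj = grid.adjacency
    for u, v in zip(path_nodes[:-1], path_nodes[1:]):
        if u == v or not adj[u, v]:
            raise ValueError("path_nodes are not a connected chain of adjacent nodes")
    return path_nodes


def plant_corridors(values, corridors, barrier_value, grid: HexGrid, ramp_step=3.0):
    """Plant one or more corridors with known maximin bottlenecks.

    ``corridors`` is a sequence of ``(path_nodes, bottleneck,
    min_position)`` tuples; ``min_position`` is the fraction along the
    path at which the single bottleneck node sits.  Every node not on
    any path is clipped to at most ``barrier_value``, so each planted
    bottleneck is the exact maximin value of its route.
    """
    values = np.array(np.asarray(values, dtype=float), copy=True)
    paths = []
    for path_nodes, bottleneck, min_position in corridors:
        if not (0.0 <= bottleneck <= 1000.0):
            raise ValueError("planted bottleneck outside [0, 1000] mm y⁻¹")
        if barrier_value >= bottleneck:
            raise ValueError("barrier value must be below the planted bottleneck")
        paths.append((_validate_chain(grid, path_nodes), float(bottleneck), float(min_position)))
    on_path = np.zeros(values.size, dtype=bool)
    for path_nodes, _, _ in paths:
        on_path[path_nodes] = True
    values[~on_path] = np.minimum(values[~on_path], barrier_value)
    # nodes shared between corridors (e.g. a common start segment) take
    # the larger assignment so neither route's maximin drops below its
    # planted bottleneck
    assigned = np.full(values.size, -np.inf)
    for path_nodes, bottleneck, min_position in paths:
        i_min = int(round(min_position * (path_nodes.size - 1)))
        offsets = np.abs(np.arange(path_nodes.size) - i_min)
        assigned[path_nodes] = np.maximum(assigned[path_nodes], bottleneck + ramp_step * offsets)
    values[on_path] = assigned[on_path]
    return values


def plant_corridor(values, path_nodes, bottleneck, barrier_value, grid: HexGrid,
                   min_position=0.5, ramp_step=3.0):
    """Single-corridor convenience wrapper around :func:`plant_corridors`."""
    return plant_corridors(values, [(path_nodes, bottleneck, min_position)],
                           barrier_value, grid, ramp_step=ramp_step)


def _walk(grid: HexGrid, start_node, waypoints):
    """Greedy chain of adjacent nodes visiting a list of (lon, lat) waypoints."""
    indptr, indices = grid.adjacency.indptr, grid.adjacency.indices
    path = [int(start_node)]
    for lon, lat in waypoints:
        target = grid.nearest_node(lon, lat)
        guard = 0
        while path[-1] != target:
            u = path[-1]
            nbrs = indices[indptr[u] : indptr[u + 1]]
            d = haversine_km(grid.lons[nbrs], grid.lats[nbrs], grid.lons[target], grid.lats[target])
            path.append(int(nbrs[np.argmin(d)]))
            guard += 1
            if guard > 10 * grid.n_nodes:
                raise RuntimeError("greedy walk failed to reach waypoint")
    # drop immediate backtracks introduced at waypoint turns
    out = [path[0]]
    for node in path[1:]:
        if len(out) >= 2 and out[-2] == node:
            out.pop()
        elif node != out[-1]:
            out.append(node)
    return np.asarray(out, dtype=int)


_NORTHERN_WAYPOINTS = ((32.8, 22.0), (31.5, 30.5), (34.2, 30.3), (36.2, 33.0), (37.5, 38.2))
_SOUTHERN_WAYPOINTS = ((38.0, 11.0), (41.2, 12.0), (43.1, 12.3), (43.4, 12.65),
                       (43.7, 13.1), (45.6, 14.6), (52.0, 18.0), (60.0, 22.0), (66.5, 24.0))


# ---------------------------------------------------------------------------
# population table

def make_population_table(n, floor, n_freshwater, seed, aridity_floor=1.7):
    """Ethnographic population table with a planted precipitation floor.

    Non-freshwater populations have precipitation ≥ ``floor`` with the
    minimum exactly at the floor (analogously ``aridity_floor`` for the
    Köppen index); ``n_freshwater`` populations are flagged as residing
    close to freshwater sources and placed below the floor.
    """
    if n < 1:
        raise ValueError("need at least one population")
    if floor < 0 or aridity_floor < 0:
        raise ValueError("floors must be non-negative")
    if n_freshwater >= n:
        raise ValueError("n_freshwater must be smaller than n")
    rng = np.random.default_rng(seed)
    n_kept = n - n_freshwater
    precip = floor + rng.gamma(1.5, 180.0, size=n_kept)
    precip[0] = floor
    aridity = aridity_floor + rng.gamma(1.5, 2.0, size=n_kept)
    aridity[0] = aridity_floor
    rows = {
        "id": [f"pop{i:03d}" for i in range(n)],
        "precip_mm_yr": np.concatenate([precip, rng.uniform(0.3 * floor, 0.9 * floor, n_freshwater)]) if floor > 0 else np.concatenate([precip, np.zeros(n_freshwater)]),
        "aridity": np.concatenate([aridity, rng.uniform(0.3 * aridity_floor, 0.9 * aridity_floor, n_freshwater)]) if aridity_floor > 0 else np.concatenate([aridity, np.zeros(n_freshwater)]),
        "freshwater_adjacent": np.concatenate([np.zeros(n_kept, bool), np.ones(n_freshwater, bool)]),
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the world

@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    coarse_grid: GridSpec
    fine_grid: GridSpec
    hex_grid: HexGrid
    coarse_series: dict          # var -> {t_ka: DataArray}
    fine_snapshots: dict         # var -> {t_ka: DataArray}
    annual_series: dict          # var -> {t_ka: ndarray (1000, nlat, nlon)}
    observed: dict               # var -> node DataArray at t=0
    elevation: xr.DataArray      # node elevation (m)
    strait_bathymetry: xr.DataArray
    sea_level: SeaLevelSeries
    co2: CO2Series
    populations: pd.DataFrame
    corridor_fields: dict        # t_ka -> ndarray (n_nodes,) planted precip
    decade_multipliers: dict     # t_ka -> ndarray (100,)
    corridor_paths: dict         # route -> node index array
    truth: pd.DataFrame

    @property
    def analysis_times_ka(self):
        return self.config.analysis_times_ka


def _margin_grid(window, dlon, dlat):
    lon0, lon1, lat0, lat1 = window
    return GridSpec.regular(
        lon0 - 2 * dlon, lon1 + 2 * dlon, dlon,
        lat0 - 2 * dlat, lat1 + 2 * dlat, dlat,
    )


def make_world(config=None, seed=0):
    """Generate the full synthetic world; same seed ⇒ identical world."""
    config = config or WorldConfig()
    rng = np.random.default_rng(seed)
    times = config.analysis_times_ka

    coarse = _margin_grid(config.window, config.coarse_dlon, config.coarse_dlat)
    fine = GridSpec.regular(
        config.window[0] - config.fine_dlon, config.window[1] + 2 * config.fine_dlon, config.fine_dlon,
        config.window[2] - config.fine_dlat, config.window[3] + 2 * config.fine_dlat, config.fine_dlat,
    )
    hexgrid = build_hex_grid(config.window, config.hex_spacing_km, elevation=synthetic_elevation)

    # scalar curves
    t_axis = np.asarray(times, dtype=float)
    co2 = CO2Series(
        time_ka=t_axis,
        value=config.co2_base_ppm + config.co2_amp_ppm * np.cos(2 * np.pi * t_axis / config.co2_period_ka)
        + rng.normal(0.0, 1.0, t_axis.size),
    )
    period_sea = 2.0 * max(config.n_millennia - 1, 1)
    sl = -config.sea_level_amp_m * np.sin(np.pi * t_axis / period_sea) ** 2
    sea = SeaLevelSeries(time_ka=t_axis, value=sl)

    clon, clat = coarse.meshgrid()
    flon, flat = fine.meshgrid()

    # coarse climatological normals per millennium
    coarse_series = {"precip": {}, "temp": {}}
    base_p = 250.0 + 120.0 * _smooth_field(rng, clon, clat, min_wavelength_deg=15.0)
    base_t = 25.0 - 0.3 * (clat - 5.0) + 2.0 * _smooth_field(rng, clon, clat, min_wavelength_deg=15.0)
    for t in times:
        mod = 1.0 + 0.25 * np.sin(2 * np.pi * t / config.co2_period_ka) \
            + 0.1 * _smooth_field(rng, clon, clat, n_modes=4, min_wavelength_deg=20.0)
        coarse_series["precip"][t] = climate_field(np.clip(base_p * mod, 5.0, None), coarse, "precip", t)
        coarse_series["temp"][t] = climate_field(
            base_t - 2.0 * np.sin(2 * np.pi * t / config.co2_period_ka)
            + 0.5 * _smooth_field(rng, clon, clat, n_modes=4, min_wavelength_deg=20.0),
            coarse, "temp", t,
        )

    # fine snapshots: regridded coarse pattern times / plus a fine-scale anomaly
    from climwindows.fields import regrid  # local import to avoid cycles

    fine_snapshots = {"precip": {}, "temp": {}}
    ratio = np.exp(0.2 * _smooth_field(rng, flon, flat, min_wavelength_deg=4.0))
    anom = 1.5 * _smooth_field(rng, flon, flat, min_wavelength_deg=4.0)
    for t in config.snapshot_times_ka:
        p = regrid(coarse_series["precip"][t], fine).values * ratio
        fine_snapshots["precip"][t] = climate_field(np.clip(p, 1.0, None), fine, "precip", t)
        fine_snapshots["temp"][t] = climate_field(
            regrid(coarse_series["temp"][t], fine).values + anom, fine, "temp", t
        )

    # annual series per millennium (coarse grid)
    annual_series = {"precip": {}, "temp": {}}
    years = np.arange(YEARS_PER_MILLENNIUM)
    for t in times:
        phase_p = 2 * np.pi * rng.random(coarse.shape)
        period_yr = rng.uniform(35.0, 90.0)
        osc = np.sin(2 * np.pi * years[:, None, None] / period_yr + phase_p[None])
        noise = rng.normal(0.0, 0.05, (YEARS_PER_MILLENNIUM, 1, 1))
        pa = coarse_series["precip"][t].values[None] * (1.0 + 0.2 * osc + noise)
        annual_series["precip"][t] = np.clip(pa, 0.5, None)
        annual_series["temp"][t] = (
            coarse_series["temp"][t].values[None] + 1.2 * osc + rng.normal(0.0, 0.3, (YEARS_PER_MILLENNIUM, 1, 1))
        )

    # present-day observations on the hexagonal grid
    node_ratio = np.exp(0.15 * _smooth_field(rng, hexgrid.lons, hexgrid.lats, min_wavelength_deg=3.0))
    obs_p = np.clip(regrid(fine_snapshots["precip"][0], (hexgrid.lons, hexgrid.lats)).values * node_ratio, 1.0, None)
    obs_t = regrid(fine_snapshots["temp"][0], (hexgrid.lons, hexgrid.lats)).values \
        + 0.8 * _smooth_field(rng, hexgrid.lons, hexgrid.lats, min_wavelength_deg=3.0)
    observed = {
        "precip": climate_field(obs_p, (hexgrid.lons, hexgrid.lats), "precip", 0),
        "temp": climate_field(obs_t, (hexgrid.lons, hexgrid.lats), "temp", 0),
    }

    elevation = climate_field(hexgrid.elevation, (hexgrid.lons, hexgrid.lats), "elevation")

    # strait bathymetry raster with the planted V cross-section
    sw = config.strait_raster_window
    slon = np.arange(sw[0], sw[1] + 1e-9, config.strait_raster_res_deg)
    slat = np.arange(sw[2], sw[3] + 1e-9, config.strait_raster_res_deg)
    sgrid = GridSpec(lon=slon, lat=slat)
    km_per_deg = 111.19492664455873  # π R / 180 on the reference sphere
    dist_km = np.abs(slat[:, None] - _STRAIT_CENTRE[1]) * km_per_deg * np.ones((1, slon.size))
    strait_bathy = climate_field(config.strait_profile_m(dist_km), sgrid, "elevation")

    # planted corridors on the hexagonal grid
    route = RouteSpec()
    start = route.start_node(hexgrid)
    north_path = _walk(hexgrid, start, _NORTHERN_WAYPOINTS)
    south_path = _walk(hexgrid, start, _SOUTHERN_WAYPOINTS)
    lo, hi = config.bottleneck_range_mm
    corridor_fields, decade_multipliers, truth_rows = {}, {}, []
    for t in times:
        background = np.clip(
            200.0 + 100.0 * _smooth_field(rng, hexgrid.lons, hexgrid.lats, min_wavelength_deg=6.0),
            0.0, None,
        )
        b_north = float(np.round(rng.uniform(lo, hi), 1))
        b_south = float(np.round(rng.uniform(lo, hi), 1))
        planted = plant_corridors(
            background,
            [(north_path, b_north, 0.35), (south_path, b_south, 0.75)],
            config.barrier_value_mm,
            hexgrid,
        )
        corridor_fields[t] = planted
        decade_multipliers[t] = rng.uniform(0.85, 1.15, 100)
        truth_rows.append({"kind": "corridor", "time_ka": t, "route": "northern",
                           "value": b_north, "units": "mm_yr"})
        truth_rows.append({"kind": "corridor", "time_ka": t, "route": "southern",
                           "value": b_south, "units": "mm_yr"})
    for t in times:
        truth_rows.append({"kind": "strait", "time_ka": t, "route": "southern",
                           "value": config.strait_width_km(sea.at(t)), "units": "km"})

    populations = make_population_table(
        config.n_populations, config.precip_floor_mm, config.n_freshwater,
        seed=int(rng.integers(2**31)), aridity_floor=config.aridity_floor,
    )

    return SyntheticWorld(
        config=config,
        seed=seed,
        coarse_grid=coarse,
        fine_grid=fine,
        hex_grid=hexgrid,
        coarse_series=coarse_series,
        fine_snapshots=fine_snapshots,
        annual_series=annual_series,
        observed=observed,
        elevation=elevation,
        strait_bathymetry=strait_bathy,
        sea_level=sea,
        co2=co2,
        populations=populations,
        corridor_fields=corridor_fields,
        decade_multipliers=decade_multipliers,
        corridor_paths={"northern": north_path, "southern": south_path},
        truth=pd.DataFrame(truth_rows),
    )
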