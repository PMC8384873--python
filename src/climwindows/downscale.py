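"""Delta-method downscaling, submarine infilling and land masks.

Two downscaling steps are chained.  The *dynamic* delta method corrects
the coarse simulated field at analysis time ``t`` with a high-resolution
reference snapshot at a time ``t̂`` whose global CO₂ is closest to that
at ``t`` — relaxing the stationarity assumption of the classical delta
method, which always references the present day.  Precipitation uses
the multiplicative form (ratio correction, output clipped at 0),
temperature the additive form (difference correction).

Multiplicative corrections are guarded against hyperarid reference
cells: denominators are floored at ``DENOM_FLOOR_MM`` (0.1 mm y⁻¹) and
correction ratios capped at ``RATIO_CAP`` (100), bounding noise
amplification where the reference precipitation is near zero.

Land configuration at time ``t`` is the set of nodes whose present-day
elevation exceeds the (negative in the past) sea level s(t), strictly:
E(x) > s(t).  Nodes currently below sea level but exposed at time ``t``
have no delta-method value and are filled by inverse-distance weighting
from the nearest present-day land donors.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy.spatial import cKDTree

from climwindows.fields import GridSpec, climate_field, regrid, _node_coords
from climwindows.geo import chord_to_arc_km, unit_vectors
from climwindows.series import CO2Series, SeaLevelSeries

DENOM_FLOOR_MM = 0.1
RATIO_CAP = 100.0


def select_reference_time(co2: CO2Series, t, snapshot_times):
    """Reference time t̂: the snapshot whose global CO₂ is closest to CO₂(t).

    Ties are broken toward the more recent (smaller ka) snapshot.
    """
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    if snapshot_times.size == 0:
        raise ValueError("snapshot_times is empty")
    target = co2.at(t)
    diffs = np.abs(co2.at(snapshot_times) - target)
    best = diffs == diffs.min()
    return float(snapshot_times[best].min())


def _guarded_ratio(num, den):
    ratio = np.asarray(num, dtype=float) / np.maximum(np.asarray(den, dtype=float), DENOM_FLOOR_MM)
    return np.minimum(ratio, RATIO_CAP)


def _check_same_grid(a: xr.DataArray, b: xr.DataArray):
    if a.dims != b.dims or a.shape != b.shape:
        raise ValueError("fields are on different grids")
    for dim in ("lat", "lon"):
        if dim in a.coords and not np.allclose(a[dim].values, b[dim].values):
            raise ValueError("fields are on different grids")


def _target_of(fine: xr.DataArray):
    if "node" in fine.dims:
        return (fine["node_lon"].values, fine["node_lat"].values)
    return GridSpec(lon=fine["lon"].values, lat=fine["lat"].values)


def dynamic_delta(coarse_t: xr.DataArray, coarse_that: xr.DataArray, fine_that: xr.DataArray, mode):
    """Dynamic delta method: downscale ``coarse_t`` with the snapshot pair at t̂.

    multiplicative:  ⊞(coarse_t) · fine_that / ⊞(coarse_that)
    additive:        ⊞(coarse_t) + (fine_that − ⊞(coarse_that))
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_same_grid(coarse_t, coarse_that)
    target = _target_of(fine_that)
    ct = regrid(coarse_t, target)
    cthat = regrid(coarse_that, target)
    if mode == "multiplicative":
        out = np.clip(ct.values * _guarded_ratio(fine_that.values, cthat.values), 0.0, None)
    else:
        out = ct.values + (fine_that.values - cthat.values)
    grid = target if isinstance(target, GridSpec) else target
    return climate_field(
        out, grid, fine_that.attrs.get("variable", coarse_t.attrs.get("variable", "precip")),
        coarse_t.attrs.get("time_ka"),
    )


def classical_delta(model_t: xr.DataArray, model_0: xr.DataArray, obs_0: xr.DataArray, mode):
    """Classical delta method against present-day observations.

    multiplicative:  ⊞(model_t) · obs_0 / ⊞(model_0)
    additive:        ⊞(model_t) + (obs_0 − ⊞(model_0))

    ``obs_0`` defines the target grid (typically the ~0.5° analysis grid).
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_same_grid(model_t, model_0)
    target = _target_of(obs_0)
    mt = regrid(model_t, target)
    m0 = regrid(model_0, target)
    if mode == "multiplicative":
        out = np.clip(mt.values * _guarded_ratio(obs_0.values, m0.values), 0.0, None)
    else:
        out = mt.values + (obs_0.values - m0.values)
    return climate_field(
        out, target, obs_0.attrs.get("variable", "precip"), model_t.attrs.get("time_ka")
    )


def land_mask(elev: xr.DataArray, sea: SeaLevelSeries, t):
    """Boolean mask of nodes strictly above sea level at time ``t`` (E > s)."""
    s = float(sea.at(t))
    mask = xr.DataArray(np.asarray(elev.values, dtype=float) > s, dims=elev.dims, coords=elev.coords)
    mask.attrs["time_ka"] = float(t)
    mask.attrs["sea_level_m"] = s
    return mask


def fill_submarine_cells(field: xr.DataArray, donor_mask, fill_mask, k=4, power=2.0):
    """Fill newly exposed cells by inverse-distance weighting from donors.

    ``donor_mask`` marks nodes with a valid delta-method value (land under
    the present-day reference configuration); ``fill_mask`` marks nodes to
    fill (exposed at the analysis time but currently submarine).  Each
    filled node receives the IDW mean (power ``power``, great-circle
    distances) of its ``k`` nearest donors; donors are never modified.
    """
    donor_mask = np.asarray(getattr(donor_mask, "values", donor_mask), dtype=bool)
    fill_mask = np.asarray(getattr(fill_mask, "values", fill_mask), dtype=bool)
    values = np.array(field.values, dtype=float)
    if donor_mask.shape != values.shape or fill_mask.shape != values.shape:
        raise ValueError("masks must match the field shape")
    if not donor_mask.any():
        raise ValueError("no donor nodes available for infilling")
    if "node" in field.dims:
        lons = field["node_lon"].values
        lats = field["node_lat"].values
    else:
        glon, glat = np.meshgrid(field["lon"].values, field["lat"].values)
        lons, lats = glon.ravel(), glat.ravel()
    flat = values.ravel()
    donors = donor_mask.ravel()
    targets = fill_mask.ravel() & ~donors
    if not targets.any():
        return field.copy()
    tree = cKDTree(unit_vectors(lons[donors], lats[donors]))
    kq = min(k, int(donors.sum()))
    chord, idx = tree.query(unit_vectors(lons[targets], lats[targets]), k=kq)
    chord = np.atleast_2d(chord.T).T
    idx = np.atleast_2d(idx.T).T
    dist = chord_to_arc_km(chord)
    donor_vals = flat[np.flatnonzero(donors)][idx]
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dist, 1e-12) ** power
    exact = dist[:, 0] < 1e-9  # coincident node: copy the donor
    filled = (w * donor_vals).sum(axis=1) / w.sum(axis=1)
    filled[exact] = donor_vals[exact, 0]
    flat[targets] = filled
    out = field.copy()
    out.values = flat.reshape(values.shape)
    return out
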