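"""Gridded climate fields and regridding (the ⊞ operation).

A climate field is an :class:`xarray.DataArray` with dims ``("lat",
"lon")`` on a regular grid, or ``("node",)`` on the hexagonal analysis
grid, carrying ``variable`` (``precip`` | ``temp`` | ``aridity``) and
``time_ka`` attributes.  Regridding uses a tensor-product PCHIP (shape
preserving cubic Hermite) interpolant: continuously differentiable,
exact on constant and (bi)linear data, and free of overshoots beyond the
local data range.  Grids with fewer than four nodes along an axis fall
back to (bi)linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

VALID_VARIABLES = ("precip", "temp", "aridity", "elevation")


def normalize_lon(lon):
    """Normalise longitudes from [-180, 360) to [0, 360)."""
    lon = np.asarray(lon, dtype=float)
    if np.any(lon < -180.0) or np.any(lon >= 360.0):
        raise ValueError("longitudes must lie in [-180, 360)")
    return np.where(lon < 0.0, lon + 360.0, lon)


@dataclass(frozen=True)
class GridSpec:
    """A regular longitude/latitude grid given by its node-centre axes."""

    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self):
        lon = np.asarray(self.lon, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        for name, ax in (("lon", lon), ("lat", lat)):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"{name} axis must be a non-empty 1-D array")
            if ax.size > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError(f"{name} axis must be strictly monotone")
        normalize_lon(lon)  # validates the admissible range

    @classmethod
    def regular(cls, lon0, lon1, dlon, lat0, lat1, dlat):
        """Build axes lon0, lon0+dlon, ... ≤ lon1 (same for latitude)."""
        if dlon <= 0 or dlat <= 0:
            raise ValueError("grid spacings must be positive")
        lon = np.arange(lon0, lon1 + 1e-9, dlon)
        lat = np.arange(lat0, lat1 + 1e-9, dlat)
        return cls(lon=lon, lat=lat)

    @property
    def shape(self):
        return (self.lat.size, self.lon.size)

    def meshgrid(self):
        return np.meshgrid(self.lon, self.lat)


def climate_field(values, grid, variable, time_ka=None):
    """Wrap a value array on ``grid`` into a labelled climate field."""
    if variable not in VALID_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    values = np.asarray(values, dtype=float)
    if isinstance(grid, GridSpec):
        if values.shape != grid.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
        da = xr.DataArray(
            values,
            dims=("lat", "lon"),
            coords={"lat": grid.lat, "lon": grid.lon},
        )
    else:  # node set: object with .lons/.lats, or (lon, lat) arrays
        lons, lats = _node_coords(grid)
        if values.shape != lons.shape:
            raise ValueError("values shape does not match node count")
        da = xr.DataArray(
            values,
            dims=("node",),
            coords={"node_lon": ("node", lons), "node_lat": ("node", lats)},
        )
    da.attrs["variable"] = variable
    if time_ka is not None:
        da.attrs["time_ka"] = float(time_ka)
    if variable == "precip" and np.nanmin(values) < 0:
        raise ValueError("precipitation field has negative values")
    return da


def _node_coords(target):
    if hasattr(target, "lons") and hasattr(target, "lats"):
        return np.asarray(target.lons, float), np.asarray(target.lats, float)
    lons, lats = target
    return np.asarray(lons, dtype=float), np.asarray(lats, dtype=float)


def _interpolator(field: xr.DataArray):
    lat = np.asarray(field["lat"].values, dtype=float)
    lon = np.asarray(field["lon"].values, dtype=float)
    vals = np.asarray(field.values, dtype=float)
    # flip to ascending axes as required by RegularGridInterpolator
    if lat.size > 1 and lat[0] > lat[-1]:
        lat, vals = lat[::-1], vals[::-1, :]
    if lon.size > 1 and lon[0] > lon[-1]:
        lon, vals = lon[::-1], vals[:, ::-1]
    method = "pchip" if (lat.size >= 4 and lon.size >= 4) else "linear"
    return RegularGridInterpolator(
        (lat, lon), vals, method=method, bounds_error=True
    )


def regrid(field: xr.DataArray, target):
    """Interpolate ``field`` onto ``target`` (the ⊞ operation).

    ``target`` may be a :class:`GridSpec` (regular grid result) or a node
    set — a :class:`~climwindows.hexgrid.HexGrid` or ``(lon, lat)`` array
    pair (1-D ``node`` result).  Raises :class:`ValueError` when a target
    node falls outside the source hull; such nodes must instead be filled
    with :func:`~climwindows.downscale.fill_submarine_cells` or excluded.
    """
    if "node" in field.dims:
        raise ValueError("can only regrid fields on a regular lat/lon grid")
    interp = _interpolator(field)
    variable = field.attrs.get("variable")
    time_ka = field.attrs.get("time_ka")
    if isinstance(target, GridSpec):
        glon, glat = target.meshgrid()
        pts = np.column_stack((glat.ravel(), glon.ravel()))
        try:
            out = interp(pts).reshape(target.shape)
        except ValueError as exc:
            raise ValueError(f"target grid extends outside the source hull: {exc}") from exc
        if variable == "precip":
            out = np.clip(out, 0.0, None)
        return climate_field(out, target, variable or "precip", time_ka)
    lons, lats = _node_coords(target)
    try:
        out = interp(np.column_stack((lats, lons)))
    except ValueError as exc:
        raise ValueError(f"target nodes outside the source hull: {exc}") from exc
    if variable == "precip":
        out = np.clip(out, 0.0, None)
    return climate_field(out, (lons, lats), variable or "precip", time_ka)
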