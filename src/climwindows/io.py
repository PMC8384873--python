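"""Reading and writing pipeline inputs/outputs.

Gridded fields travel as CF-style NetCDF (via xarray's scipy backend),
scalar series and tables as CSV.  A written synthetic world can be read
back by the CLI subcommands without regenerating it.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import xarray as xr

from climwindows.series import CO2Series, SeaLevelSeries

_ENGINE = "scipy"


def _to_netcdf(ds: xr.Dataset, path):
    ds.to_netcdf(path, engine=_ENGINE)


def _stack_times(fields: dict, name, time_name="time_ka"):
    """Stack a {time: DataArray} mapping along a new time dimension."""
    times = sorted(fields)
    da = xr.concat([fields[t] for t in times], dim=time_name)
    da = da.assign_coords({time_name: np.asarray(times, dtype=float)})
    return da.rename(name)


def write_world(world, out_dir):
    """Write all inputs of a synthetic world under ``out_dir``."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for var in ("precip", "temp"):
        _to_netcdf(_stack_times(world.coarse_series[var], var).to_dataset(), out / f"coarse_{var}.nc")
        _to_netcdf(
            _stack_times(world.fine_snapshots[var], var, "snapshot_ka").to_dataset(),
            out / f"fine_{var}.nc",
        )
        ann = xr.Dataset(
            {var: (("time_ka", "year", "lat", "lon"),
                   np.stack([world.annual_series[var][t] for t in world.analysis_times_ka]))},
            coords={
                "time_ka": np.asarray(world.analysis_times_ka, dtype=float),
                "year": np.arange(1, 1001),
                "lat": world.coarse_grid.lat,
                "lon": world.coarse_grid.lon,
            },
        )
        _to_netcdf(ann, out / f"annual_{var}.nc")
    obs = xr.Dataset({f"{var}": world.observed[var] for var in ("precip", "temp")})
    _to_netcdf(obs, out / "observed.nc")
    _to_netcdf(world.elevation.to_dataset(name="elevation"), out / "elevation_nodes.nc")
    _to_netcdf(world.strait_bathymetry.to_dataset(name="elevation"), out / "strait_bathymetry.nc")
    cf = xr.Dataset(
        {"precip": (("time_ka", "node"),
                    np.stack([world.corridor_fields[t] for t in world.analysis_times_ka]))},
        coords={
            "time_ka": np.asarray(world.analysis_times_ka, dtype=float),
            "node_lon": ("node", world.hex_grid.lons),
            "node_lat": ("node", world.hex_grid.lats),
        },
    )
    _to_netcdf(cf, out / "corridor_precip.nc")
    mult = pd.DataFrame(
        {str(t): world.decade_multipliers[t] for t in world.analysis_times_ka}
    )
    mult.insert(0, "decade", np.arange(1, 101))
    mult.to_csv(out / "decade_multipliers.csv", index=False)
    world.sea_level.to_frame("sea_level_m").to_csv(out / "sea_level.csv", index=False)
    world.co2.to_frame("co2_ppm").to_csv(out / "co2.csv", index=False)
    world.populations.to_csv(out / "populations.csv", index=False)
    world.truth.to_csv(out / "truth.csv", index=False)
    return out


def read_field(path, name=None):
    ds = xr.open_dataset(path, engine=_ENGINE)
    if name is None:
        name = list(ds.data_vars)[0]
    return ds[name].load()


def read_sea_level(path):
    df = pd.read_csv(path)
    return SeaLevelSeries(time_ka=df["time_ka"].to_numpy(), value=df["sea_level_m"].to_numpy())


def read_co2(path):
    df = pd.read_csv(path)
    return CO2Series(time_ka=df["time_ka"].to_numpy(), value=df["co2_ppm"].to_numpy())


def read_populations(path):
    return pd.read_csv(path)
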