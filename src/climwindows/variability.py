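"""Decadal-scale variability scalers and the Köppen aridity index.

Coarse palaeoclimate reconstructions carry 30-year climatological
normals at 1k-year steps.  Annual-resolution simulations (1000 years per
millennium) refine these to 100 decadal fields per millennium: for each
decade ``d ∈ {1..100}`` the scaler is the ratio (precipitation) or
difference (temperature) between the decade's mean and the mean of the
30-year window of decades ``d−1, d, d+1``.  With this mean convention a
constant annual series yields a scaler of exactly 1 (offset 0), so
applying scalers to a normal preserves its scale.  Edge decades (d=1,
d=100) clamp the window to the years available within the millennium;
annual series of successive millennia are not stitched because their
ends generally do not coincide.

The Köppen aridity index is A = P / (T + 33): annual precipitation (mm)
over mean annual temperature (°C) plus 33 °C; lower values are more
arid.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from climwindows.downscale import DENOM_FLOOR_MM

YEARS_PER_MILLENNIUM = 1000
DECADES_PER_MILLENNIUM = 100
KOPPEN_OFFSET_C = 33.0


def decadal_scalers(annual, mode):
    """Per-decade scalers ε (precip, ratio) or offsets δ (temp, difference).

    ``annual`` is an array (or DataArray) whose leading axis holds the
    1000 annual fields of one millennium.  Returns an array with leading
    axis of length 100 (decade index d−1).
    """
    if mode not in ("precip", "temp"):
        raise ValueError(f"unknown mode {mode!r}")
    values = np.asarray(getattr(annual, "values", annual), dtype=float)
    if values.shape[0] != YEARS_PER_MILLENNIUM:
        raise ValueError(
            f"annual series must have exactly {YEARS_PER_MILLENNIUM} years, "
            f"got {values.shape[0]}"
        )
    out = np.empty((DECADES_PER_MILLENNIUM,) + values.shape[1:], dtype=float)
    for d in range(1, DECADES_PER_MILLENNIUM + 1):
        dec = values[(d - 1) * 10 : d * 10].mean(axis=0)
        lo = max((d - 2) * 10, 0)          # 30-year window clamped to the millennium
        hi = min((d + 1) * 10, YEARS_PER_MILLENNIUM)
        win = values[lo:hi].mean(axis=0)
        if mode == "precip":
            if np.any(win < DENOM_FLOOR_MM):
                raise ValueError(
                    f"30-year precipitation mean below {DENOM_FLOOR_MM} mm y⁻¹ "
                    f"in decade {d}; scaler undefined"
                )
            out[d - 1] = dec / win
        else:
            out[d - 1] = dec - win
    return out


def apply_scalers(normal, scalers, mode):
    """Apply decadal scalers to a climatological normal.

    precip: normal · ε ; temp: normal + δ.  ``scalers`` must already be
    regridded (⊞) to the normal's grid; its leading axis is the decade.
    Returns an array of 100 decadal fields (leading axis decade).
    """
    if mode not in ("precip", "temp"):
        raise ValueError(f"unknown mode {mode!r}")
    base = np.asarray(getattr(normal, "values", normal), dtype=float)
    sc = np.asarray(getattr(scalers, "values", scalers), dtype=float)
    if sc.shape[1:] != base.shape:
        raise ValueError(
            f"scaler grid {sc.shape[1:]} does not match normal grid {base.shape}"
        )
    if mode == "precip":
        return np.clip(sc * base[np.newaxis], 0.0, None)
    return base[np.newaxis] + sc


def koppen_aridity(precip, temp):
    """Köppen aridity index A = P / (T + 33), elementwise.

    Raises when any temperature is at or below −33 °C, where the index
    is singular or negative.
    """
    p = np.asarray(getattr(precip, "values", precip), dtype=float)
    t = np.asarray(getattr(temp, "values", temp), dtype=float)
    if p.shape != t.shape:
        raise ValueError("precipitation and temperature shapes differ")
    finite = np.isfinite(t)
    if np.any(t[finite] <= -KOPPEN_OFFSET_C):
        raise ValueError("temperature at or below −33 °C: aridity index undefined")
    out = p / (t + KOPPEN_OFFSET_C)
    if isinstance(precip, xr.DataArray):
        res = precip.copy()
        res.values = out
        res.attrs["variable"] = "aridity"
        return res
    return out
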