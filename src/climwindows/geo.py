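"""Spherical geometry helpers.

All distances in the package are great-circle distances on a sphere of
radius 6371.0088 km (the IUGG mean Earth radius), computed with the
haversine formula.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Inputs broadcast against each other.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def unit_vectors(lon, lat):
    """Cartesian unit vectors (n, 3) for lon/lat in degrees.

    Used to query spherical neighbourhoods with a k-d tree on chord
    distances.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack(
        (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
    )


def arc_to_chord(arc_km):
    """Chord length (unit sphere) subtending a great-circle arc in km."""
    return 2.0 * np.sin(np.asarray(arc_km, dtype=float) / (2.0 * EARTH_RADIUS_KM))


def chord_to_arc_km(chord):
    """Great-circle arc in km subtended by a chord on the unit sphere."""
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.asarray(chord, dtype=float) / 2.0, -1.0, 1.0))
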