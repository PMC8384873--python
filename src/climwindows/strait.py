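"""Sea-crossing width of a strait from bathymetry and sea level.

At each time, cells of a high-resolution elevation/bathymetry raster
strictly above the sea level are partitioned into 8-connected land
masses.  The land masses form a complete graph whose edge weights are
the minimum great-circle distances between the closest cells of each
pair of masses.  The minimum continuous water distance between two
labelled masses (Africa and the Arabian Peninsula, identified by seed
coordinates) is the minimax path value on that graph: the path that
minimises the maximum single hop, allowing stepping-stone islands.
Distances are between cell centres, so results carry an uncertainty of
about one cell size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from climwindows.geo import chord_to_arc_km, unit_vectors
from climwindows.series import SeaLevelSeries

AFRICA_SEED = (42.8, 11.6)   # near Djibouti
ARABIA_SEED = (43.3, 13.0)   # Yemen coast


@dataclass
class LabelledLandmasses:
    labels: np.ndarray          # 0 = sea, 1..n_masses = land masses
    n_masses: int
    africa: int                 # label containing the Africa seed
    arabia: int                 # label containing the Arabia seed
    lons: np.ndarray            # cell-centre longitudes (1-D)
    lats: np.ndarray            # cell-centre latitudes (1-D)


def _raster_axes(bathy: xr.DataArray):
    return np.asarray(bathy["lon"].values, float), np.asarray(bathy["lat"].values, float)


def _seed_index(lons, lats, seed):
    lon, lat = seed
    return int(np.argmin(np.abs(lats - lat))), int(np.argmin(np.abs(lons - lon)))


def label_landmasses(bathy: xr.DataArray, sea_level, africa_seed=AFRICA_SEED, arabia_seed=ARABIA_SEED):
    """Label 8-connected land masses (elevation strictly above sea level).

    Raises when a seed coordinate is submarine at this sea level.
    """
    lons, lats = _raster_axes(bathy)
    land = np.asarray(bathy.values, dtype=float) > float(sea_level)
    labels, n = measure.label(land, connectivity=2, return_num=True)
    out = LabelledLandmasses(labels=labels, n_masses=int(n), africa=0, arabia=0, lons=lons, lats=lats)
    for name, seed in (("africa", africa_seed), ("arabia", arabia_seed)):
        i, j = _seed_index(lons, lats, seed)
        lab = int(labels[i, j])
        if lab == 0:
            raise ValueError(f"{name} seed {seed} is submarine at sea level {sea_level} m")
        setattr(out, name, lab)
    return out


def _boundary_cells(labels, lab):
    """Cells of one mass that touch sea or another mass (8-neighbourhood)."""
    mass = labels == lab
    interior = ndimage.binary_erosion(mass, structure=np.ones((3, 3)), border_value=0)
    return np.nonzero(mass & ~interior)


def landmass_distances(labelled: LabelledLandmasses):
    """Complete graph of minimum great-circle distances between masses.

    Returns a symmetric (n_masses, n_masses) array in km (0 on the
    diagonal), index ``k`` holding label ``k+1``.  Only boundary cells
    enter the pairwise search.
    """
    n = labelled.n_masses
    glon, glat = np.meshgrid(labelled.lons, labelled.lats)
    boundaries = []
    for lab in range(1, n + 1):
        ii, jj = _boundary_cells(labelled.labels, lab)
        boundaries.append(unit_vectors(glon[ii, jj], glat[ii, jj]))
    dist = np.zeros((n, n))
    for a in range(n):
        tree = cKDTree(boundaries[a])
        for b in range(a + 1, n):
            chord, _ = tree.query(boundaries[b], k=1)
            d = float(chord_to_arc_km(chord.min()))
            dist[a, b] = dist[b, a] = d
    return dist


def minimax_crossing(dist, africa, arabia):
    """Minimax path value between two labelled masses.

    ``dist`` is the complete distance matrix from
    :func:`landmass_distances`; ``africa``/``arabia`` are 1-based
    labels.  The result is the minimum, over all paths between the two
    masses, of the maximum edge weight along the path — 0 when both
    labels name the same mass.  Computed as a bottleneck search: edges
    are admitted in increasing weight until the two masses connect.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    a, b = int(africa) - 1, int(arabia) - 1
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError("africa/arabia labels missing from the graph")
    if a == b:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(dist[iu, ju], kind="stable")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k in order:
        u, v, w = iu[k], ju[k], dist[iu[k], ju[k]]
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
        if find(a) == find(b):
            return float(w)
    raise RuntimeError("complete graph failed to connect")  # unreachable


def crossing_series(bathy: xr.DataArray, sea: SeaLevelSeries, times,
                    africa_seed=AFRICA_SEED, arabia_seed=ARABIA_SEED):
    """Minimax crossing distance (km) per requested time.

    Returns an array aligned with ``times``; 0 where a land bridge
    connects the two masses.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty(times.size)
    for i, t in enumerate(times):
        s = float(sea.at(t))
        labelled = label_landmasses(bathy, s, africa_seed, arabia_seed)
        if labelled.africa == labelled.arabia:
            out[i] = 0.0
            continue
        dist = landmass_distances(labelled)
        out[i] = minimax_crossing(dist, labelled.africa, labelled.arabia)
    return out
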