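"""Great-circle geometry on the WGS84 sphere.

All coordinates are decimal degrees (longitude, latitude); all distances are
kilometres along the great circle (haversine). Grid cells are treated as
squares of ``resolution`` degrees with an equatorial degree of 111.32 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = 111.32


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays; scalars return a float.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def pairwise_haversine_km(lons, lats) -> np.ndarray:
    """Symmetric matrix of great-circle distances between n points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def min_distance_to_points_km(lons, lats, ref_lons, ref_lats) -> np.ndarray:
    """Per query point, the distance to the nearest reference point (km)."""
    ref_lons = np.asarray(ref_lons, dtype=float)
    ref_lats = np.asarray(ref_lats, dtype=float)
    if ref_lons.size == 0:
        raise ValueError("reference point set is empty")
    d = haversine_km(
        np.asarray(lons, dtype=float)[:, None],
        np.asarray(lats, dtype=float)[:, None],
        ref_lons[None, :],
        ref_lats[None, :],
    )
    return d.min(axis=1)


def cell_area_km2(lat, resolution: float):
    """Area of a ``resolution``-degree square cell centred at latitude ``lat``.

    Uses the equirectangular approximation (res * 111.32 km)^2 * cos(lat),
    adequate for coarse range-shift accounting.
    """
    return (resolution * KM_PER_DEGREE) ** 2 * np.cos(np.radians(np.asarray(lat, dtype=float)))
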