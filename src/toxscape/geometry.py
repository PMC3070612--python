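"""Distances between sites and region centroids.

Coordinates are planar by default, with one planar unit declared to be one
mile so that the distance thresholds used throughout (buffer/cutter ``T``,
distance-band weights) are directly in miles.  When coordinates are declared
``lonlat`` the engine switches to great-circle distances on a sphere of
radius 3958.8 miles.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import ConfigurationError, Region, ReleaseSite

__all__ = [
    "EARTH_RADIUS_MILES",
    "KM_PER_MILE",
    "pairwise_distances",
    "distance_matrix",
    "min_connecting_threshold",
]

EARTH_RADIUS_MILES = 3958.8
KM_PER_MILE = 1.609344

_COORD_SYSTEMS = ("planar", "lonlat")


def _check_coords(coords: str) -> None:
    if coords not in _COORD_SYSTEMS:
        raise ConfigurationError(
            f"coordinate system must be one of {_COORD_SYSTEMS}, got {coords!r}"
        )


def _haversine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distances in miles between (n,2) and (m,2) lon/lat arrays."""
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances(a: np.ndarray, b: np.ndarray, coords: str = "planar") -> np.ndarray:
    """Distance matrix between two (n, 2) coordinate arrays, in miles.

    Planar coordinates use Euclidean distance (one unit = one mile);
    ``lonlat`` uses the haversine great-circle formula.
    """
    _check_coords(coords)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    if coords == "lonlat":
        return _haversine(a, b)
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def site_coords(sites: Sequence[ReleaseSite]) -> np.ndarray:
    return np.array([[s.x, s.y] for s in sites], dtype=float).reshape(len(sites), 2)


def region_coords(regions: Sequence[Region]) -> np.ndarray:
    return np.array([[r.x, r.y] for r in regions], dtype=float).reshape(len(regions), 2)


def distance_matrix(
    sites: Sequence[ReleaseSite],
    regions: Sequence[Region],
    coords: str = "planar",
) -> np.ndarray:
    """Matrix ``d[i, j]`` of distances from site *i* to region *j*'s centroid.

    The location of a region is its centroid; distances are in miles.
    """
    return pairwise_distances(site_coords(sites), region_coords(regions), coords)


def min_connecting_threshold(regions: Sequence[Region], coords: str = "planar") -> float:
    """Smallest distance band that leaves no region without a neighbor.

    Returns the maximum, over regions, of the distance to the nearest other
    region centroid.  A distance-band weights matrix built at exactly this
    threshold (boundary included) has no isolated rows, while any smaller
    threshold isolates at least one region.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to compute a connecting threshold")
    pts = region_coords(regions)
    d = pairwise_distances(pts, pts, coords)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())
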