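"""Great-circle distances between birthplace coordinates.

Distances are computed with the spherical law of cosines on a sphere of
radius 6371.0 km, the classic "geodatasource"-style formula that many
survey pipelines use for birthplace records.  At sub-1000-km scales the
difference from an ellipsoidal geodesic is far below the resolution of
municipality-level birthplace data.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = ["GeoPoint", "EARTH_RADIUS_KM", "great_circle_km", "pairwise_km"]


class GeoPoint(NamedTuple):
    """A (latitude, longitude) pair in decimal degrees."""

    latitude: float
    longitude: float


def _validate(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def great_circle_km(a, b) -> float:
    """Spherical-law-of-cosines distance between two points, in km.

    Parameters
    ----------
    a, b : GeoPoint or (lat, lon) tuple
        Coordinates in decimal degrees.

    The arccos argument is clamped to [-1, 1] so that identical or
    antipodal points never produce a domain error.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    return float(pairwise_km(lat1, lon1, lat2, lon2))


def pairwise_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised elementwise great-circle distance (broadcasting)."""
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    p1 = np.radians(np.asarray(lat1, dtype=float))
    p2 = np.radians(np.asarray(lat2, dtype=float))
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    cosc = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_RADIUS_KM * np.arccos(np.clip(cosc, -1.0, 1.0))
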