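"""Geodesic computations on the WGS84 ellipsoid.

Distances use Vincenty's inverse method (sub-millimetre accurate away from
near-antipodal pairs, which never arise for nearest-feature queries at
landscape scale); a spherical great-circle fallback covers the rare
non-convergent antipodal case. Polygon areas use the spherical-excess line
integral evaluated in authalic latitude, which maps ellipsoidal area onto an
equal-area sphere; ring edges are densified first so the short-edge
approximation error is negligible at the sub-degree polygon sizes this
package works with.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "WGS84_A",
    "WGS84_F",
    "geodesic_distance",
    "densify_coords",
    "authalic_ring_area_km2",
]

WGS84_A = 6378137.0  # semi-major axis, m
WGS84_F = 1 / 298.257223563  # flattening
_B = WGS84_A * (1 - WGS84_F)  # semi-minor axis, m


def geodesic_distance(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Geodesic distance in metres between two lon/lat points (degrees, WGS84).

    Vincenty inverse iteration; returns 0.0 for coincident points.
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:  # equatorial geodesic
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16 * cos2_alpha * (4 + WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # near-antipodal: great-circle on the mean-radius sphere
        r = (2 * WGS84_A + _B) / 3
        d = math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(L)
        return r * math.acos(max(-1.0, min(1.0, d)))

    u2 = cos2_alpha * (WGS84_A**2 - _B**2) / _B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _B * A * (sigma - delta_sigma)


def densify_coords(coords: np.ndarray, max_step_deg: float) -> np.ndarray:
    """Insert vertices so no segment spans more than ``max_step_deg`` degrees.

    Interpolation is linear in lon/lat, matching the planar segment geometry
    GeoJSON coordinates define.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 2:
        return coords
    out = [coords[0]]
    for p, q in zip(coords[:-1], coords[1:]):
        span = max(abs(q[0] - p[0]), abs(q[1] - p[1]))
        n = max(1, int(math.ceil(span / max_step_deg)))
        for k in range(1, n + 1):
            out.append(p + (q - p) * (k / n))
    return np.asarray(out)


def _authalic_latitude(phi: np.ndarray) -> np.ndarray:
    """Map geodetic latitude (radians) to authalic latitude (radians)."""
    e2 = WGS84_F * (2 - WGS84_F)
    s = np.sin(phi)
    q = (1 - e2) * (
        s / (1 - e2 * s**2)
        - (1 / (2 * math.sqrt(e2))) * np.log((1 - math.sqrt(e2) * s) / (1 + math.sqrt(e2) * s))
    )
    qp = (1 - e2) * (
        1 / (1 - e2) + (1 / (2 * math.sqrt(e2))) * math.log((1 + math.sqrt(e2)) / (1 - math.sqrt(e2)))
    )
    return np.arcsin(np.clip(q / qp, -1.0, 1.0))


def _authalic_radius() -> float:
    e2 = WGS84_F * (2 - WGS84_F)
    qp = (1 - e2) * (
        1 / (1 - e2) + (1 / (2 * math.sqrt(e2))) * math.log((1 + math.sqrt(e2)) / (1 - math.sqrt(e2)))
    )
    return WGS84_A * math.sqrt(qp / 2)


def authalic_ring_area_km2(coords: np.ndarray, max_step_deg: float = 0.005) -> float:
    """Unsigned ellipsoidal area in km^2 of a closed lon/lat ring.

    Evaluates the spherical-excess line integral on the authalic sphere after
    densifying the ring edges.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        return 0.0
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[0]])
    coords = densify_coords(coords, max_step_deg)
    lam = np.radians(coords[:, 0])
    beta = _authalic_latitude(np.radians(coords[:, 1]))
    r = _authalic_radius()
    # trapezoid form of the spherical shoelace integral
    dlam = np.diff(lam)
    s = np.sin(beta)
    area = r * r * np.sum(dlam * (2 + s[:-1] + s[1:])) / 2
    return abs(area) / 1e6
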