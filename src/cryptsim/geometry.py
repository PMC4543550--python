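"""Rigid test-tube crypt surface: a hemisphere of radius R capped by a cylinder.

Coordinates: the base pole of the crypt is the origin, the crypt axis is +z,
the hemisphere occupies z in [0, R] (centre at (0,0,R)) and the cylinder wall
x^2 + y^2 = R^2 spans z in [R, H].  The meridian arc coordinate runs from 0 at
the base pole to (pi/2) R + (H - R) at the rim and is the natural measure of
position "up the crypt wall" (niche height is reported in units of cell
diameters along this arc).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["CryptSurface"]

_HALF_PI = math.pi / 2.0


@njit(cache=True, fastmath=False)
def _query(x, y, z, R, H):
    """Return (distance, nx, ny, nz, fx, fy, fz): unsigned wall distance,
    inward (lumen-pointing) unit normal, and nearest wall point."""
    if z >= R:
        # cylinder part; clamp foot to the wall segment
        rho = math.sqrt(x * x + y * y)
        fz = z if z <= H else H
        if rho < 1e-12:
            # on the axis: direction degenerate, pick +x
            return R, -1.0, 0.0, 0.0, R, 0.0, fz
        ux, uy = x / rho, y / rho
        dist = abs(R - rho)
        if z > H:
            dx = rho - R
            dist = math.sqrt(dx * dx + (z - H) * (z - H)) if rho > R else z - H
        return dist, -ux, -uy, 0.0, R * ux, R * uy, fz
    # hemisphere part: centre C = (0, 0, R)
    qx, qy, qz = x, y, z - R
    qn = math.sqrt(qx * qx + qy * qy + qz * qz)
    if qn < 1e-12:
        # hemisphere centre: every direction equidistant; use the pole
        return R, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0
    ux, uy, uz = qx / qn, qy / qn, qz / qn
    return abs(R - qn), -ux, -uy, -uz, R * ux, R * uy, R + R * uz


@njit(cache=True, fastmath=False)
def _arc(x, y, z, R, H):
    """Meridian arc length from the base pole to the wall projection of p."""
    if z >= R:
        zc = z if z <= H else H
        return _HALF_PI * R + (zc - R)
    qx, qy, qz = x, y, z - R
    qn = math.sqrt(qx * qx + qy * qy + qz * qz)
    if qn < 1e-12:
        return 0.0
    c = -qz / qn  # cos(angle from the downward axis)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return R * math.acos(c)


@njit(cache=True, fastmath=False)
def _downhill(x, y, z, R, H):
    """Unit tangent at the wall foot of p pointing toward decreasing arc."""
    if z >= R:
        return 0.0, 0.0, -1.0
    qx, qy, qz = x, y, z - R
    rho = math.sqrt(qx * qx + qy * qy)
    if rho < 1e-12:
        return 0.0, 0.0, 0.0  # at/above the base pole: no downhill direction
    qn = math.sqrt(rho * rho + qz * qz)
    sin_phi = rho / qn
    cos_phi = -qz / qn
    ex, ey = qx / rho, qy / rho
    return -cos_phi * ex, -cos_phi * ey, -sin_phi


@njit(cache=True, fastmath=False)
def _batch_wall_distances(pos, R, H, out):
    for i in range(pos.shape[0]):
        d, _nx, _ny, _nz, _fx, _fy, _fz = _query(pos[i, 0], pos[i, 1],
                                                 pos[i, 2], R, H)
        out[i] = d


@njit(cache=True, fastmath=False)
def _inside(x, y, z, R, H):
    if z >= R:
        return x * x + y * y <= R * R and z <= H
    qx, qy, qz = x, y, z - R
    return qx * qx + qy * qy + qz * qz <= R * R


class CryptSurface:
    """Distance / normal / arc-coordinate queries against the crypt wall."""

    def __init__(self, radius: float = 30.0, height: float = 160.0):
        if height <= radius:
            raise ValueError("crypt height must exceed its radius")
        self.R = float(radius)
        self.H = float(height)

    @property
    def total_arc(self) -> float:
        """Meridian arc length from base pole to rim."""
        return _HALF_PI * self.R + (self.H - self.R)

    def surface_query(self, p) -> tuple:
        """Return (distance, inward_normal, foot) for a 3D point ``p`` (μm)."""
        x, y, z = float(p[0]), float(p[1]), float(p[2])
        d, nx, ny, nz, fx, fy, fz = _query(x, y, z, self.R, self.H)
        return d, np.array([nx, ny, nz]), np.array([fx, fy, fz])

    def wall_height(self, p) -> float:
        """Meridian arc length (μm) from the base pole to the projection of p."""
        return _arc(float(p[0]), float(p[1]), float(p[2]), self.R, self.H)

    def downhill_tangent(self, p) -> np.ndarray:
        """Unit wall tangent at the foot of p toward decreasing arc (zero at pole)."""
        tx, ty, tz = _downhill(float(p[0]), float(p[1]), float(p[2]), self.R, self.H)
        return np.array([tx, ty, tz])

    def inside(self, p) -> bool:
        """True if p lies inside (or on) the tube."""
        return bool(_inside(float(p[0]), float(p[1]), float(p[2]), self.R, self.H))

    def wall_heights(self, pos: np.ndarray) -> np.ndarray:
        out = np.empty(len(pos))
        for i in range(len(pos)):
            out[i] = _arc(pos[i, 0], pos[i, 1], pos[i, 2], self.R, self.H)
        return out

    def __repr__(self):  # pragma: no cover
        return f"CryptSurface(radius={self.R}, height={self.H})"
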