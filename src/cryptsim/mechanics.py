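"""Subcellular-element mechanics.

Each cell is a set of point elements.  Elements of the same cell interact
through a harmonic spring potential V_intra = mu (r - r0)^2 / 2 (all pairs, no
cutoff); elements of different cells interact through a Lennard-Jones type
potential V_inter = eps ((sigma/r)^12 - (sigma/r)^6) truncated at lj_cutoff;
elements within wall_cutoff of the crypt wall feel a linear adhesion force of
magnitude eps_external * distance pulling them back onto the wall.  Motion is
overdamped: velocity = mobility * (sum of potential forces), plus an active
downhill migration velocity for Paneth cells, with the z-component of the
near-wall velocity attenuated by the linear drag coefficient b_z.

The public scalar functions are the reference implementations; the numba
kernels below evaluate the same expressions over the whole element population
using a binned Verlet neighbour list and are checked against an all-pairs
oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import ScenarioConfig
from .geometry import CryptSurface, _query, _downhill

__all__ = [
    "ForceField", "Mechanics",
    "intra_force", "inter_force", "wall_force", "drag_force", "paneth_bias",
    "brute_force_forces",
]

# cell-type codes shared across modules
STEM, PANETH, ENTEROCYTE, GOBLET, UNASSIGNED = 0, 1, 2, 3, 4


@dataclass
class ForceField:
    mu: float = 2.5
    r0: float = 1.5
    eps_lj: float = 0.05
    sigma_lj: float = 4.5
    lj_cutoff: float = 10.0
    eps_external: float = 0.001
    wall_cutoff: float = 5.0
    b_z: float = -0.3
    paneth_bias_speed: float = 8.0e-4

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "ForceField":
        return cls(
            mu=config.mu, r0=config.r0, eps_lj=config.eps_lj,
            sigma_lj=config.sigma_lj, lj_cutoff=config.lj_cutoff,
            eps_external=config.eps_external, wall_cutoff=config.wall_cutoff,
            b_z=config.b_z * config.drag_multiplier,
            paneth_bias_speed=config.paneth_bias_speed,
        )

    @property
    def lj_force_cap(self) -> float:
        """Repulsion magnitude at r = sigma/2; caps post-division overlaps."""
        s = 2.0  # sigma / r at r = sigma/2
        return abs(self.eps_lj / self.sigma_lj * (-12.0 * s**13 + 6.0 * s**7))


# ---------------------------------------------------------------------------
# reference scalar operations
# ---------------------------------------------------------------------------

def intra_force(ri, rj, field: ForceField) -> np.ndarray:
    """Spring force on element i from same-cell element j (no cutoff)."""
    d = np.asarray(ri, float) - np.asarray(rj, float)
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        raise ValueError("coincident same-cell elements: spring direction undefined")
    return -field.mu * (r - field.r0) * d / r


def inter_force(ri, rj, field: ForceField) -> np.ndarray:
    """Lennard-Jones force on element i from element j of another cell."""
    d = np.asarray(ri, float) - np.asarray(rj, float)
    r = float(np.linalg.norm(d))
    if r > field.lj_cutoff:
        return np.zeros(3)
    cap = field.lj_force_cap
    if r < 1e-12:
        return np.array([cap, 0.0, 0.0])  # arbitrary fixed direction
    s = field.sigma_lj / r
    mag = -field.eps_lj / r * (-12.0 * s**12 + 6.0 * s**6)  # +: repulsive
    mag = min(mag, cap)
    return mag * d / r


def wall_force(p, field: ForceField, surface: CryptSurface) -> np.ndarray:
    """Adhesive force pulling a near-wall element back toward the wall."""
    dist, normal, _foot = surface.surface_query(p)
    if dist > field.wall_cutoff or dist == 0.0:
        return np.zeros(3)
    return -field.eps_external * dist * normal


def drag_force(v, near_wall: bool, field: ForceField) -> np.ndarray:
    """Linear drag b_z * v_z opposing vertical motion of near-wall elements."""
    if not near_wall:
        return np.zeros(3)
    return np.array([0.0, 0.0, field.b_z * float(v[2])])


def paneth_bias(cell_type: int, p, field: ForceField, surface: CryptSurface,
                migration_on: bool = True) -> np.ndarray:
    """Active downhill migration velocity; non-zero for Paneth cells only."""
    if not migration_on or cell_type != PANETH:
        return np.zeros(3)
    return field.paneth_bias_speed * surface.downhill_tangent(p)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _pair_force_mag(r2, eps, sigma, cutoff2, cap):
    """Scalar multiplier m such that F_i = m * (r_i - r_j); LJ with cap."""
    if r2 > cutoff2:
        return 0.0
    if r2 < 1e-24:
        return 0.0  # handled by caller (coincident)
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    m = 6.0 * eps / r2 * s6 * (2.0 * s6 - 1.0)
    r = math.sqrt(r2)
    if m * r > cap:
        m = cap / r
    return m


@njit(cache=True, fastmath=True)
def _fill_pairs(pos, cell_of, bin_of, bin_start, bin_order, nbx, nby, nbz,
                cutoff2, pi, pj):
    """Single-pass pair collection; returns -1 if capacity is exceeded."""
    n = pos.shape[0]
    cap = pi.shape[0]
    count = 0
    for i in range(n):
        bi = bin_of[i]
        bx = bi // (nby * nbz)
        rem = bi % (nby * nbz)
        by = rem // nbz
        bz = rem % nbz
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ci = cell_of[i]
        for dx in range(-1, 2):
            cx = bx + dx
            if cx < 0 or cx >= nbx:
                continue
            for dy in range(-1, 2):
                cy = by + dy
                if cy < 0 or cy >= nby:
                    continue
                for dz in range(-1, 2):
                    cz = bz + dz
                    if cz < 0 or cz >= nbz:
                        continue
                    b = (cx * nby + cy) * nbz + cz
                    for k in range(bin_start[b], bin_start[b + 1]):
                        j = bin_order[k]
                        if j <= i or cell_of[j] == ci:
                            continue
                        ddx = xi - pos[j, 0]
                        ddy = yi - pos[j, 1]
                        ddz = zi - pos[j, 2]
                        if ddx * ddx + ddy * ddy + ddz * ddz <= cutoff2:
                            if count >= cap:
                                return -1
                            pi[count] = i
                            pj[count] = j
                            count += 1
    return count


def build_pair_list(pos: np.ndarray, cell_of: np.ndarray, list_cutoff: float):
    """Verlet list of inter-cell element pairs within ``list_cutoff``.

    Uses a uniform spatial hash with bin size = list_cutoff, so the 27
    surrounding bins cover all candidate partners.
    """
    n = len(pos)
    if n == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lo = pos.min(axis=0) - 1e-9
    span = pos.max(axis=0) - lo + 1e-6
    nb = np.maximum(1, (span / list_cutoff).astype(np.int64))
    nbx, nby, nbz = int(nb[0]), int(nb[1]), int(nb[2])
    ix = np.minimum((pos[:, 0] - lo[0]) / (span[0] / nbx), nbx - 1e-9).astype(np.int64)
    iy = np.minimum((pos[:, 1] - lo[1]) / (span[1] / nby), nby - 1e-9).astype(np.int64)
    iz = np.minimum((pos[:, 2] - lo[2]) / (span[2] / nbz), nbz - 1e-9).astype(np.int64)
    # bin sizes can exceed list_cutoff when span/nb > cutoff; enforce bins >= cutoff
    # by construction above (nb = floor(span/cutoff) ensures size >= cutoff)
    bin_of = (ix * nby + iy) * nbz + iz
    order = np.argsort(bin_of, kind="stable")
    counts = np.bincount(bin_of, minlength=nbx * nby * nbz)
    bin_start = np.zeros(nbx * nby * nbz + 1, np.int64)
    np.cumsum(counts, out=bin_start[1:])
    c2 = list_cutoff * list_cutoff
    cap = max(4 * n, 80 * n // 1)
    while True:
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        m = _fill_pairs(pos, cell_of, bin_of, bin_start, order, nbx, nby, nbz,
                        c2, pi, pj)
        if m >= 0:
            return pi[:m], pj[:m]
        cap *= 2


@njit(cache=True, fastmath=True)
def _accumulate_forces(pos, cell_start, pi, pj, mu, r0, eps, sigma, cutoff,
                       cap, F):
    F[:] = 0.0
    ncell = cell_start.shape[0] - 1
    # intra-cell springs: all pairs within a cell, no cutoff
    for c in range(ncell):
        s, e = cell_start[c], cell_start[c + 1]
        for a in range(s, e):
            for b in range(a + 1, e):
                dx = pos[a, 0] - pos[b, 0]
                dy = pos[a, 1] - pos[b, 1]
                dz = pos[a, 2] - pos[b, 2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r < 1e-12:
                    continue
                m = -mu * (r - r0) / r
                fx, fy, fz = m * dx, m * dy, m * dz
                F[a, 0] += fx; F[a, 1] += fy; F[a, 2] += fz
                F[b, 0] -= fx; F[b, 1] -= fy; F[b, 2] -= fz
    # inter-cell Lennard-Jones over the pair list
    cutoff2 = cutoff * cutoff
    for k in range(pi.shape[0]):
        a, b = pi[k], pj[k]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            F[a, 0] += cap
            F[b, 0] -= cap
            continue
        m = _pair_force_mag(r2, eps, sigma, cutoff2, cap)
        if m != 0.0:
            fx, fy, fz = m * dx, m * dy, m * dz
            F[a, 0] += fx; F[a, 1] += fy; F[a, 2] += fz
            F[b, 0] -= fx; F[b, 1] -= fy; F[b, 2] -= fz
    return F


@njit(cache=True, fastmath=True)
def _integrate(pos, F, type_of_el, R, H, eps_ext, wall_cut, b_z, bias_speed,
               migration_on, mobility, dt, max_disp):
    """Wall force, drag, Paneth bias, forward-Euler position update.

    Returns the maximum element displacement of the step (for Verlet-list
    bookkeeping).  Aborts with -1.0 on non-finite forces.
    """
    n = pos.shape[0]
    maxd = 0.0
    for i in range(n):
        fx, fy, fz = F[i, 0], F[i, 1], F[i, 2]
        if not (math.isfinite(fx) and math.isfinite(fy) and math.isfinite(fz)):
            return -1.0
        dist, nx, ny, nz, _fx, _fy, _fz = _query(pos[i, 0], pos[i, 1], pos[i, 2], R, H)
        near = dist <= wall_cut
        if near and dist > 0.0:
            fx -= eps_ext * dist * nx
            fy -= eps_ext * dist * ny
            fz -= eps_ext * dist * nz
        vx = mobility * fx
        vy = mobility * fy
        vz = mobility * fz
        if migration_on and type_of_el[i] == 1:  # PANETH
            tx, ty, tz = _downhill(pos[i, 0], pos[i, 1], pos[i, 2], R, H)
            vx += bias_speed * tx
            vy += bias_speed * ty
            vz += bias_speed * tz
        if near:
            fac = 1.0 + b_z
            if fac < 0.0:
                fac = 0.0
            vz *= fac
        dx, dy, dz = vx * dt, vy * dt, vz * dt
        step = math.sqrt(dx * dx + dy * dy + dz * dz)
        if step > max_disp:
            sc = max_disp / step
            dx *= sc; dy *= sc; dz *= sc
            step = max_disp
        pos[i, 0] += dx
        pos[i, 1] += dy
        pos[i, 2] += dz
        if step > maxd:
            maxd = step
    return maxd


def brute_force_forces(pos, cell_of, field: ForceField) -> np.ndarray:
    """All-pairs oracle for the potential forces (no wall/drag/bias)."""
    n = len(pos)
    F = np.zeros((n, 3))
    cap = field.lj_force_cap
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            r = float(np.linalg.norm(d))
            if cell_of[i] == cell_of[j]:
                if r < 1e-12:
                    continue
                f = -field.mu * (r - field.r0) * d / r
            else:
                if r > field.lj_cutoff:
                    continue
                if r < 1e-12:
                    f = np.array([cap, 0.0, 0.0])
                else:
                    s = field.sigma_lj / r
                    mag = min(-field.eps_lj / r * (-12.0 * s**12 + 6.0 * s**6), cap)
                    f = mag * d / r
            F[i] += f
            F[j] -= f
    return F


class Mechanics:
    """Stateful integrator: owns the Verlet pair list and advances positions."""

    def __init__(self, config: ScenarioConfig, surface: CryptSurface):
        self.field = ForceField.from_config(config)
        self.surface = surface
        self.mobility = config.mobility
        self.dt = config.dt_mech
        self.max_disp = config.max_step_displacement
        self.skin = config.verlet_skin
        self.migration_on = config.paneth_migration_on
        self._pi = np.empty(0, np.int64)
        self._pj = np.empty(0, np.int64)
        self._pos_ref: np.ndarray | None = None  # positions at last rebuild
        self._F = np.empty((0, 3))

    def invalidate(self):
        """Call after any change to element topology (growth/division/death)."""
        self._pos_ref = None

    @property
    def pair_list(self):
        return self._pi, self._pj

    def _ensure_pairs(self, pos, cell_of):
        # rebuild when any element's net displacement since the last build
        # could let an unlisted pair cross the interaction cutoff
        if self._pos_ref is not None and len(self._pos_ref) == len(pos):
            drift = pos - self._pos_ref
            if 2.0 * math.sqrt(float(np.max(np.einsum("ij,ij->i", drift,
                                                      drift)))) <= self.skin:
                return
        self._pi, self._pj = build_pair_list(
            pos, cell_of, self.field.lj_cutoff + self.skin)
        self._pos_ref = pos.copy()

    def compute_forces(self, pos, cell_of, cell_start) -> np.ndarray:
        self._ensure_pairs(pos, cell_of)
        if self._F.shape[0] != len(pos):
            self._F = np.zeros((len(pos), 3))
        f = self.field
        return _accumulate_forces(pos, cell_start, self._pi, self._pj,
                                  f.mu, f.r0, f.eps_lj, f.sigma_lj,
                                  f.lj_cutoff, f.lj_force_cap, self._F)

    def integrate_step(self, pos, cell_of, cell_start, type_of_el) -> None:
        """Advance all element positions by one overdamped Euler step."""
        F = self.compute_forces(pos, cell_of, cell_start)
        f = self.field
        maxd = _integrate(pos, F, type_of_el, self.surface.R, self.surface.H,
                          f.eps_external, f.wall_cutoff, f.b_z,
                          f.paneth_bias_speed, self.migration_on,
                          self.mobility, self.dt, self.max_disp)
        if maxd < 0.0:
            raise FloatingPointError(
                "non-finite force encountered; simulation aborted")
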