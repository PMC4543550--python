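"""Diffusible Wnt field on a regular rectangular grid.

The field obeys dc/dt = div(D grad c) + S - d*c.  Sources are Paneth-cell
elements, spread onto the grid by cloud-in-cell (trilinear) deposition; cells
read the field back by trilinear interpolation.  The basement membrane and the
crypt lumen are impermeable: rather than imposing no-flux conditions on the
curved wall, the computational box extends beyond the epithelium and the
diffusivity is set to zero outside the epithelial shell.  Inside the shell the
diffusivity decreases with the local element density, mimicking the obstacle
effect of cell bodies on extracellular transport.

A one-dimensional reduction with a point source at x = 0,

    W_t = D W_xx - delta W,   -D W_x(0) = P,

has the closed-form steady state W_ss(x) = P / sqrt(delta D) * exp(-sqrt(delta/D) x),
used both to calibrate the base production rate (the "100%" level is the flux
at which W_ss equals the Wnt threshold at 12.5 μm) and as an independent
oracle for the finite-difference solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import csr_matrix, diags as sp_diags
from scipy.sparse.linalg import cg
from numba import njit

from .config import ScenarioConfig
from .geometry import CryptSurface, _query, _inside

__all__ = [
    "Calibration1D", "steady_state_1d", "calibrate_base_production",
    "solve_steady_1d", "march_explicit_1d", "threshold_crossing",
    "ChemicalGrid", "deposit_sources", "element_density",
    "effective_diffusivity", "step_field", "sample_field",
]


# ---------------------------------------------------------------------------
# 1D closed form and calibration
# ---------------------------------------------------------------------------

@dataclass
class Calibration1D:
    """Parameters of the 1D point-source steady state used for calibration."""
    D: float = 10.0        # μm²/s
    delta: float = 1.0e-3  # 1/s
    P: float = 0.0         # boundary flux (concentration · μm / s)
    th: float = 0.85       # Wnt threshold
    x_star: float = 12.5   # μm, target threshold distance

    @property
    def decay_length(self) -> float:
        return math.sqrt(self.D / self.delta)


def steady_state_1d(x, cal: Calibration1D):
    """Closed-form steady state W_ss(x) = P/sqrt(delta D) exp(-sqrt(delta/D) x)."""
    if cal.D <= 0 or cal.delta <= 0:
        raise ValueError("D and delta must be positive")
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    k = math.sqrt(cal.delta / cal.D)
    return cal.P / math.sqrt(cal.delta * cal.D) * np.exp(-k * x)


def calibrate_base_production(D: float, delta: float, th: float,
                              x_star: float) -> float:
    """Flux P at which W_ss(x_star) = th; defines the 100% production level."""
    if min(D, delta, th, x_star) <= 0:
        raise ValueError("all calibration arguments must be positive")
    return th * math.sqrt(delta * D) * math.exp(x_star * math.sqrt(delta / D))


def solve_steady_1d(P: float, D: float, delta: float, L: float = 300.0,
                    h: float = 1.0) -> tuple:
    """Finite-difference steady state of the 1D problem on [0, L].

    Flux condition -D W_x(0) = P via a ghost node; at x = L a matched
    impedance (Robin) condition -D W_x = sqrt(delta D) W absorbs the decaying
    tail so the half-line solution is reproduced on a finite domain.
    Returns (x_nodes, W).
    """
    n = int(round(L / h)) + 1
    k = math.sqrt(delta / D)
    main = np.full(n, -2.0 * D / h**2 - delta)
    upper = np.full(n, D / h**2)
    lower = np.full(n, D / h**2)
    rhs = np.zeros(n)
    # node 0: ghost c[-1] = c[1] + 2hP/D
    upper[1] = 2.0 * D / h**2
    rhs[0] = -2.0 * P / h
    # node n-1: ghost c[n] = c[n-2] - 2 h k c[n-1]
    lower[-2] = 2.0 * D / h**2
    main[-1] = -2.0 * D / h**2 - delta - 2.0 * D * k / h
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1, :] = main
    ab[2, :-1] = lower[:-1]
    W = solve_banded((1, 1), ab, rhs)
    return np.arange(n) * h, W


def march_explicit_1d(P: float, D: float, delta: float, L: float = 300.0,
                      h: float = 1.0, t_end: float = 20000.0,
                      dt: float | None = None) -> tuple:
    """Forward-Euler/central-difference marching of the same 1D problem.

    Serves as the explicit-scheme reference for the steady state; stability
    requires D dt / h^2 <= 1/2 (the dt default uses half that bound).
    """
    if dt is None:
        dt = 0.25 * h * h / D
    if D * dt / h**2 > 0.5:
        raise ValueError("explicit 1D step violates the stability bound")
    n = int(round(L / h)) + 1
    k = math.sqrt(delta / D)
    c = np.zeros(n)
    steps = int(math.ceil(t_end / dt))
    lam = D * dt / h**2
    for _ in range(steps):
        left = np.empty(n)
        right = np.empty(n)
        left[1:] = c[:-1]
        left[0] = c[1] + 2.0 * h * P / D       # flux ghost
        right[:-1] = c[1:]
        right[-1] = c[-2] - 2.0 * h * k * c[-1]  # matched-impedance ghost
        c = c + lam * (left - 2.0 * c + right) - delta * dt * c
    return np.arange(n) * h, c


def threshold_crossing(x: np.ndarray, W: np.ndarray, th: float) -> float:
    """Distance at which the monotonically decaying profile W crosses th."""
    below = np.nonzero(W < th)[0]
    if len(below) == 0 or below[0] == 0:
        raise ValueError("profile does not cross the threshold inside the domain")
    i = below[0]
    x0, x1, w0, w1 = x[i - 1], x[i], W[i - 1], W[i]
    return float(x0 + (w0 - th) / (w0 - w1) * (x1 - x0))


# ---------------------------------------------------------------------------
# 3D masked grid
# ---------------------------------------------------------------------------

class ChemicalGrid:
    """Regular concentration lattice with a per-node diffusivity mask."""

    def __init__(self, origin, spacing: float, shape):
        self.origin = np.asarray(origin, float)
        self.spacing = float(spacing)
        self.shape = tuple(int(s) for s in shape)
        self.c = np.zeros(self.shape)
        self.D_node = np.zeros(self.shape)
        self.mask = np.zeros(self.shape, dtype=bool)  # True = interior
        self._qs_cache = None

    @classmethod
    def from_crypt(cls, surface: CryptSurface, config: ScenarioConfig) -> "ChemicalGrid":
        h = config.grid_spacing
        m = config.grid_margin
        R, H = surface.R, surface.H
        lo = np.array([-(R + m), -(R + m), -m])
        hi = np.array([R + m, R + m, H + m])
        shape = tuple(int(math.floor((hi[i] - lo[i]) / h)) + 1 for i in range(3))
        grid = cls(lo, h, shape)
        shell = config.cell_diameter  # epithelial shell thickness
        nx, ny, nz = shape
        xs = lo[0] + h * np.arange(nx)
        ys = lo[1] + h * np.arange(ny)
        zs = lo[2] + h * np.arange(nz)
        _fill_mask(grid.mask, xs, ys, zs, R, H, shell)
        grid.D_node[grid.mask] = config.D_c * config.diffusivity_multiplier
        return grid

    def node_positions_flat(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        return self.origin + self.spacing * np.stack(
            [ii.ravel(), jj.ravel(), kk.ravel()], axis=1)

    # -- quasi-steady solve --------------------------------------------------
    def _qs_structure(self):
        """Precomputed interior indexing and neighbour maps for the solver."""
        if self._qs_cache is not None:
            return self._qs_cache
        idx = -np.ones(self.shape, np.int64)
        interior = np.argwhere(self.mask)
        idx[tuple(interior.T)] = np.arange(len(interior))
        nbrs = []
        for axis in range(3):
            for sgn in (-1, 1):
                shifted = np.roll(idx, -sgn, axis=axis)
                # rolled wrap-around is invalid: mark edge slabs as exterior
                sl = [slice(None)] * 3
                sl[axis] = -1 if sgn > 0 else 0
                shifted = shifted.copy()
                shifted[tuple(sl)] = -1
                nbrs.append(shifted[tuple(interior.T)])
        self._qs_cache = (interior, idx, nbrs)
        return self._qs_cache

    def solve_quasi_steady(self, sources: np.ndarray, d_c: float,
                           rtol: float = 1e-8) -> None:
        """Solve div(D grad c) - d_c c + S = 0 on the interior; updates c.

        Faces toward exterior nodes carry no flux (impermeable membrane /
        lumen).  The system is symmetric positive definite and is solved by
        Jacobi-preconditioned conjugate gradients warm-started from the
        previous field.
        """
        interior, idx, nbrs = self._qs_structure()
        n = len(interior)
        if n == 0:
            return
        h2 = self.spacing**2
        Di = self.D_node[tuple(interior.T)]
        diag = np.full(n, d_c)
        off_rows, off_cols, off_vals = [], [], []
        for nb in nbrs:
            valid = nb >= 0
            Dj = np.zeros(n)
            Dj[valid] = Di[nb[valid]]
            w = 0.5 * (Di + Dj) / h2  # arithmetic-mean face diffusivity
            w[~valid] = 0.0           # no flux toward exterior/edge
            diag += w
            off_rows.append(np.nonzero(valid)[0])
            off_cols.append(nb[valid])
            off_vals.append(-w[valid])
        rows = np.concatenate([np.arange(n)] + off_rows)
        cols = np.concatenate([np.arange(n)] + off_cols)
        vals = np.concatenate([diag] + off_vals)
        A = csr_matrix((vals, (rows, cols)), shape=(n, n))
        b = sources[tuple(interior.T)]
        x0 = self.c[tuple(interior.T)]
        M = sp_diags(1.0 / A.diagonal())
        x, info = cg(A, b, x0=x0, rtol=rtol, maxiter=5000, M=M)
        if info != 0:  # pragma: no cover - CG on an SPD system converges
            from scipy.sparse.linalg import spsolve
            x = spsolve(A.tocsc(), b)
        x = np.maximum(x, 0.0)
        self.c[:] = 0.0
        self.c[tuple(interior.T)] = x


@njit(cache=True)
def _fill_mask(mask, xs, ys, zs, R, H, shell):
    for i in range(xs.shape[0]):
        for j in range(ys.shape[0]):
            for k in range(zs.shape[0]):
                x, y, z = xs[i], ys[j], zs[k]
                if _inside(x, y, z, R, H):
                    dist, _nx, _ny, _nz, _a, _b, _c = _query(x, y, z, R, H)
                    if dist <= shell:
                        mask[i, j, k] = True


# ---------------------------------------------------------------------------
# particle <-> grid transfer
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cic_deposit(points, weights, origin, h, field):
    nx, ny, nz = field.shape
    for p in range(points.shape[0]):
        gx = (points[p, 0] - origin[0]) / h
        gy = (points[p, 1] - origin[1]) / h
        gz = (points[p, 2] - origin[2]) / h
        i0 = int(math.floor(gx)); fx = gx - i0
        j0 = int(math.floor(gy)); fy = gy - j0
        k0 = int(math.floor(gz)); fz = gz - k0
        if i0 < 0 or j0 < 0 or k0 < 0 or i0 + 1 >= nx or j0 + 1 >= ny or k0 + 1 >= nz:
            return p + 1  # signal: point p outside the box
        w = weights[p]
        field[i0, j0, k0] += w * (1 - fx) * (1 - fy) * (1 - fz)
        field[i0 + 1, j0, k0] += w * fx * (1 - fy) * (1 - fz)
        field[i0, j0 + 1, k0] += w * (1 - fx) * fy * (1 - fz)
        field[i0, j0, k0 + 1] += w * (1 - fx) * (1 - fy) * fz
        field[i0 + 1, j0 + 1, k0] += w * fx * fy * (1 - fz)
        field[i0 + 1, j0, k0 + 1] += w * fx * (1 - fy) * fz
        field[i0, j0 + 1, k0 + 1] += w * (1 - fx) * fy * fz
        field[i0 + 1, j0 + 1, k0 + 1] += w * fx * fy * fz
    return 0


@njit(cache=True)
def _trilinear_sample(points, origin, h, field, out):
    nx, ny, nz = field.shape
    for p in range(points.shape[0]):
        gx = (points[p, 0] - origin[0]) / h
        gy = (points[p, 1] - origin[1]) / h
        gz = (points[p, 2] - origin[2]) / h
        i0 = int(math.floor(gx)); fx = gx - i0
        j0 = int(math.floor(gy)); fy = gy - j0
        k0 = int(math.floor(gz)); fz = gz - k0
        if i0 < 0 or j0 < 0 or k0 < 0 or i0 + 1 >= nx or j0 + 1 >= ny or k0 + 1 >= nz:
            return p + 1
        out[p] = (
            field[i0, j0, k0] * (1 - fx) * (1 - fy) * (1 - fz)
            + field[i0 + 1, j0, k0] * fx * (1 - fy) * (1 - fz)
            + field[i0, j0 + 1, k0] * (1 - fx) * fy * (1 - fz)
            + field[i0, j0, k0 + 1] * (1 - fx) * (1 - fy) * fz
            + field[i0 + 1, j0 + 1, k0] * fx * fy * (1 - fz)
            + field[i0 + 1, j0, k0 + 1] * fx * (1 - fy) * fz
            + field[i0, j0 + 1, k0 + 1] * (1 - fx) * fy * fz
            + field[i0 + 1, j0 + 1, k0 + 1] * fx * fy * fz
        )
    return 0


def deposit_sources(paneth_elements: np.ndarray, rate_per_element: float,
                    grid: ChemicalGrid) -> np.ndarray:
    """Cloud-in-cell spreading of per-element emission onto the grid.

    The returned source field sums exactly to n_elements * rate_per_element.
    """
    pts = np.atleast_2d(np.asarray(paneth_elements, float))
    field = np.zeros(grid.shape)
    if len(pts) == 0 or pts.size == 0:
        return field
    w = np.full(len(pts), rate_per_element)
    bad = _cic_deposit(pts, w, grid.origin, grid.spacing, field)
    if bad:
        raise ValueError(f"element {bad - 1} lies outside the chemical grid box")
    return field


def element_density(element_positions: np.ndarray, grid: ChemicalGrid) -> np.ndarray:
    """Per-node element density (elements per voxel) by cloud-in-cell counting."""
    pts = np.atleast_2d(np.asarray(element_positions, float))
    field = np.zeros(grid.shape)
    if len(pts) == 0 or pts.size == 0:
        return field
    w = np.ones(len(pts))
    bad = _cic_deposit(pts, w, grid.origin, grid.spacing, field)
    if bad:
        raise ValueError(f"element {bad - 1} lies outside the chemical grid box")
    return field


def effective_diffusivity(density: np.ndarray, D_c: float, rho_sat: float,
                          floor_frac: float = 0.0,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Linear crowding ramp D = D_c max(floor, 1 - rho/rho_sat), 0 outside mask."""
    if np.any(np.asarray(density) < 0):
        raise ValueError("element density must be non-negative")
    D = D_c * np.clip(1.0 - density / rho_sat, floor_frac, 1.0)
    if mask is not None:
        D = np.where(mask, D, 0.0)
    return D


# ---------------------------------------------------------------------------
# explicit time stepping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ftcs_step(c, D, src, mask, h2, dt, d_c):
    nx, ny, nz = c.shape
    out = np.empty_like(c)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    out[i, j, k] = 0.0
                    continue
                ci = c[i, j, k]
                Di = D[i, j, k]
                lap = 0.0
                # flux form over interior faces only: the membrane and lumen
                # are impermeable, so faces toward exterior nodes carry none
                if i > 0 and mask[i - 1, j, k]:
                    lap += 0.5 * (Di + D[i - 1, j, k]) * (c[i - 1, j, k] - ci)
                if i < nx - 1 and mask[i + 1, j, k]:
                    lap += 0.5 * (Di + D[i + 1, j, k]) * (c[i + 1, j, k] - ci)
                if j > 0 and mask[i, j - 1, k]:
                    lap += 0.5 * (Di + D[i, j - 1, k]) * (c[i, j - 1, k] - ci)
                if j < ny - 1 and mask[i, j + 1, k]:
                    lap += 0.5 * (Di + D[i, j + 1, k]) * (c[i, j + 1, k] - ci)
                if k > 0 and mask[i, j, k - 1]:
                    lap += 0.5 * (Di + D[i, j, k - 1]) * (c[i, j, k - 1] - ci)
                if k < nz - 1 and mask[i, j, k + 1]:
                    lap += 0.5 * (Di + D[i, j, k + 1]) * (c[i, j, k + 1] - ci)
                v = ci + dt * (lap / h2 + src[i, j, k] - d_c * ci)
                out[i, j, k] = v if v > 0.0 else 0.0
    c[:] = out


def step_field(grid: ChemicalGrid, sources: np.ndarray, dt: float,
               substeps: int, d_c: float) -> None:
    """Advance the field by `substeps` forward-Euler steps of length dt."""
    ratio = float(np.max(grid.D_node)) * dt / grid.spacing**2
    if ratio > 1.0 / 6.0 + 1e-12:
        raise ValueError(
            f"explicit step unstable: max(D) dt / h^2 = {ratio:.4g} > 1/6")
    for _ in range(substeps):
        _ftcs_step(grid.c, grid.D_node, sources, grid.mask, grid.spacing**2,
                   dt, d_c)


def sample_field(grid: ChemicalGrid, p) -> float | np.ndarray:
    """Trilinear interpolation of the concentration at point(s) p."""
    pts = np.atleast_2d(np.asarray(p, float))
    out = np.empty(len(pts))
    bad = _trilinear_sample(pts, grid.origin, grid.spacing, grid.c, out)
    if bad:
        raise ValueError(f"point {bad - 1} lies outside the chemical grid box")
    return float(out[0]) if np.asarray(p).ndim == 1 else out
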