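"""Cell state and fate regulation.

Four cell types are modelled: stem, Paneth, enterocyte and Goblet.  Fate is a
threshold function of two inputs (the joint Wnt/Notch fate table): the total
Wnt exposure I_wnt (exogenous mesenchymal gradient plus the diffusible
Paneth-derived field) and the Notch activation I_notch contributed by
ligand-presenting contacts (Paneth and Goblet neighbours).  A BMP gradient
opposing the Wnt gradient gates proliferation: stem cells exposed to BMP above
threshold do not divide.  Paneth fate is absorbing; Paneth cells age and are
removed at the end of a stochastic lifetime.  Goblet and enterocyte identities
interconvert freely with Notch; re-entry of differentiated cells into the stem
pool is disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .geometry import CryptSurface, _batch_wall_distances
from .mechanics import STEM, PANETH, ENTEROCYTE, GOBLET, UNASSIGNED, build_pair_list
from . import chemfield

__all__ = [
    "STEM", "PANETH", "ENTEROCYTE", "GOBLET", "UNASSIGNED", "TYPE_NAMES",
    "CellCollection", "GradientSpec",
    "contact_pairs", "contact_neighbors", "notch_activity", "compute_notch",
    "exogenous_signal", "total_wnt", "compute_total_wnt",
    "fate_table", "update_fate", "update_fates",
    "draw_cycle_length", "draw_paneth_lifetime",
    "divide_cell", "lifecycle_update",
]

TYPE_NAMES = {STEM: "stem", PANETH: "paneth", ENTEROCYTE: "enterocyte",
              GOBLET: "goblet", UNASSIGNED: "unassigned"}


# ---------------------------------------------------------------------------
# the cell population container
# ---------------------------------------------------------------------------

class CellCollection:
    """Struct-of-arrays container for cells and their elements.

    Element positions are stored in one (n, 3) array grouped by cell, so the
    mechanics kernels can operate on contiguous per-cell blocks.
    """

    def __init__(self):
        self.pos = np.empty((0, 3))
        self.counts = np.empty(0, np.int64)         # elements per cell
        self.cell_id = np.empty(0, np.int64)
        self.type = np.empty(0, np.int8)
        self.cycle_length_h = np.empty(0)
        self.timer_h = np.empty(0)
        self.growth_progress_h = np.empty(0)
        self.paneth_life_wk = np.empty(0)
        self.age_paneth_wk = np.empty(0)
        self.out_of_contact = np.empty(0, np.int8)
        self.I_wnt = np.empty(0)
        self.I_notch = np.empty(0)
        self.I_bmp = np.empty(0)
        self._next_id = 0

    # -- basic queries -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def n_elements(self) -> int:
        return len(self.pos)

    @property
    def cell_start(self) -> np.ndarray:
        cs = np.zeros(self.n_cells + 1, np.int64)
        np.cumsum(self.counts, out=cs[1:])
        return cs

    @property
    def el_cell(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_cells), self.counts)

    @property
    def type_of_el(self) -> np.ndarray:
        return np.repeat(self.type, self.counts)

    def elements_of(self, i: int) -> np.ndarray:
        cs = self.cell_start
        return self.pos[cs[i]:cs[i + 1]]

    def centroids(self) -> np.ndarray:
        if self.n_cells == 0:
            return np.empty((0, 3))
        cs = self.cell_start
        sums = np.add.reduceat(self.pos, cs[:-1], axis=0)
        return sums / self.counts[:, None]

    # -- structural edits ----------------------------------------------------
    def add_cell(self, positions: np.ndarray, cell_type: int,
                 cycle_length_h: float, paneth_life_wk: float = 0.0) -> int:
        positions = np.atleast_2d(np.asarray(positions, float))
        self.pos = np.vstack([self.pos, positions])
        self.counts = np.append(self.counts, len(positions))
        self.cell_id = np.append(self.cell_id, self._next_id)
        self._next_id += 1
        self.type = np.append(self.type, np.int8(cell_type))
        self.cycle_length_h = np.append(self.cycle_length_h, cycle_length_h)
        self.timer_h = np.append(self.timer_h, 0.0)
        self.growth_progress_h = np.append(self.growth_progress_h, 0.0)
        self.paneth_life_wk = np.append(self.paneth_life_wk, paneth_life_wk)
        self.age_paneth_wk = np.append(self.age_paneth_wk, 0.0)
        self.out_of_contact = np.append(self.out_of_contact, np.int8(0))
        self.I_wnt = np.append(self.I_wnt, 0.0)
        self.I_notch = np.append(self.I_notch, 0.0)
        self.I_bmp = np.append(self.I_bmp, 0.0)
        return self.n_cells - 1

    def add_elements(self, cell_indices, new_positions) -> None:
        """Insert one new element into each listed cell (batched)."""
        if len(cell_indices) == 0:
            return
        cs = self.cell_start
        where = [cs[i + 1] for i in cell_indices]
        order = np.argsort(where, kind="stable")
        where = np.asarray(where)[order]
        new_positions = np.asarray(new_positions, float)[order]
        self.pos = np.insert(self.pos, where, new_positions, axis=0)
        for i in cell_indices:
            self.counts[i] += 1

    def remove_cells(self, cell_mask: np.ndarray) -> None:
        if not np.any(cell_mask):
            return
        keep = ~cell_mask
        el_keep = np.repeat(keep, self.counts)
        self.pos = self.pos[el_keep]
        for name in ("counts", "cell_id", "type", "cycle_length_h", "timer_h",
                     "growth_progress_h", "paneth_life_wk", "age_paneth_wk",
                     "out_of_contact", "I_wnt", "I_notch", "I_bmp"):
            setattr(self, name, getattr(self, name)[keep])


@dataclass
class GradientSpec:
    """Exogenous gradient along the crypt axis, normalised to [0, 1].

    WNT is highest at the base (1 - z/H); BMP opposes it (z/H).  Multiplicative
    Gaussian noise of amplitude sigma, uncorrelated in space and time, is
    applied on top of the clipped profile.
    """
    kind: str          # "WNT" or "BMP"
    H: float = 160.0
    sigma: float = 0.0

    def profile(self, z):
        z = np.asarray(z, float)
        frac = np.clip(z / self.H, 0.0, 1.0)
        return 1.0 - frac if self.kind == "WNT" else frac


def exogenous_signal(z, spec: GradientSpec, rng: np.random.Generator):
    """Noisy gradient level at height z: profile(z) * (1 + sigma*xi), floored at 0."""
    base = spec.profile(z)
    if spec.sigma == 0.0:
        return base if np.ndim(z) else float(base)
    xi = rng.standard_normal(np.shape(base) if np.ndim(base) else None)
    val = np.maximum(base * (1.0 + spec.sigma * xi), 0.0)
    return val if np.ndim(z) else float(val)


# ---------------------------------------------------------------------------
# Notch contact signalling
# ---------------------------------------------------------------------------

def contact_pairs(coll: CellCollection, contact_distance: float):
    """Unique undirected pairs of cells with any element pair within range."""
    if coll.n_elements == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ei, ej = build_pair_list(coll.pos, coll.el_cell, contact_distance)
    if len(ei) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ec = coll.el_cell
    a, b = ec[ei], ec[ej]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    key = np.unique(lo.astype(np.int64) * coll.n_cells + hi)
    return key // coll.n_cells, key % coll.n_cells


def contact_neighbors(coll: CellCollection, i: int,
                      contact_distance: float) -> np.ndarray:
    """Indices of cells in contact with cell i (excluding i itself)."""
    a, b = contact_pairs(coll, contact_distance)
    return np.concatenate([b[a == i], a[b == i]])


def notch_activity(coll: CellCollection, contacts: np.ndarray,
                   config: ScenarioConfig) -> float:
    """I_notch = sum over contacting neighbours of their ligand weight NP."""
    np_weight = {PANETH: config.np_paneth, GOBLET: config.np_goblet}
    return float(sum(np_weight.get(int(t), 0.0) for t in coll.type[contacts]))


def compute_notch(coll: CellCollection, config: ScenarioConfig) -> np.ndarray:
    """Vectorised I_notch for every cell."""
    weights = np.zeros(5)
    weights[PANETH] = config.np_paneth
    weights[GOBLET] = config.np_goblet
    out = np.zeros(coll.n_cells)
    a, b = contact_pairs(coll, config.contact_distance)
    if len(a):
        np.add.at(out, a, weights[coll.type[b]])
        np.add.at(out, b, weights[coll.type[a]])
    return out


# ---------------------------------------------------------------------------
# Wnt exposure
# ---------------------------------------------------------------------------

def total_wnt(coll: CellCollection, i: int, grid, spec: GradientSpec,
              rng: np.random.Generator, global_on: bool = True) -> float:
    """Local (mean over the cell's elements) plus exogenous Wnt exposure."""
    local = 0.0
    if grid is not None:
        local = float(np.mean(chemfield.sample_field(grid, coll.elements_of(i))))
    if not global_on:
        return local
    zc = float(coll.elements_of(i)[:, 2].mean())
    return local + exogenous_signal(zc, spec, rng)


def compute_total_wnt(coll: CellCollection, grid, spec: GradientSpec,
                      rng: np.random.Generator, global_on: bool) -> np.ndarray:
    local = np.zeros(coll.n_cells)
    if grid is not None and coll.n_elements:
        # clamp stray elements to the box edge; the field vanishes there
        lo = grid.origin + 1e-9
        hi = (grid.origin + (np.array(grid.shape) - 1) * grid.spacing - 1e-9)
        pts = np.clip(coll.pos, lo, hi)
        per_el = chemfield.sample_field(grid, pts)
        cs = coll.cell_start
        local = np.add.reduceat(per_el, cs[:-1]) / coll.counts
    if not global_on:
        return local
    zc = coll.centroids()[:, 2]
    return local + exogenous_signal(zc, spec, rng)


# ---------------------------------------------------------------------------
# fate rules
# ---------------------------------------------------------------------------

def fate_table(I_wnt, I_notch, config: ScenarioConfig):
    """The raw joint Wnt/Notch fate map (before absorbing/reversibility rules)."""
    I_wnt = np.asarray(I_wnt, float)
    I_notch = np.asarray(I_notch, float)
    high_w = I_wnt >= config.th_wnt
    high_n = I_notch >= config.th_notch
    out = np.where(high_w, np.where(high_n, STEM, PANETH),
                   np.where(high_n, ENTEROCYTE, GOBLET))
    return out.astype(np.int8)


def update_fate(cell_type: int, I_wnt: float, I_notch: float,
                config: ScenarioConfig) -> int:
    """New type of a single cell; Paneth is absorbing, E/G only interconvert."""
    if cell_type == PANETH:
        return PANETH
    raw = int(fate_table(I_wnt, I_notch, config))
    if cell_type in (ENTEROCYTE, GOBLET) and not config.allow_stem_reentry:
        return ENTEROCYTE if I_notch >= config.th_notch else GOBLET
    return raw


def update_fates(types: np.ndarray, I_wnt: np.ndarray, I_notch: np.ndarray,
                 config: ScenarioConfig) -> np.ndarray:
    raw = fate_table(I_wnt, I_notch, config)
    new = types.copy()
    stem = types == STEM
    new[stem] = raw[stem]
    eg = (types == ENTEROCYTE) | (types == GOBLET)
    if config.allow_stem_reentry:
        new[eg] = raw[eg]
    else:
        new[eg] = np.where(I_notch[eg] >= config.th_notch, ENTEROCYTE, GOBLET)
    return new


# ---------------------------------------------------------------------------
# stochastic draws
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


def draw_cycle_length(rng: np.random.Generator, config: ScenarioConfig,
                      size=None):
    """Stem-cell cycle length (h): truncated normal, minus any cycle_shift_h."""
    lo, hi = config.cycle_bounds_h
    val = _truncated_normal(rng, config.cycle_mean_h, config.cycle_sd_h,
                            lo, hi, size)
    return val - config.cycle_shift_h


def draw_paneth_lifetime(rng: np.random.Generator, config: ScenarioConfig,
                         size=None):
    """Paneth post-differentiation lifetime (weeks): truncated normal."""
    lo, hi = config.paneth_life_bounds_wk
    return _truncated_normal(rng, config.paneth_life_mean_wk,
                             config.paneth_life_sd_wk, lo, hi, size)


# ---------------------------------------------------------------------------
# growth, division, removal
# ---------------------------------------------------------------------------

def divide_cell(coll: CellCollection, i: int, surface: CryptSurface,
                rng: np.random.Generator, config: ScenarioConfig,
                cycle_mean_override: float | None = None,
                plane_normal: np.ndarray | None = None,
                separation: float = 0.0) -> int:
    """Split cell i through a plane perpendicular to the crypt wall.

    The division plane contains the local wall normal (so both daughters keep
    wall contact) at a uniformly random azimuth; elements are partitioned by
    side with counts balanced to within one.  Returns the new cell's index.

    ``plane_normal`` overrides the random azimuth (used by the packing stage
    to steer daughters toward free wall area) and ``separation`` nudges the
    two daughters apart along it.
    """
    if coll.type[i] not in (STEM, UNASSIGNED):
        raise ValueError("only stem (or pre-identity) cells divide")
    els = coll.elements_of(i)
    if len(els) < 2:
        raise ValueError("cannot divide a single-element cell")
    centroid = els.mean(axis=0)
    _, w, _ = surface.surface_query(centroid)
    if plane_normal is None:
        # orthonormal tangent basis perpendicular to the wall normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, w)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(w, ref)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(w, t1)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        plane_normal = np.cos(theta) * t1 + np.sin(theta) * t2
    else:
        plane_normal = np.asarray(plane_normal, float)
        plane_normal = plane_normal - np.dot(plane_normal, w) * w
        nrm = np.linalg.norm(plane_normal)
        if nrm < 1e-9:
            raise ValueError("plane normal parallel to the wall normal")
        plane_normal = plane_normal / nrm
    d = (els - centroid) @ plane_normal
    order = np.argsort(d, kind="stable")  # median split balances counts +-1
    half = len(els) // 2
    keep_local = np.sort(order[:half + len(els) % 2])
    move_local = np.sort(order[half + len(els) % 2:])
    moved = els[move_local].copy()
    kept = els[keep_local].copy()
    if separation > 0.0:
        # nudge the daughters apart along the separation axis (packing aid)
        kept -= 0.5 * separation * plane_normal
        moved += 0.5 * separation * plane_normal

    cs = coll.cell_start
    # shrink cell i to the kept elements
    mask = np.ones(coll.n_elements, bool)
    mask[cs[i] + move_local] = False
    coll.pos = coll.pos[mask]
    coll.pos[cs[i]:cs[i] + len(kept)] = kept
    coll.counts[i] = len(kept)

    if cycle_mean_override is not None:
        new_cycle = rng.uniform(0.8, 1.2) * cycle_mean_override
        my_cycle = rng.uniform(0.8, 1.2) * cycle_mean_override
    else:
        new_cycle = draw_cycle_length(rng, config)
        my_cycle = draw_cycle_length(rng, config)
    j = coll.add_cell(moved, int(coll.type[i]), new_cycle)
    coll.timer_h[i] = 0.0
    coll.timer_h[j] = 0.0
    coll.cycle_length_h[i] = my_cycle
    coll.growth_progress_h[i] = 0.0
    coll.growth_progress_h[j] = 0.0
    return j


def wall_distances(pos: np.ndarray, surface: CryptSurface) -> np.ndarray:
    out = np.empty(len(pos))
    _batch_wall_distances(np.ascontiguousarray(pos), surface.R, surface.H, out)
    return out


def lifecycle_update(coll: CellCollection, grid, surface: CryptSurface,
                     config: ScenarioConfig, rng: np.random.Generator,
                     dt_h: float, packing: bool = False,
                     packing_division_mask: np.ndarray | None = None,
                     packing_division_dirs: np.ndarray | None = None) -> dict:
    """One growth / division / fate / removal update.

    Order: timers advance; growth adds elements on schedule; stem cells whose
    timer expired divide unless BMP-inhibited; fates update from the current
    signal exposures; cells past the rim, detached from the wall, or at the
    end of a Paneth lifetime are removed.  Returns bookkeeping counts.

    With ``packing=True`` (initial-condition generation) fate rules and
    signalling are skipped, every cell is proliferative and cycle lengths are
    drawn around config.packing_cycle_h.
    """
    stats = {"births": 0, "removed_rim": 0, "removed_detached": 0,
             "removed_apoptosis": 0, "fate_changes": 0, "grown": 0}
    if coll.n_cells == 0:
        return stats
    n_before = coll.n_cells

    # (1) timers
    coll.timer_h += dt_h
    coll.growth_progress_h += dt_h
    paneth = coll.type == PANETH
    coll.age_paneth_wk[paneth] += dt_h / (7.0 * 24.0)

    # (2) growth: elements on a regular schedule until N elements; when the
    # update interval spans several growth intervals, several are added
    N = config.n_elements
    cycle_ref = config.packing_cycle_h if packing else config.cycle_mean_h
    growth_interval = cycle_ref / (N / 2.0)
    n_add = np.minimum((coll.growth_progress_h // growth_interval).astype(int),
                       N - coll.counts)
    n_add = np.maximum(n_add, 0)
    grow_idx = np.nonzero(n_add > 0)[0]
    if len(grow_idx):
        rep = np.repeat(grow_idx, n_add[grow_idx])
        cents = coll.centroids()[rep]
        offsets = rng.normal(0.0, 0.5, size=(len(rep), 3))
        coll.add_elements(rep, cents + offsets)
        coll.growth_progress_h[grow_idx] -= (n_add[grow_idx]
                                             * growth_interval)
        stats["grown"] = int(n_add[grow_idx].sum())

    # (3) signal exposures (needed both for division gating and fates)
    if not packing:
        wnt_spec = GradientSpec("WNT", config.crypt_height, config.noise_sigma_wnt)
        bmp_spec = GradientSpec("BMP", config.crypt_height, config.noise_sigma_bmp)
        contacts = contact_pairs(coll, config.contact_distance)
        coll.I_wnt = compute_total_wnt(coll, grid, wnt_spec, rng,
                                       config.global_wnt_on)
        zc = coll.centroids()[:, 2]
        coll.I_bmp = np.asarray(exogenous_signal(zc, bmp_spec, rng))
        weights = np.zeros(5)
        weights[PANETH] = config.np_paneth
        weights[GOBLET] = config.np_goblet
        coll.I_notch = np.zeros(coll.n_cells)
        a, b = contacts
        if len(a):
            np.add.at(coll.I_notch, a, weights[coll.type[b]])
            np.add.at(coll.I_notch, b, weights[coll.type[a]])

    # (4) divisions
    if packing:
        ready = (coll.timer_h >= coll.cycle_length_h) & (coll.counts >= 2)
        if packing_division_mask is not None:
            ready &= packing_division_mask
    else:
        ready = ((coll.type == STEM)
                 & (coll.timer_h >= coll.cycle_length_h)
                 & (coll.counts >= 2))
        if config.bmp_on:
            ready &= coll.I_bmp < config.th_bmp
    for i in np.nonzero(ready)[0]:
        if packing:
            pn = None
            if packing_division_dirs is not None:
                pn = packing_division_dirs[i]
                if not np.any(pn):
                    pn = None
            try:
                # pre-separate daughters to near the LJ equilibrium spacing
                # so no long capped-force transient follows the division
                divide_cell(coll, int(i), surface, rng, config,
                            cycle_mean_override=config.packing_cycle_h,
                            plane_normal=pn, separation=4.0)
            except ValueError:
                divide_cell(coll, int(i), surface, rng, config,
                            cycle_mean_override=config.packing_cycle_h)
        else:
            divide_cell(coll, int(i), surface, rng, config)
        stats["births"] += 1
    if not packing and stats["births"]:
        # daughters keep their inherited type this update; their exposures
        # are measured from the next update on
        pad = coll.n_cells - len(coll.I_notch)
        if pad > 0:
            coll.I_notch = np.append(coll.I_notch, np.zeros(pad))
            coll.I_wnt = np.append(coll.I_wnt, np.zeros(pad))
            coll.I_bmp = np.append(coll.I_bmp, np.zeros(pad))

    # (5) fates: cells are visited in random order and commit immediately,
    # so each decision sees its neighbours' current identities (asynchronous
    # lateral inhibition; a synchronous sweep makes the whole Goblet/
    # enterocyte mosaic flip coherently instead of settling)
    if not packing:
        n_eval = coll.n_cells - stats["births"]
        adj = [[] for _ in range(coll.n_cells)]
        for x, y in zip(*contacts):
            adj[x].append(y)
            adj[y].append(x)
        old = coll.type.copy()
        for i in rng.permutation(n_eval):
            t = coll.type[i]
            if t == PANETH or t == UNASSIGNED:
                continue
            notch = float(weights[coll.type[adj[i]]].sum()) if adj[i] else 0.0
            coll.I_notch[i] = notch
            coll.type[i] = update_fate(int(t), float(coll.I_wnt[i]), notch,
                                       config)
        became_paneth = (old != PANETH) & (coll.type == PANETH)
        for i in np.nonzero(became_paneth)[0]:
            coll.paneth_life_wk[i] = draw_paneth_lifetime(rng, config)
            coll.age_paneth_wk[i] = 0.0
        stats["fate_changes"] = int(np.sum(old != coll.type))

    # (6) removals
    cents = coll.centroids()
    over_rim = cents[:, 2] > surface.H
    dists = wall_distances(coll.pos, surface)
    cs = coll.cell_start
    attached = np.minimum.reduceat(dists, cs[:-1]) <= config.wall_cutoff
    coll.out_of_contact = np.where(attached, 0, coll.out_of_contact + 1).astype(np.int8)
    detached = coll.out_of_contact >= 2  # one full update of grace
    apoptotic = ((coll.type == PANETH)
                 & (coll.age_paneth_wk >= coll.paneth_life_wk))
    stats["removed_rim"] = int(np.sum(over_rim))
    stats["removed_detached"] = int(np.sum(detached & ~over_rim))
    stats["removed_apoptosis"] = int(np.sum(apoptotic & ~over_rim & ~detached))
    doomed = over_rim | detached | apoptotic
    if np.any(doomed):
        coll.remove_cells(doomed)

    stats["n_cells"] = coll.n_cells
    assert coll.n_cells == n_before + stats["births"] - int(np.sum(doomed))
    return stats
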