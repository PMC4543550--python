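"""Summary statistics of a crypt state: niche height, composition, stability.

Niche height is the extent of the stem compartment up the crypt wall, measured
as the 95th percentile of the stem cells' meridian arc coordinates divided by
the cell diameter (a robust estimate of the compartment boundary in units of
"cells up the wall").  Stability labels follow the qualitative taxonomy used
for crypt simulations: a crypt "dies" when the stem pool is lost, is
"unstable" when the niche expands toward the rim or keeps growing, and is
"stable" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CryptSurface
from .lineage import CellCollection, STEM, PANETH, ENTEROCYTE, GOBLET

__all__ = ["niche_height", "composition", "z_density_profile",
           "classify_stability", "NicheSummary"]


@dataclass
class NicheSummary:
    time_h: float
    niche_height_cd: float
    fractions: dict
    counts: dict


def niche_height(coll: CellCollection, surface: CryptSurface,
                 cell_diameter: float = 10.0) -> float:
    """95th percentile of stem-cell wall-arc positions, in cell diameters."""
    stem = coll.type == STEM
    if not np.any(stem):
        return 0.0
    cents = coll.centroids()[stem]
    arcs = surface.wall_heights(cents)
    return float(np.percentile(arcs, 95.0) / cell_diameter)


def composition(coll: CellCollection) -> dict:
    """Fractions of stem / Paneth / enterocyte / Goblet among live cells."""
    if coll.n_cells == 0:
        raise ValueError("composition of an empty crypt is undefined")
    total = coll.n_cells
    return {
        "stem": float(np.sum(coll.type == STEM)) / total,
        "paneth": float(np.sum(coll.type == PANETH)) / total,
        "enterocyte": float(np.sum(coll.type == ENTEROCYTE)) / total,
        "goblet": float(np.sum(coll.type == GOBLET)) / total,
    }


def z_density_profile(coll: CellCollection, surface: CryptSurface,
                      cell_diameter: float = 10.0,
                      bin_cd: float = 1.0) -> dict:
    """Binned counts of stem and Paneth cells along the wall arc (cell diam.)."""
    nbins = int(np.ceil(surface.total_arc / cell_diameter / bin_cd))
    edges = np.arange(nbins + 1) * bin_cd
    out = {"edges_cd": edges}
    cents = coll.centroids()
    arcs = surface.wall_heights(cents) / cell_diameter
    for name, code in (("stem", STEM), ("paneth", PANETH)):
        sel = coll.type == code
        out[name], _ = np.histogram(arcs[sel], bins=edges)
    return out


def classify_stability(times_h: np.ndarray, heights_cd: np.ndarray,
                       stem_counts: np.ndarray, total_arc_cd: float,
                       occupancy_frac: float = 0.9,
                       slope_threshold_cd_per_h: float = 0.1,
                       slope_window_h: float = 24.0) -> str:
    """Label a niche-height trajectory as 'stable', 'unstable' or 'dies'.

    dies: the stem pool is empty at the end of the series.  unstable: the
    niche occupies >= occupancy_frac of the wall, or its trailing slope over
    slope_window_h exceeds slope_threshold_cd_per_h.  stable: otherwise.
    """
    times_h = np.asarray(times_h, float)
    heights_cd = np.asarray(heights_cd, float)
    stem_counts = np.asarray(stem_counts)
    if times_h[-1] - times_h[0] < 48.0:
        raise ValueError("stability classification needs >= 2 simulated days")
    if stem_counts[-1] == 0:
        return "dies"
    if np.max(heights_cd) >= occupancy_frac * total_arc_cd:
        return "unstable"
    tail = times_h >= times_h[-1] - slope_window_h
    if np.sum(tail) >= 2:
        slope = np.polyfit(times_h[tail], heights_cd[tail], 1)[0]
        if slope > slope_threshold_cd_per_h:
            return "unstable"
    return "stable"
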