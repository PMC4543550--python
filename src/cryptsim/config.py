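"""Scenario configuration: the full simulation parameter set plus experiment switches.

Every physical parameter of the model lives here with its default value, so a
default-constructed :class:`ScenarioConfig` is the baseline parameterization of
the crypt model.  Lengths are in micrometres, mechanical time steps in seconds,
cell-cycle quantities in hours and Paneth lifetimes in weeks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ScenarioConfig", "ConfigError", "ValidationError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for unknown configuration keys."""


class ValidationError(ValueError):
    """Raised when a configuration violates a model invariant; names the field."""


@dataclass
class ScenarioConfig:
    # -- geometry -----------------------------------------------------------
    cell_diameter: float = 10.0          # μm
    crypt_height: float = 160.0          # μm, base pole to rim
    crypt_diameter: float = 60.0         # μm

    # -- subcellular elements / mechanics -----------------------------------
    n_elements: int = 20                 # elements per mature cell (N)
    mu: float = 2.5                      # intra-cell spring stiffness
    r0: float = 1.5                      # μm, spring rest length
    eps_lj: float = 0.05                 # inter-cell Lennard-Jones strength
    sigma_lj: float = 4.5                # μm, LJ zero-crossing separation
    lj_cutoff: float = 10.0              # μm
    eps_external: float = 0.001          # wall adhesion strength
    wall_cutoff: float = 5.0             # μm, half a cell diameter
    b_z: float = -0.3                    # linear drag coefficient along z
    mobility: float = 0.015              # μm²/s per force unit; see docs/methods.md
    paneth_bias_speed: float = 8.0e-4    # μm/s active downhill Paneth migration
    max_step_displacement: float = 0.5   # μm, per-element displacement cap per step
    verlet_skin: float = 1.5             # μm, neighbour-list skin

    # -- time stepping -------------------------------------------------------
    dt_mech: float = 3.6                 # s, mechanics / coupling step
    dt_chem: float = 0.0036              # s, explicit chemical substep
    chem_substeps: int = 1000            # substeps per mechanics step
    lifecycle_every: int = 1             # mechanics steps per lifecycle update
    chem_update_every_s: float = 360.0   # s, quasi-steady field refresh cadence

    # -- signalling thresholds ----------------------------------------------
    th_wnt: float = 0.85
    th_bmp: float = 0.15
    th_notch: float = 0.3                # not printed in the source table; see docs
    np_paneth: float = 0.35              # Notch ligand weight of a Paneth contact
    np_goblet: float = 1.0               # Notch ligand weight of a Goblet contact
    # μm, element separation defining Notch contact; exceeds the inter-cell
    # equilibrium element spacing 2^(1/6)*sigma_lj ~ 5.05 μm so mechanically
    # touching neighbours register as in contact
    contact_distance: float = 6.0

    # -- diffusible Wnt field ------------------------------------------------
    delta_c: float = 0.01                # nominal per-element secretion rate
    D_c: float = 10.0                    # μm²/s (= 1e-7 cm²/s)
    d_c: float = 1.0e-3                  # 1/s decay
    wnt_calibration_distance: float = 12.5  # μm, threshold distance of the base rate
    grid_spacing: float = 1.0            # μm
    grid_margin: float = 4.0             # μm of padding around the crypt box
    chem_mode: str = "explicit"          # {"explicit", "quasi_steady"}
    rho_sat: float = -1.0                # elements/voxel saturating diffusion; <0 → N·h³/V_cell
    diffusivity_floor: float = 0.05      # fraction of D_c kept in saturated tissue

    # -- cell cycle / lifetimes ----------------------------------------------
    cycle_mean_h: float = 24.0
    cycle_sd_h: float = 4.0
    cycle_bounds_h: tuple = (20.0, 28.0)
    paneth_life_mean_wk: float = 8.0
    paneth_life_sd_wk: float = 2.0
    paneth_life_bounds_wk: tuple = (6.0, 10.0)

    # -- scenario switches ----------------------------------------------------
    wnt_production_pct: float = 100.0    # % of the calibrated base rate (0–400)
    global_wnt_on: bool = True
    bmp_on: bool = True
    paneth_migration_on: bool = True
    noise_sigma_wnt: float = 0.0
    noise_sigma_bmp: float = 0.0
    drag_multiplier: float = 1.0
    cycle_shift_h: float = 0.0           # subtracted from drawn stem cycle lengths
    diffusivity_multiplier: float = 1.0  # scales D_c (length-scale experiments)
    decay_multiplier: float = 1.0        # scales d_c
    allow_stem_reentry: bool = False     # differentiated → stem re-entry switch

    # -- initialization (packing) ---------------------------------------------
    packing_cycle_h: float = 1.0         # accelerated cycle used only while packing
    packing_mobility: float = 0.035      # μm²/s per force unit while packing
    packing_eps_factor: float = 3.0      # inter-cell repulsion boost while packing
    packing_coverage: float = 0.95       # wall-coverage fraction ending packing
    packing_cover_radius_cd: float = 1.0 # coverage radius in cell diameters
    packing_saturation_h: float = 5.0    # hours without net growth → confluent
    packing_max_h: float = 240.0         # abort threshold for the packing stage

    # -- misc ------------------------------------------------------------------
    seed: int = 0

    # derived ------------------------------------------------------------------
    @property
    def crypt_radius(self) -> float:
        return self.crypt_diameter / 2.0

    @property
    def rho_sat_value(self) -> float:
        """Saturation element density (elements per voxel of side grid_spacing)."""
        if self.rho_sat > 0:
            return self.rho_sat
        cell_volume = (4.0 / 3.0) * 3.141592653589793 * (self.cell_diameter / 2.0) ** 3
        return self.n_elements * self.grid_spacing**3 / cell_volume

    def validate(self) -> "ScenarioConfig":
        pos = [
            "cell_diameter", "crypt_height", "crypt_diameter", "mu", "r0",
            "eps_lj", "sigma_lj", "lj_cutoff", "eps_external", "wall_cutoff",
            "dt_mech", "dt_chem", "th_wnt", "th_bmp", "th_notch", "np_paneth",
            "np_goblet", "delta_c", "D_c", "d_c", "cycle_mean_h", "cycle_sd_h",
            "paneth_life_mean_wk", "paneth_life_sd_wk", "grid_spacing",
            "mobility", "contact_distance", "wnt_calibration_distance",
        ]
        for name in pos:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.b_z >= 0:
            raise ValidationError("b_z must be negative (drag opposes motion)")
        if self.noise_sigma_wnt < 0 or self.noise_sigma_bmp < 0:
            raise ValidationError("noise_sigma_wnt/noise_sigma_bmp must be >= 0")
        if self.n_elements < 2:
            raise ValidationError("n_elements must be at least 2")
        if self.chem_substeps < 1:
            raise ValidationError("chem_substeps must be at least 1")
        if abs(self.dt_mech - self.chem_substeps * self.dt_chem) > 1e-9 * self.dt_mech:
            raise ValidationError(
                "dt_mech must equal chem_substeps * dt_chem "
                f"({self.dt_mech} != {self.chem_substeps} * {self.dt_chem})"
            )
        if self.chem_mode not in ("explicit", "quasi_steady"):
            raise ValidationError("chem_mode must be 'explicit' or 'quasi_steady'")
        if self.chem_mode == "explicit":
            ratio = self.D_c * self.diffusivity_multiplier * self.dt_chem / self.grid_spacing**2
            if ratio > 1.0 / 6.0 + 1e-12:
                raise ValidationError(
                    f"dt_chem violates the 3D forward-Euler stability bound: "
                    f"D_c*dt_chem/grid_spacing^2 = {ratio:.4g} > 1/6"
                )
        lo, hi = self.cycle_bounds_h
        if not lo < self.cycle_mean_h < hi:
            raise ValidationError("cycle_bounds_h must bracket cycle_mean_h")
        lo, hi = self.paneth_life_bounds_wk
        if not lo < self.paneth_life_mean_wk < hi:
            raise ValidationError("paneth_life_bounds_wk must bracket paneth_life_mean_wk")
        if not 0.0 <= self.wnt_production_pct:
            raise ValidationError("wnt_production_pct must be >= 0")
        if self.crypt_height <= self.crypt_radius:
            raise ValidationError("crypt_height must exceed the crypt radius")
        if self.lj_cutoff <= self.sigma_lj:
            raise ValidationError("lj_cutoff must exceed sigma_lj")
        return self

    # -- serialization ----------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cycle_bounds_h"] = list(self.cycle_bounds_h)
        d["paneth_life_bounds_wk"] = list(self.paneth_life_bounds_wk)
        return d

    def replace(self, **overrides: Any) -> "ScenarioConfig":
        return dataclasses.replace(self, **overrides).validate()


_FIELD_NAMES = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_config(source: "str | Path | dict | None" = None) -> ScenarioConfig:
    """Build a validated config from defaults overlaid with *source*.

    *source* may be a mapping, a YAML file path, or None (pure defaults).
    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("configuration document must be a flat mapping")
    unknown = set(doc) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("cycle_bounds_h", "paneth_life_bounds_wk"):
        if key in doc:
            doc[key] = tuple(doc[key])
    cfg = ScenarioConfig(**doc)
    cfg.validate()
    return cfg


def save_config(config: ScenarioConfig, sink: "str | Path") -> None:
    """Write *config* as a flat YAML document (round-trips through load_config)."""
    with open(sink, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
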