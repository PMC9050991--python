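"""Tissue material properties and temperature-dependent constitutive laws.

The model distinguishes five regions — the metal electrode, the tumour,
trabecular and cortical bone, and surrounding muscle — each with baseline
properties at body temperature (37 °C) and piecewise-linear temperature
dependence:

* electrical conductivity rises 1.5 %/°C up to 100 °C, drops linearly to the
  vapourised-tissue value over 100–105 °C and stays there above;
* thermal conductivity rises 0.33 %/°C up to 100 °C and is capped above;
* volumetric enthalpy is linear in temperature below 99 °C, absorbs the
  latent heat of vaporisation over the 99–100 °C ramp, and continues with
  vapour properties above 100 °C (the enthalpy method for phase change);
* the blood-perfusion sink is proportional to (T − T_blood) while the local
  Arrhenius damage is below the cell-death threshold, and zero afterwards.

All temperatures are handled in °C; only the Arrhenius rate (damage module)
converts to Kelvin.  Enthalpy is volumetric (J/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
import yaml

#: Canonical region tags, in the order used for integer region indices.
REGIONS = ("electrode", "tumour", "trabecular", "cortical", "muscle")

#: Boundary facet tags.
BOUNDARIES = ("outer_muscle", "electrode_surface", "electrode_bottom", "symmetry_axis")

BODY_TEMPERATURE_C = 37.0


class MaterialError(ValueError):
    """Raised for physically invalid material parameters."""


@dataclass(frozen=True)
class TissueProperties:
    """Baseline properties of one tissue/material at 37 °C.

    ``sigma_slope_per_C`` / ``k_slope_per_C`` are fractional increases per °C
    of the electrical / thermal conductivity (defaults 1.5 % and 0.33 %).
    ``water_fraction`` scales the latent-heat ramp of the enthalpy law.
    ``temperature_dependent=False`` (the metal electrode) freezes every law at
    its baseline value except the purely sensible enthalpy.
    """

    sigma_S_per_m: float
    perfusion_per_s: float
    density_kg_per_m3: float
    specific_heat_J_per_kgK: float
    thermal_conductivity_W_per_mK: float
    sigma_slope_per_C: float = 0.015
    k_slope_per_C: float = 0.0033
    water_fraction: float = 0.77
    temperature_dependent: bool = True

    def validate(self) -> None:
        pos = (
            ("sigma_S_per_m", self.sigma_S_per_m),
            ("density_kg_per_m3", self.density_kg_per_m3),
            ("specific_heat_J_per_kgK", self.specific_heat_J_per_kgK),
            ("thermal_conductivity_W_per_mK", self.thermal_conductivity_W_per_mK),
        )
        for name, v in pos:
            if not v > 0:
                raise MaterialError(f"{name} must be > 0, got {v!r}")
        if self.perfusion_per_s < 0:
            raise MaterialError("perfusion_per_s must be >= 0")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise MaterialError("water_fraction must lie in [0, 1]")
        if self.sigma_slope_per_C < 0 or self.k_slope_per_C < 0:
            raise MaterialError("conductivity slopes must be >= 0")


@dataclass(frozen=True)
class GlobalConstants:
    """Constants shared by all tissues: vapour phase, latent heat and blood."""

    sigma_vap_S_per_m: float = 10e-3
    latent_heat_J_per_kg: float = 2.25e6
    rho_vap_kg_per_m3: float = 370.0
    c_vap_J_per_kgK: float = 2156.0
    rho_blood_kg_per_m3: float = 1050.0
    c_blood_J_per_kgK: float = 3617.0
    T_blood_C: float = 37.0
    #: Multiplier on the latent ramp; 1.0 keeps the published volumetric form
    #: h_fg * C_i per degree of the 99-100 °C ramp.
    latent_scale: float = 1.0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name == "latent_scale":
                continue
            if not v > 0:
                raise MaterialError(f"{name} must be > 0, got {v!r}")


def _default_tissues() -> dict[str, TissueProperties]:
    return {
        "electrode": TissueProperties(
            sigma_S_per_m=1.00e8,
            perfusion_per_s=0.0,
            density_kg_per_m3=6450.0,
            specific_heat_J_per_kgK=840.0,
            thermal_conductivity_W_per_mK=18.0,
            water_fraction=0.0,
            temperature_dependent=False,
        ),
        "tumour": TissueProperties(0.4, 0.0, 1150.0, 3664.0, 0.487, water_fraction=0.77),
        "trabecular": TissueProperties(0.05, 0.167e-3, 1080.0, 2060.0, 0.36, water_fraction=0.30),
        "cortical": TissueProperties(0.022, 0.167e-3, 1908.0, 1313.0, 0.32, water_fraction=0.20),
        "muscle": TissueProperties(0.44, 6.6167e-3, 1090.0, 3421.0, 0.49, water_fraction=0.77),
    }


@dataclass(frozen=True)
class MaterialTable:
    """Mapping region tag -> :class:`TissueProperties` plus global constants."""

    tissues: Mapping[str, TissueProperties] = field(default_factory=_default_tissues)
    constants: GlobalConstants = field(default_factory=GlobalConstants)

    def validate(self, required: tuple[str, ...] = REGIONS) -> None:
        missing = [r for r in required if r not in self.tissues]
        if missing:
            raise MaterialError(f"material table is missing regions: {missing}")
        for t in self.tissues.values():
            t.validate()
        self.constants.validate()

    def __getitem__(self, region: str) -> TissueProperties:
        return self.tissues[region]

    # -- constitutive laws dispatched by region name -------------------------
    def sigma(self, region: str, T_C):
        return electrical_conductivity(self.tissues[region], T_C, self.constants)

    def k(self, region: str, T_C):
        return thermal_conductivity(self.tissues[region], T_C)

    def h(self, region: str, T_C):
        return enthalpy(self.tissues[region], T_C, self.constants)

    def dh_dT(self, region: str, T_C):
        return apparent_volumetric_heat_capacity(self.tissues[region], T_C, self.constants)

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tissues": {name: asdict(t) for name, t in self.tissues.items()},
            "constants": asdict(self.constants),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MaterialTable":
        defaults = _default_tissues()
        tissues: dict[str, TissueProperties] = {}
        for name, props in d.get("tissues", {}).items():
            base = defaults.get(name)
            tissues[name] = replace(base, **props) if base else TissueProperties(**props)
        for name, t in defaults.items():
            tissues.setdefault(name, t)
        constants = GlobalConstants(**d.get("constants", {}))
        table = cls(tissues=tissues, constants=constants)
        table.validate()
        return table

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MaterialTable":
        return cls.from_dict(yaml.safe_load(text) or {})


def default_material_table() -> MaterialTable:
    """The published baseline property table with its documented defaults."""
    return MaterialTable()


# ---------------------------------------------------------------------------
# Constitutive laws (vectorised over temperature)
# ---------------------------------------------------------------------------

def electrical_conductivity(tissue: TissueProperties, T_C, constants: GlobalConstants | None = None):
    """Piecewise sigma(T): +1.5 %/°C to 100 °C, linear drop to sigma_vap by 105 °C."""
    gc = constants or GlobalConstants()
    T = np.asarray(T_C, dtype=float)
    s0 = tissue.sigma_S_per_m
    if not tissue.temperature_dependent:
        out = np.full_like(T, s0)
        return out if out.ndim else float(out)
    slope = tissue.sigma_slope_per_C * s0
    lin = s0 + slope * (T - BODY_TEMPERATURE_C)
    s100 = s0 + slope * (100.0 - BODY_TEMPERATURE_C)
    drop = s100 + (gc.sigma_vap_S_per_m - s100) * (T - 100.0) / 5.0
    out = np.where(T <= 100.0, lin, np.where(T <= 105.0, drop, gc.sigma_vap_S_per_m))
    return out if out.ndim else float(out)


def thermal_conductivity(tissue: TissueProperties, T_C):
    """Piecewise k(T): +0.33 %/°C below 100 °C, capped at its 100 °C value."""
    T = np.asarray(T_C, dtype=float)
    k0 = tissue.thermal_conductivity_W_per_mK
    if not tissue.temperature_dependent:
        out = np.full_like(T, k0)
        return out if out.ndim else float(out)
    out = k0 * (1.0 + tissue.k_slope_per_C * (np.minimum(T, 100.0) - BODY_TEMPERATURE_C))
    return out if out.ndim else float(out)


def enthalpy(tissue: TissueProperties, T_C, constants: GlobalConstants | None = None):
    """Volumetric enthalpy h(T) in J/m^3 with h(37 °C) = 0.

    Sensible branch rho_i c_i (T-37) up to 99 °C (extended linearly below
    37 °C), latent ramp over (99, 100] °C, vapour branch above.  The latent
    ramp amplitude is ``latent_scale * h_fg * C_i`` per the published
    volumetric form.
    """
    gc = constants or GlobalConstants()
    T = np.asarray(T_C, dtype=float)
    rc = tissue.density_kg_per_m3 * tissue.specific_heat_J_per_kgK
    sens = rc * (T - BODY_TEMPERATURE_C)
    if not tissue.temperature_dependent:
        return sens if sens.ndim else float(sens)
    h99 = rc * (99.0 - BODY_TEMPERATURE_C)
    latent = gc.latent_scale * gc.latent_heat_J_per_kg * tissue.water_fraction
    ramp = h99 + latent * (T - 99.0)  # printed 1 °C ramp width
    h100 = h99 + latent
    vap = h100 + gc.rho_vap_kg_per_m3 * gc.c_vap_J_per_kgK * (T - 100.0)
    out = np.where(T <= 99.0, sens, np.where(T <= 100.0, ramp, vap))
    return out if out.ndim else float(out)


def apparent_volumetric_heat_capacity(
    tissue: TissueProperties, T_C, constants: GlobalConstants | None = None
):
    """dh/dT in J/(m^3 K); the latent ramp contributes its slope on (99, 100]."""
    gc = constants or GlobalConstants()
    T = np.asarray(T_C, dtype=float)
    rc = tissue.density_kg_per_m3 * tissue.specific_heat_J_per_kgK
    if not tissue.temperature_dependent:
        out = np.full_like(T, rc)
        return out if out.ndim else float(out)
    latent = gc.latent_scale * gc.latent_heat_J_per_kg * tissue.water_fraction
    vap = gc.rho_vap_kg_per_m3 * gc.c_vap_J_per_kgK
    out = np.where(T <= 99.0, rc, np.where(T <= 100.0, latent, vap))
    return out if out.ndim else float(out)


def perfusion_sink(
    tissue: TissueProperties,
    T_C,
    omega,
    constants: GlobalConstants | None = None,
    omega_death: float = 4.6,
):
    """Pennes perfusion heat loss Q_p = omega_i rho_b c_b (T - T_b), gated by damage.

    Returns W/m^3 to be *subtracted* from the heat balance; zero once the
    local damage integral has crossed ``omega_death`` (dead tissue is no
    longer perfused).
    """
    gc = constants or GlobalConstants()
    T = np.asarray(T_C, dtype=float)
    om = np.asarray(omega, dtype=float)
    alive = om < omega_death
    out = np.where(
        alive,
        tissue.perfusion_per_s * gc.rho_blood_kg_per_m3 * gc.c_blood_J_per_kgK * (T - gc.T_blood_C),
        0.0,
    )
    return out if out.ndim else float(out)
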