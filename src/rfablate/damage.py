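"""Arrhenius thermal-damage model.

Cell death is tracked by the dimensionless damage integral

    Omega(t) = integral_0^t A * exp(-dE / (R * T(tau))) dtau

with cell-line parameters for osteocytes (frequency factor A, activation
energy dE).  The survival fraction is exp(-Omega), so Omega = 4.6 marks a
99 % probability of cell death; the same threshold shuts off blood
perfusion and defines the ablation-zone boundary.

Rates are computed in log space first: A is of order 1e133 and the naive
product would overflow long before the exponential brings it back down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class ArrheniusParams:
    """Cell-death kinetics (defaults: osteocytes) and the lesion threshold."""

    frequency_factor_per_s: float = 8.99e133
    activation_energy_J_per_mol: float = 8.38e5
    gas_constant_J_per_molK: float = 8.314
    omega_death: float = 4.6
    rule: str = "rectangle"  # "rectangle" (end-of-step T) or "trapezoid"

    def __post_init__(self):
        if self.frequency_factor_per_s <= 0 or self.activation_energy_J_per_mol <= 0:
            raise ValueError("Arrhenius parameters must be positive")
        if self.omega_death <= 0:
            raise ValueError("omega_death must be positive")
        if self.rule not in ("rectangle", "trapezoid"):
            raise ValueError(f"unknown integration rule {self.rule!r}")

    @property
    def log_frequency_factor(self) -> float:
        return math.log(self.frequency_factor_per_s)


def damage_rate(T_C, params: ArrheniusParams = ArrheniusParams()):
    """First-order damage rate A*exp(-dE/RT) in 1/s, evaluated in log space."""
    T_K = np.asarray(T_C, dtype=float) + _KELVIN_OFFSET
    log_rate = params.log_frequency_factor - params.activation_energy_J_per_mol / (
        params.gas_constant_J_per_molK * T_K
    )
    out = np.exp(np.clip(log_rate, -745.0, 700.0))
    # clip floor maps to exactly 0-ish underflow; restore true zero there
    out = np.where(log_rate <= -745.0, 0.0, out)
    return out if out.ndim else float(out)


def damage_increment(T_C, dt_s: float, params: ArrheniusParams = ArrheniusParams(), T_prev_C=None):
    """One-step increment of Omega.

    Rectangle rule uses the end-of-step temperature ``T_C``; the trapezoid
    rule additionally needs the start-of-step temperature ``T_prev_C``.
    """
    if dt_s < 0:
        raise ValueError("dt_s must be >= 0")
    if params.rule == "trapezoid" and T_prev_C is not None:
        rate = 0.5 * (damage_rate(T_prev_C, params) + damage_rate(T_C, params))
    else:
        rate = damage_rate(T_C, params)
    out = np.asarray(rate, dtype=float) * dt_s
    return out if out.ndim else float(out)


def cell_death_probability(omega):
    """Probability of cell death 1 - exp(-Omega)."""
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ValueError("Omega must be >= 0")
    out = -np.expm1(-om)
    return out if out.ndim else float(out)


def time_to_death_constant_T(T_C: float, params: ArrheniusParams = ArrheniusParams()) -> float:
    """Closed-form time for Omega to reach the death threshold at constant T.

    Inverse of the damage integral at fixed temperature; serves as the
    independent oracle for the time-stepped integrator.  Returns ``inf``
    when the rate underflows (temperature too low to ever kill).
    """
    rate = damage_rate(T_C, params)
    if rate == 0.0:
        return math.inf
    return params.omega_death / rate
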