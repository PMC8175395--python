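"""Adsorption thermodynamics from a temperature series of Langmuir affinities.

The dimensionless thermodynamic equilibrium constant Ke° is obtained from the
Langmuir affinity constant b_L (L/mg) by converting to molar units
(multiplying by the adsorbate molar mass in mg/mol), multiplying by the unit
standard concentration (1 mol/L) and dividing by the activity coefficient
(unity for dilute solutions). Then

    dG°(T) = -R T ln Ke°(T)
    ln Ke° = -dH°/(R T) + dS°/R       (van't Hoff)

so a straight-line regression of ln Ke° on 1/T yields dH° = -R*slope and
dS° = R*intercept.

The affinity constant b_L is the parameter with concentration-inverse units
convertible to L/mol; the monolayer capacity (mg/g) has no such conversion
and is never used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "DIAZINON_MOLAR_MASS",
    "ThermoSeries",
    "ThermoResult",
    "equilibrium_constant",
    "gibbs",
    "vant_hoff_fit",
]

R_GAS = 8.314  # J/(mol K)
#: molar mass of diazinon (C12H21N2O3PS), g/mol — external physical constant
DIAZINON_MOLAR_MASS = 304.35


@dataclass(frozen=True)
class ThermoSeries:
    """Langmuir affinity constants measured at several temperatures."""

    temperatures: tuple[float, ...]  # K
    bL: tuple[float, ...]  # L/mg
    molar_mass: float = DIAZINON_MOLAR_MASS  # g/mol
    activity_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.bL):
            raise ValueError("temperatures and bL must have equal length")
        if len(self.temperatures) < 2:
            raise ValueError("need at least 2 temperatures")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive (K)")
        if any(b <= 0 for b in self.bL):
            raise ValueError("bL must be positive")
        if self.molar_mass <= 0 or self.activity_coefficient <= 0:
            raise ValueError("molar mass and activity coefficient must be positive")


@dataclass(frozen=True)
class ThermoResult:
    temperatures: tuple[float, ...]  # K
    ke: tuple[float, ...]  # dimensionless Ke° per temperature
    dG: tuple[float, ...]  # kJ/mol per temperature
    dH: float  # kJ/mol
    dS: float  # J/(mol K)
    vant_hoff_r2: float


def equilibrium_constant(bL: float, molar_mass: float = DIAZINON_MOLAR_MASS,
                         activity_coefficient: float = 1.0) -> float:
    """Dimensionless Ke° from the Langmuir affinity constant.

    Ke° = b_L [L/mg] * (molar_mass * 1000) [mg/mol] * 1 [mol/L] / gamma.
    """
    if bL <= 0 or molar_mass <= 0 or activity_coefficient <= 0:
        raise ValueError("all inputs must be positive")
    return bL * molar_mass * 1000.0 / activity_coefficient


def gibbs(ke: float, T: float) -> float:
    """Standard Gibbs free energy change, dG° = -R T ln Ke°, in kJ/mol."""
    if ke <= 0:
        raise ValueError("Ke must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return -R_GAS * T * np.log(ke) / 1000.0


def vant_hoff_fit(series: ThermoSeries) -> ThermoResult:
    """van't Hoff regression of ln Ke° on 1/T.

    Returns per-temperature Ke° and dG° plus dH° (kJ/mol, from the slope) and
    dS° (J/(mol K), from the intercept).
    """
    temps = np.asarray(series.temperatures, dtype=float)
    ke = np.array(
        [
            equilibrium_constant(b, series.molar_mass, series.activity_coefficient)
            for b in series.bL
        ]
    )
    inv_t = 1.0 / temps
    ln_ke = np.log(ke)
    if len(temps) == 2:
        slope = (ln_ke[1] - ln_ke[0]) / (inv_t[1] - inv_t[0])
        intercept = ln_ke[0] - slope * inv_t[0]
        r2 = 1.0
    elif np.ptp(ln_ke) < 1e-12:
        # temperature-independent Ke: zero slope, R^2 of a perfect constant fit
        slope, intercept, r2 = 0.0, float(ln_ke.mean()), 1.0
    else:
        reg = stats.linregress(inv_t, ln_ke)
        slope, intercept = reg.slope, reg.intercept
        r2 = reg.rvalue ** 2
    dH = -R_GAS * slope / 1000.0  # kJ/mol
    dS = R_GAS * intercept  # J/(mol K)
    dG = tuple(gibbs(k, t) for k, t in zip(ke, temps))
    return ThermoResult(
        temperatures=tuple(temps),
        ke=tuple(ke),
        dG=dG,
        dH=float(dH),
        dS=float(dS),
        vant_hoff_r2=float(r2),
    )
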