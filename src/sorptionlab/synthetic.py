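"""Seeded generators for every input the analysis pipeline consumes.

The study's raw measurements (30-run design table, equilibrium and kinetic
traces, temperature series) are not deposited, so these generators emulate
them: a known ground truth (quadratic surface, isotherm, kinetic law or
(dH°, dS°) pair) plus additive Gaussian noise, truncated to the physical
range with truncation events counted. Defaults reproduce the study
conditions: a 30-run four-factor CCD with replicate variability well under
2 % of the response, 21-point equilibrium curves, 3-30 min kinetic traces,
and the four-temperature series 293/303/313/323 K.

Every generator is a pure function of its arguments; the same seed yields an
identical table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import IsothermSpec, KineticSpec, isotherm_predict, kinetic_predict
from .rsm import CCDDesign, FactorSpace, QuadraticModel, build_ccd, predict_quadratic
from .thermo import DIAZINON_MOLAR_MASS, R_GAS, ThermoSeries, equilibrium_constant

__all__ = [
    "DEFAULT_CE_GRID",
    "DEFAULT_TIME_GRID",
    "DEFAULT_TEMPERATURES",
    "gen_ccd_response",
    "gen_equilibrium",
    "gen_kinetics",
    "gen_thermo_series",
]

#: 21 equilibrium concentrations spanning 0.5-50 mg/L
DEFAULT_CE_GRID = tuple(np.linspace(0.5, 50.0, 21))
#: kinetic sampling instants, 3-30 min
DEFAULT_TIME_GRID = tuple(np.arange(3.0, 31.0, 3.0))
#: 20/30/40/50 degC expressed in kelvin
DEFAULT_TEMPERATURES = (293.0, 303.0, 313.0, 323.0)


def gen_ccd_response(
    space: FactorSpace,
    truth: QuadraticModel,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_center: int = 6,
) -> tuple[pd.DataFrame, CCDDesign, int]:
    """CCD design table with a quadratic response plus Gaussian noise.

    Removal is clipped to [0, 100] % after noise; the number of clipped rows
    is returned so callers can require zero truncations. Default noise
    (sd 0.5 %) reflects replicate variability below 2 % of the response.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    design = build_ccd(space, n_center)
    rng = np.random.default_rng(seed)
    clean = predict_quadratic(truth, design.actuals)
    noisy = clean + rng.normal(0.0, noise_sd, size=len(design)) if noise_sd > 0 else clean.copy()
    clipped = np.clip(noisy, 0.0, 100.0)
    n_truncated = int(np.sum(clipped != noisy))
    df = pd.DataFrame(design.actuals, columns=list(space.names))
    for i, name in enumerate(space.names):
        df[f"coded_{name}"] = design.runs[:, i]
    df["response"] = clipped
    return df, design, n_truncated


def gen_equilibrium(
    spec: IsothermSpec,
    ce_grid: Sequence[float] = DEFAULT_CE_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Equilibrium (ce, qe) table from an isotherm ground truth."""
    ce = np.asarray(ce_grid, dtype=float)
    if np.any(ce <= 0):
        raise ValueError("ce grid must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    qe = np.asarray(isotherm_predict(spec, ce), dtype=float)
    if noise_sd > 0:
        qe = qe + rng.normal(0.0, noise_sd, size=ce.size)
    truncated = qe < 0
    qe = np.where(truncated, 0.0, qe)
    return pd.DataFrame({"ce_mg_L": ce, "qe_mg_g": qe}), int(truncated.sum())


def gen_kinetics(
    spec: KineticSpec,
    t_grid: Sequence[float] = DEFAULT_TIME_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Kinetic (t, qt) table from a rate-law ground truth."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    qt = np.asarray(kinetic_predict(spec, t), dtype=float)
    if noise_sd > 0:
        qt = qt + rng.normal(0.0, noise_sd, size=t.size)
    truncated = qt < 0
    qt = np.where(truncated, 0.0, qt)
    return pd.DataFrame({"t_min": t, "qt_mg_g": qt}), int(truncated.sum())


def gen_thermo_series(
    dH: float,
    dS: float,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    molar_mass: float = DIAZINON_MOLAR_MASS,
) -> ThermoSeries:
    """Temperature series of Langmuir affinities from chosen (dH°, dS°).

    Ke(T) = exp(dS/R - dH*1000/(R T)); b_L is back-computed by inverting the
    Ke° unit conversion, so a van't Hoff fit of the series recovers (dH, dS)
    exactly.
    """
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (K)")
    ke = np.exp(dS / R_GAS - dH * 1000.0 / (R_GAS * temps))
    scale = equilibrium_constant(1.0, molar_mass)  # Ke per unit bL
    bl = ke / scale
    return ThermoSeries(
        temperatures=tuple(temps), bL=tuple(bl), molar_mass=molar_mass
    )
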