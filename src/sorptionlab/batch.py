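"""Mass-balance arithmetic of batch adsorption runs and adsorbent characterization.

Covers the bookkeeping every batch sorption study relies on: removal
efficiency and adsorption capacity from initial/residual concentrations,
porosity and dry density of a porous adsorbent from a saturation/buoyancy
weighing sequence, and location of the point of zero charge from a pH-drift
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "BatchRecord",
    "BuoyancyMeasurement",
    "PorosityResult",
    "removal_efficiency",
    "adsorption_capacity",
    "porosity_density",
    "find_phzpc",
    "read_batch_records",
]

_DOSAGE_RTOL = 1e-6

BATCH_CSV_COLUMNS = ["pH", "time_min", "c0_mg_L", "ce_mg_L", "volume_L", "mass_g"]


@dataclass
class BatchRecord:
    """One batch adsorption run.

    ``ce > c0`` (apparent negative removal) is retained and flagged as a
    measurement anomaly rather than rejected: at low initial concentration
    instrument noise routinely produces such records.
    """

    pH: float
    time: float  # contact time, min
    c0: float  # initial concentration, mg/L
    ce: float  # residual concentration, mg/L
    dosage: Optional[float] = None  # adsorbent, g/L
    volume: Optional[float] = None  # solution, L
    mass: Optional[float] = None  # adsorbent, g
    temperature: Optional[float] = None  # K
    anomaly: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if self.ce < 0:
            raise ValueError(f"ce must be nonnegative, got {self.ce}")
        if self.volume is not None and self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.mass is not None and self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.volume is not None and self.mass is not None:
            derived = self.mass / self.volume
            if self.dosage is None:
                self.dosage = derived
            elif not math.isclose(self.dosage, derived, rel_tol=_DOSAGE_RTOL):
                raise ValueError(
                    f"dosage {self.dosage} g/L inconsistent with mass/volume = {derived} g/L"
                )
        self.anomaly = self.ce > self.c0

    @property
    def removal(self) -> float:
        return removal_efficiency(self.c0, self.ce)

    @property
    def capacity(self) -> Optional[float]:
        if self.volume is None or self.mass is None:
            if self.dosage is None:
                return None
            return (self.c0 - self.ce) / self.dosage
        return adsorption_capacity(self.c0, self.ce, self.volume, self.mass)


@dataclass(frozen=True)
class BuoyancyMeasurement:
    """Weighing sequence of the saturation/buoyancy (Archimedes) technique.

    A = empty container; B = saturated sample + container;
    C = oven-dry sample + container; Msub = saturated-submerged sample mass.
    """

    massContainer_A: float
    massSatPlusContainer_B: float
    massDryPlusContainer_C: float
    massSubmerged_Msub: float
    waterDensity_rho_w: float = 1.0  # g/cm3

    def __post_init__(self) -> None:
        a, b, c = self.massContainer_A, self.massSatPlusContainer_B, self.massDryPlusContainer_C
        if min(a, b, c, self.massSubmerged_Msub) < 0:
            raise ValueError("all masses must be nonnegative")
        if not (b >= c >= a):
            raise ValueError(f"expected B >= C >= A, got B={b}, C={c}, A={a}")
        if self.waterDensity_rho_w <= 0:
            raise ValueError("water density must be positive")


@dataclass(frozen=True)
class PorosityResult:
    msat: float  # saturated sample mass, g
    ms: float  # dry sample mass, g
    bulkVolume_V: float  # cm3
    poreVolume_VV: float  # cm3
    dryDensity_rho_d: float  # g/cm3
    porosity_n: float  # percent


def removal_efficiency(c0: float, ce: float) -> float:
    """Percent of solute removed from solution, 100*(c0-ce)/c0.

    May be negative when ce > c0; the caller flags such records as anomalies.
    """
    if c0 <= 0:
        raise ValueError(f"c0 must be positive, got {c0}")
    return 100.0 * (c0 - ce) / c0


def adsorption_capacity(c0: float, ce: float, volume: float, mass: float) -> float:
    """Adsorbed amount per adsorbent mass, q = (c0-ce)*V/m in mg/g."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return (c0 - ce) * volume / mass


def porosity_density(m: BuoyancyMeasurement) -> PorosityResult:
    """Porosity and dry density from a saturation/buoyancy weighing sequence.

    msat = B - A, ms = C - A, bulk volume V = (msat - Msub)/rho_w,
    pore volume VV = (msat - ms)/rho_w, rho_d = ms/V, n = 100*VV/V.
    """
    msat = m.massSatPlusContainer_B - m.massContainer_A
    ms = m.massDryPlusContainer_C - m.massContainer_A
    volume = (msat - m.massSubmerged_Msub) / m.waterDensity_rho_w
    pore = (msat - ms) / m.waterDensity_rho_w
    if volume <= 0:
        raise ValueError(
            "degenerate sample: bulk volume is nonpositive "
            f"(msat={msat} g, Msub={m.massSubmerged_Msub} g)"
        )
    return PorosityResult(
        msat=msat,
        ms=ms,
        bulkVolume_V=volume,
        poreVolume_VV=pore,
        dryDensity_rho_d=ms / volume,
        porosity_n=100.0 * pore / volume,
    )


def find_phzpc(initial_pH: Sequence[float], final_pH: Sequence[float]) -> float:
    """Point of zero charge from a pH-drift experiment.

    Locates the pH at which the drift (final - initial) crosses zero, by
    linear interpolation between the bracketing measurement pair. An exact
    zero drift at a measured point returns that point directly.
    """
    init = list(initial_pH)
    fin = list(final_pH)
    if len(init) != len(fin):
        raise ValueError("initial and final pH lists must have equal length")
    if len(init) < 2:
        raise ValueError("need at least 2 drift measurements")
    if any(b <= a for a, b in zip(init, init[1:])):
        raise ValueError("initial pH values must be strictly increasing")
    drift = [f - i for i, f in zip(init, fin)]
    for x, d in zip(init, drift):
        if d == 0.0:
            return x
    for (x1, d1), (x2, d2) in zip(zip(init, drift), zip(init[1:], drift[1:])):
        if d1 * d2 < 0:
            return x1 - d1 * (x2 - x1) / (d2 - d1)
    raise ValueError("no zero crossing of pH drift in the measured range")


def read_batch_records(path: str | Path) -> list[BatchRecord]:
    """Read batch runs from CSV.

    Expected header: ``pH,time_min,c0_mg_L,ce_mg_L,volume_L,mass_g,temperature_K``
    (temperature column optional).
    """
    df = pd.read_csv(path)
    missing = [c for c in BATCH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"batch CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        temp = row.get("temperature_K")
        records.append(
            BatchRecord(
                pH=float(row["pH"]),
                time=float(row["time_min"]),
                c0=float(row["c0_mg_L"]),
                ce=float(row["ce_mg_L"]),
                volume=float(row["volume_L"]),
                mass=float(row["mass_g"]),
                temperature=None if temp is None or pd.isna(temp) else float(temp),
            )
        )
    return records
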