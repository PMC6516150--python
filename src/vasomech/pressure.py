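"""Pressure myography: passive mechanics of pressurized resistance arteries.

A cannulated mesenteric artery in calcium-free medium is inflated in steps
(nominally 3 to 120 mmHg) while inner and outer diameters are tracked.
From the passive pressure-diameter series this module derives

- wall thickness ``WT = (De - Di) / 2`` and wall:lumen ``(De - Di)/(2 Di)``,
- incremental distensibility, the percent change of inner diameter per mmHg
  of each pressure step,
- circumferential strain ``eps = (Di - D00)/D00`` relative to the inner
  diameter at 3 mmHg (D00), and circumferential stress
  ``sigma = P * Di / (2 WT)`` in dyn/cm^2,
- the stiffness exponent ``beta`` of the exponential wall model
  ``sigma = sigma_orig * exp(beta * eps)``, fitted per animal; the
  incremental elastic modulus follows as ``E_inc = beta * sigma``.

Higher beta means a stiffer wall independent of geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from vasomech.units import MMHG_TO_DYN_PER_CM2

__all__ = [
    "PressureDiameterSeries",
    "BetaFit",
    "PassiveMechanics",
    "geometry",
    "incremental_distensibility",
    "stress_strain",
    "fit_beta",
    "analyze_series",
    "read_series_csv",
]

#: Pressure protocol: 20 mmHg steps from 3 mmHg, capped at 120 mmHg
#: (the last step is therefore 17 mmHg).
DEFAULT_PRESSURES_MMHG = (3.0, 23.0, 43.0, 63.0, 83.0, 103.0, 120.0)


@dataclass
class PressureDiameterSeries:
    """Passive pressure vs inner/outer diameter series for one artery.

    ``d00`` is the inner diameter at the 3 mmHg entry — the strain
    reference — and is derived from the series itself.
    """

    pressures_mmhg: np.ndarray
    di_um: np.ndarray
    de_um: np.ndarray
    animal_id: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures_mmhg = np.asarray(self.pressures_mmhg, dtype=float)
        self.di_um = np.asarray(self.di_um, dtype=float)
        self.de_um = np.asarray(self.de_um, dtype=float)
        if not (
            self.pressures_mmhg.shape == self.di_um.shape == self.de_um.shape
        ):
            raise ValueError("pressure and diameter arrays differ in length")
        if not np.all(np.diff(self.pressures_mmhg) > 0):
            raise ValueError("pressures must be strictly increasing")
        if np.any(self.de_um <= self.di_um):
            raise ValueError("outer diameter must exceed inner diameter")
        if not np.any(np.isclose(self.pressures_mmhg, 3.0)):
            raise ValueError("series must contain the 3 mmHg reference point")

    @property
    def d00_um(self) -> float:
        """Inner diameter at 3 mmHg (unloaded reference, um)."""
        idx = int(np.argmin(np.abs(self.pressures_mmhg - 3.0)))
        return float(self.di_um[idx])


@dataclass(frozen=True)
class BetaFit:
    """Exponential stress-strain fit ``sigma = sigma_orig * exp(beta*eps)``."""

    beta: float
    sigma_orig: float  # dyn/cm^2, stress at the unloaded diameter
    r2: float

    def einc_at(self, sigma: float) -> float:
        """Incremental elastic modulus E_inc = beta * sigma (dyn/cm^2)."""
        return self.beta * sigma


@dataclass(frozen=True)
class PassiveMechanics:
    """Per-pressure structural/mechanical profile plus the beta fit."""

    pressures_mmhg: np.ndarray
    wt_um: np.ndarray
    wall_lumen: np.ndarray
    incr_distensibility_pct_per_mmhg: np.ndarray  # per step, length n-1
    strain: np.ndarray
    stress_dyn_per_cm2: np.ndarray
    fit: BetaFit


def geometry(series: PressureDiameterSeries) -> tuple[np.ndarray, np.ndarray]:
    """Wall thickness (um) and wall:lumen ratio at each pressure."""
    wt = (series.de_um - series.di_um) / 2.0
    if np.any(wt <= 0):
        raise ValueError("invalid geometry: outer diameter <= inner diameter")
    wall_lumen = (series.de_um - series.di_um) / (2.0 * series.di_um)
    return wt, wall_lumen


def incremental_distensibility(
    series: PressureDiameterSeries, denominator: str = "lower"
) -> np.ndarray:
    """Percent change in inner diameter per mmHg for each pressure step.

    ``denominator`` selects the reference diameter of each step: ``"lower"``
    (default) uses the diameter at the lower pressure, ``"midpoint"`` the
    mean of the two.
    """
    if series.pressures_mmhg.size < 2:
        raise ValueError("need at least two pressures")
    dp = np.diff(series.pressures_mmhg)
    if np.any(dp == 0):
        raise ValueError("zero pressure step")
    ddi = np.diff(series.di_um)
    if denominator == "lower":
        ref = series.di_um[:-1]
    elif denominator == "midpoint":
        ref = (series.di_um[:-1] + series.di_um[1:]) / 2.0
    else:
        raise ValueError("denominator must be 'lower' or 'midpoint'")
    return ddi / (ref * dp) * 100.0


def stress_strain(
    series: PressureDiameterSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Circumferential strain and stress (dyn/cm^2) at each pressure.

    Strain is relative to the 3 mmHg inner diameter; stress is
    ``P * Di / (2 WT)`` with P converted at 1 mmHg = 133.4e3 dyn/cm^2
    (the diameter units cancel).
    """
    d00 = series.d00_um
    if d00 <= 0:
        raise ValueError("non-positive reference diameter")
    wt, _ = geometry(series)
    strain = (series.di_um - d00) / d00
    stress = (
        series.pressures_mmhg * MMHG_TO_DYN_PER_CM2 * series.di_um / (2.0 * wt)
    )
    return strain, stress


def fit_beta(strain: np.ndarray, stress: np.ndarray) -> BetaFit:
    """Log-linear least squares of ``ln sigma = ln sigma_orig + beta*eps``.

    The log transform makes the exponential model linear and
    variance-stabilizes multiplicative noise; on noiseless exponential data
    it coincides with nonlinear least squares.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.size < 3:
        raise ValueError("need at least 3 stress-strain points")
    bad = np.nonzero(stress <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive stress at indices {bad.tolist()}")
    if np.ptp(strain) <= 0:
        raise ValueError("strain must span a positive range")
    logs = np.log(stress)
    coeffs, residuals, *_ = np.polyfit(strain, logs, 1, full=True)
    beta, log_sigma_orig = float(coeffs[0]), float(coeffs[1])
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    ss_res = float(residuals[0]) if residuals.size else 0.0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BetaFit(beta=beta, sigma_orig=float(np.exp(log_sigma_orig)), r2=r2)


def analyze_series(series: PressureDiameterSeries) -> PassiveMechanics:
    """Full passive-mechanics profile for one artery."""
    wt, wall_lumen = geometry(series)
    incr = incremental_distensibility(series)
    strain, stress = stress_strain(series)
    fit = fit_beta(strain, stress)
    return PassiveMechanics(
        pressures_mmhg=series.pressures_mmhg,
        wt_um=wt,
        wall_lumen=wall_lumen,
        incr_distensibility_pct_per_mmhg=incr,
        strain=strain,
        stress_dyn_per_cm2=stress,
        fit=fit,
    )


def read_series_csv(path) -> list[PressureDiameterSeries]:
    """Read per-animal passive pressure-diameter series from CSV.

    Expected columns: ``animal_id, pressure_mmHg, di_um, de_um``; any other
    columns become metadata.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "pressure_mmHg", "di_um", "de_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in pressure CSV: {sorted(missing)}")
    meta_cols = [c for c in df.columns if c not in required]
    out = []
    for animal, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("pressure_mmHg")
        out.append(
            PressureDiameterSeries(
                pressures_mmhg=g["pressure_mmHg"].to_numpy(float),
                di_um=g["di_um"].to_numpy(float),
                de_um=g["de_um"].to_numpy(float),
                animal_id=str(animal),
                metadata={c: str(g[c].iloc[0]) for c in meta_cols},
            )
        )
    return out
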