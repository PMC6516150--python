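"""Wire myography: diameter-tension analysis of aortic rings.

An aortic ring mounted on two wires is stretched stepwise; at each step the
internal diameter (um) and the wall tension resisting the stretch (mN/mm)
are recorded. The diameter-tension relationship is summarized by an ordinary
least-squares line: its slope is the stiffness readout (steeper = stiffer),
its zero-tension intercept gives the unloaded diameter Y0, and its
intersection with the Laplace isobar T = P*d/2 at 100 mmHg estimates the
diameter the vessel would adopt at physiological pressure. Segments whose
force channel disagrees with the acquisition software beyond a calibration
tolerance are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from vasomech.units import laplace_tension_coefficient

__all__ = [
    "WireMyoCurve",
    "WireMyoFit",
    "tension_from_force",
    "fit_diameter_tension",
    "estimate_d100",
    "qc_exclude",
    "read_curves_csv",
    "analyze_curves",
]

#: Default calibration-discrepancy threshold between the myograph unit and
#: the software, in mN (strict inequality: exactly at threshold is kept).
QC_DISCREPANCY_THRESHOLD = 5.0


@dataclass
class WireMyoCurve:
    """Stepwise diameter-tension recording from one aortic ring segment."""

    segment_id: str
    segment_length_mm: float
    diameters_um: np.ndarray
    tensions_mn_per_mm: np.ndarray
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        self.tensions_mn_per_mm = np.asarray(self.tensions_mn_per_mm, dtype=float)
        if self.diameters_um.shape != self.tensions_mn_per_mm.shape:
            raise ValueError("diameter and tension arrays differ in length")
        if self.diameters_um.size < 3:
            raise ValueError("a diameter-tension curve needs at least 3 points")
        if not np.all(np.diff(self.diameters_um) > 0):
            raise ValueError("diameters must be strictly increasing across steps")
        if not np.all(np.isfinite(self.tensions_mn_per_mm)):
            raise ValueError("tensions must be finite")
        if self.segment_length_mm <= 0:
            raise ValueError("segment length must be positive")


@dataclass(frozen=True)
class WireMyoFit:
    """OLS summary of a diameter-tension curve.

    ``y0_diameter`` (diameter at zero tension) and ``d100`` (estimated
    diameter at 100 mmHg) are NaN when the slope is non-positive, which
    signals a non-physiologic recording rather than raising.
    """

    segment_id: str
    slope: float  # mN/mm per um
    intercept: float  # mN/mm
    y0_diameter: float  # um
    d100: float  # um
    r2: float
    metadata: Mapping[str, str] = field(default_factory=dict)

    @property
    def physiologic(self) -> bool:
        return self.slope > 0 and math.isfinite(self.d100)


def tension_from_force(force_mn: float, segment_length_mm: float) -> float:
    """Convert transducer force (mN) to wall tension (mN/mm).

    The load is borne by the two wall strips above and below the wires, so
    tension per unit length of one strip is ``F / (2 L)``.
    """
    if segment_length_mm <= 0:
        raise ValueError("segment length must be positive")
    return force_mn / (2.0 * segment_length_mm)


def estimate_d100(
    slope: float, intercept: float, pressure_mmhg: float = 100.0
) -> float:
    """Diameter where the fitted line crosses the Laplace isobar at P.

    Solves ``slope*d + intercept = k*d`` with ``k`` the isobar slope
    (see :func:`vasomech.units.laplace_tension_coefficient`).

    Raises
    ------
    ValueError
        If the fitted line is parallel to the isobar or the intersection is
        non-positive (no physically meaningful diameter).
    """
    k = laplace_tension_coefficient(pressure_mmhg)
    denom = k - slope
    if denom == 0:
        raise ValueError(
            f"fitted line is parallel to the {pressure_mmhg} mmHg Laplace isobar"
        )
    d = intercept / denom
    if d <= 0:
        raise ValueError(
            f"isobar intersection at {d:.3g} um is non-positive; "
            "diameter undefined"
        )
    return d


def fit_diameter_tension(curve: WireMyoCurve, pressure_mmhg: float = 100.0) -> WireMyoFit:
    """OLS regression of wall tension on diameter, with Y0 and d100."""
    d = curve.diameters_um
    t = curve.tensions_mn_per_mm
    if np.var(d) == 0:
        raise ValueError("zero diameter variance; cannot fit")
    res = sps.linregress(d, t)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope > 0:
        y0 = -intercept / slope
        try:
            d100 = estimate_d100(slope, intercept, pressure_mmhg)
        except ValueError:
            d100 = float("nan")
    else:
        y0 = float("nan")
        d100 = float("nan")
    return WireMyoFit(
        segment_id=curve.segment_id,
        slope=slope,
        intercept=intercept,
        y0_diameter=y0,
        d100=d100,
        r2=float(res.rvalue) ** 2,
        metadata=dict(curve.metadata),
    )


def qc_exclude(
    channel_discrepancy: float, threshold: float = QC_DISCREPANCY_THRESHOLD
) -> bool:
    """True (exclude) when the myograph-vs-software discrepancy exceeds
    the calibration threshold; the boundary value itself is kept."""
    if channel_discrepancy < 0:
        raise ValueError("discrepancy must be non-negative")
    return channel_discrepancy > threshold


def read_curves_csv(path) -> list[WireMyoCurve]:
    """Read stepwise recordings from CSV.

    Expected columns: ``segment_id, segment_length_mm, step, diameter_um``
    and either ``tension_mN_per_mm`` or ``force_mN`` (converted via
    :func:`tension_from_force`). Any other columns are kept as metadata
    (first value per segment).
    """
    df = pd.read_csv(path)
    required = {"segment_id", "segment_length_mm", "diameter_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in wire CSV: {sorted(missing)}")
    has_tension = "tension_mN_per_mm" in df.columns
    if not has_tension and "force_mN" not in df.columns:
        raise ValueError("need a tension_mN_per_mm or force_mN column")
    meta_cols = [
        c
        for c in df.columns
        if c
        not in {
            "segment_id",
            "segment_length_mm",
            "step",
            "diameter_um",
            "tension_mN_per_mm",
            "force_mN",
        }
    ]
    curves = []
    for seg_id, g in df.groupby("segment_id", sort=True):
        if "step" in g.columns:
            g = g.sort_values("step")
        length = float(g["segment_length_mm"].iloc[0])
        if has_tension:
            tension = g["tension_mN_per_mm"].to_numpy(float)
        else:
            tension = np.array(
                [tension_from_force(f, length) for f in g["force_mN"].to_numpy(float)]
            )
        curves.append(
            WireMyoCurve(
                segment_id=str(seg_id),
                segment_length_mm=length,
                diameters_um=g["diameter_um"].to_numpy(float),
                tensions_mn_per_mm=tension,
                metadata={c: str(g[c].iloc[0]) for c in meta_cols},
            )
        )
    return curves


def analyze_curves(
    curves: Sequence[WireMyoCurve],
    discrepancies_mn: Mapping[str, float] | None = None,
    qc_threshold: float = QC_DISCREPANCY_THRESHOLD,
) -> pd.DataFrame:
    """Fit every segment; one row per segment with slope, Y0, d100, r2 and
    a QC flag (``excluded`` True when the channel discrepancy fails QC)."""
    rows = []
    for curve in curves:
        fit = fit_diameter_tension(curve)
        disc = (discrepancies_mn or {}).get(curve.segment_id, 0.0)
        row = {
            "segment_id": fit.segment_id,
            "slope_mN_per_mm_per_um": fit.slope,
            "intercept_mN_per_mm": fit.intercept,
            "y0_um": fit.y0_diameter,
            "d100_um": fit.d100,
            "r2": fit.r2,
            "qc_discrepancy_mN": disc,
            "excluded": qc_exclude(disc, qc_threshold),
        }
        row.update(curve.metadata)
        rows.append(row)
    return pd.DataFrame(rows)
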