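"""In vivo aortic kinetics from cine MRI and transit-time pulse wave velocity.

ECG-gated cine MRI yields a lumen-area vs time curve per animal (time zero
at the R wave). Because heart rate differs between animals, curves are
linearly interpolated onto a common 1 ms grid and truncated at 150 ms before
any derived quantity is computed. The distensibility readout is the initial
ascending slope of the area-time curve (OLS over the first 20 ms of
systole); further metrics are the incremental area (area minus the first
point), the radial strain curve ``(r(t) - r(0)) / r(0)`` with
``r = sqrt(A/pi)``, and the total strain, the time integral of the strain
curve over the 150 ms window (units: ms, since strain is dimensionless).

Transit-time pulse wave velocity (PWV) divides the aorto-femoral path
distance by the difference of the R-to-foot times measured at the ascending
aorta and the femoral artery; mm/ms equals m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaTimeCurve",
    "AortaKinetics",
    "PWVRecord",
    "resample",
    "ascending_slope",
    "strain_metrics",
    "compute_pwv",
    "foot_time_intersecting_tangent",
    "group_curve_stats",
    "read_area_csv",
    "read_pwv_csv",
]

T_MAX_MS = 150.0
SLOPE_WINDOW_MS = 20.0


@dataclass
class AreaTimeCurve:
    """Lumen area (mm^2) vs time from the ECG R wave (ms) for one slice.

    Missing samples may be encoded as NaN areas; they are dropped or filled
    from a secondary slice during :func:`resample`.
    """

    times_ms: np.ndarray
    areas_mm2: np.ndarray
    animal_id: str = ""
    slice_id: str = "upper"
    heart_period_ms: float = float("nan")
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.times_ms.shape != self.areas_mm2.shape:
            raise ValueError("time and area arrays differ in length")
        if not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("times must be strictly increasing")
        finite = np.isfinite(self.areas_mm2)
        if np.any(self.areas_mm2[finite] <= 0):
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class AortaKinetics:
    """Derived aortic distensibility metrics on the common time grid."""

    times_ms: np.ndarray
    incremental_area_mm2: np.ndarray
    strain: np.ndarray
    total_strain_ms: float
    asc_slope_mm2_per_ms: float


@dataclass(frozen=True)
class PWVRecord:
    """Transit-time PWV measurement between two arterial sites."""

    path_distance_mm: float
    t_aorta_ms: float  # R wave to foot, ascending aorta
    t_femoral_ms: float  # R wave to foot, femoral artery
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.path_distance_mm <= 0:
            raise ValueError("path distance must be positive")
        if self.t_femoral_ms <= self.t_aorta_ms:
            raise ValueError("femoral foot must arrive after the aortic foot")


def resample(
    curve: AreaTimeCurve,
    dt_ms: float = 1.0,
    t_max_ms: float = T_MAX_MS,
    fill_from: AreaTimeCurve | None = None,
) -> AreaTimeCurve:
    """Interpolate a curve onto a uniform grid truncated at ``t_max_ms``.

    NaN samples in the primary slice are first substituted with the
    time-matched value of the secondary slice (``fill_from``), then linear
    interpolation maps the merged samples onto ``0, dt, 2dt, ... <= t_max``.
    A coverage gap wider than a quarter heart period with no secondary curve
    to fill it is an error.
    """
    t = curve.times_ms.copy()
    a = curve.areas_mm2.copy()
    missing = ~np.isfinite(a)
    if missing.any() and fill_from is not None:
        sec_t, sec_a = fill_from.times_ms, fill_from.areas_mm2
        for i in np.nonzero(missing)[0]:
            j = int(np.argmin(np.abs(sec_t - t[i])))
            if np.isfinite(sec_a[j]):
                a[i] = sec_a[j]
    keep = np.isfinite(a)
    t, a = t[keep], a[keep]
    in_win = t <= t_max_ms
    if np.count_nonzero(in_win) < 2:
        raise ValueError("need at least two samples within the time window")
    if np.isfinite(curve.heart_period_ms):
        max_gap = float(np.max(np.diff(t))) if t.size > 1 else np.inf
        if max_gap > curve.heart_period_ms / 4.0 and fill_from is None:
            raise ValueError(
                f"coverage gap of {max_gap:.1f} ms exceeds a quarter heart "
                "period and no secondary slice was provided"
            )
    grid = np.arange(0.0, t_max_ms + dt_ms / 2, dt_ms)
    areas = np.interp(grid, t, a)
    return AreaTimeCurve(
        times_ms=grid,
        areas_mm2=areas,
        animal_id=curve.animal_id,
        slice_id=curve.slice_id,
        heart_period_ms=curve.heart_period_ms,
        metadata=dict(curve.metadata),
    )


def ascending_slope(
    curve: AreaTimeCurve, window_ms: float = SLOPE_WINDOW_MS
) -> float:
    """Initial systolic slope (mm^2/ms): OLS of area on time over [0, window]."""
    sel = curve.times_ms <= window_ms
    if np.count_nonzero(sel) < 3:
        raise ValueError(
            f"need at least 3 samples within the first {window_ms} ms"
        )
    coeffs = np.polyfit(curve.times_ms[sel], curve.areas_mm2[sel], 1)
    return float(coeffs[0])


def strain_metrics(curve: AreaTimeCurve, t_max_ms: float = T_MAX_MS) -> AortaKinetics:
    """Incremental area, radial strain curve, and total strain.

    The radius follows from the area assuming a circular lumen,
    ``r = sqrt(A/pi)``; total strain integrates the dimensionless strain
    over time (trapezoidal rule), so its unit is ms.
    """
    sel = curve.times_ms <= t_max_ms
    t = curve.times_ms[sel]
    a = curve.areas_mm2[sel]
    if a[0] <= 0 or np.any(a <= 0):
        raise ValueError("areas must be positive")
    r = np.sqrt(a / np.pi)
    strain = (r - r[0]) / r[0]
    incremental = a - a[0]
    total = float(np.trapezoid(strain, t))
    return AortaKinetics(
        times_ms=t,
        incremental_area_mm2=incremental,
        strain=strain,
        total_strain_ms=total,
        asc_slope_mm2_per_ms=ascending_slope(curve),
    )


def compute_pwv(record: PWVRecord) -> float:
    """Pulse wave velocity in m/s: path distance over the transit time."""
    tt = record.t_femoral_ms - record.t_aorta_ms
    if tt <= 0:
        raise ValueError("transit time must be positive")
    return record.path_distance_mm / tt  # mm/ms == m/s


def foot_time_intersecting_tangent(
    times_ms: np.ndarray, signal: np.ndarray, upstroke_frac: tuple[float, float] = (0.2, 0.8)
) -> float:
    """Experimental: foot of a pulse waveform by the intersecting-tangent
    method (baseline horizontal vs upstroke tangent).

    Provided for convenience only — R-to-foot times are normally measured
    by the operator and supplied as inputs. The upstroke tangent is fitted
    over the portion of the systolic rise between the given amplitude
    fractions; the baseline is the pre-upstroke minimum.
    """
    t = np.asarray(times_ms, float)
    y = np.asarray(signal, float)
    i_peak = int(np.argmax(y))
    if i_peak == 0:
        raise ValueError("waveform peak at first sample; no upstroke")
    i_min = int(np.argmin(y[: i_peak + 1]))
    base = y[i_min]
    amp = y[i_peak] - base
    if amp <= 0:
        raise ValueError("flat waveform; no foot")
    lo, hi = (base + upstroke_frac[0] * amp, base + upstroke_frac[1] * amp)
    sel = slice(i_min, i_peak + 1)
    mask = (y[sel] >= lo) & (y[sel] <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError("too few samples on the upstroke for a tangent")
    slope, intercept = np.polyfit(t[sel][mask], y[sel][mask], 1)
    return float((base - intercept) / slope)


def group_curve_stats(curves: Sequence[AreaTimeCurve]) -> pd.DataFrame:
    """Per-timepoint mean and SD across resampled curves (for plotting)."""
    if not curves:
        raise ValueError("no curves")
    grid = curves[0].times_ms
    for c in curves[1:]:
        if not np.array_equal(c.times_ms, grid):
            raise ValueError("curves must share a common time grid; resample first")
    stack = np.vstack([c.areas_mm2 for c in curves])
    return pd.DataFrame(
        {
            "time_ms": grid,
            "mean_mm2": stack.mean(axis=0),
            "sd_mm2": stack.std(axis=0, ddof=1) if len(curves) > 1 else 0.0,
            "n": len(curves),
        }
    )


def read_area_csv(path) -> list[AreaTimeCurve]:
    """Read MRI lumen-area series: ``animal_id, slice_id, time_ms, area_mm2``
    (optional ``heart_period_ms``)."""
    df = pd.read_csv(path)
    required = {"animal_id", "slice_id", "time_ms", "area_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in MRI CSV: {sorted(missing)}")
    curves = []
    for (animal, sl), g in df.groupby(["animal_id", "slice_id"], sort=True):
        g = g.sort_values("time_ms")
        period = (
            float(g["heart_period_ms"].iloc[0])
            if "heart_period_ms" in g.columns
            else float("nan")
        )
        curves.append(
            AreaTimeCurve(
                times_ms=g["time_ms"].to_numpy(float),
                areas_mm2=g["area_mm2"].to_numpy(float),
                animal_id=str(animal),
                slice_id=str(sl),
                heart_period_ms=period,
            )
        )
    return curves


def read_pwv_csv(path) -> list[PWVRecord]:
    """Read PWV records: ``animal_id, distance_mm, t_aorta_ms, t_femoral_ms``."""
    df = pd.read_csv(path)
    required = {"animal_id", "distance_mm", "t_aorta_ms", "t_femoral_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in PWV CSV: {sorted(missing)}")
    return [
        PWVRecord(
            path_distance_mm=float(r.distance_mm),
            t_aorta_ms=float(r.t_aorta_ms),
            t_femoral_ms=float(r.t_femoral_ms),
            animal_id=str(r.animal_id),
        )
        for r in df.itertuples()
    ]
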