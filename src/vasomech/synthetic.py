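"""Seeded synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here with known
parameters, so each stage supports parameter-recovery testing without the
original animals or images:

- :func:`make_pressure_series` — a passive vessel obeying the exponential
  wall model ``sigma = sigma_orig * exp(beta * eps)`` with an
  incompressible wall (constant cross-sectional area), solved for the
  equilibrium inner diameter at each pressure by bracketed root finding;
- :func:`make_wire_curve` — a linear diameter-tension recording;
- :func:`make_area_waveform` — a pulsatile lumen-area curve with a linear
  systolic rise of known slope and a smooth diastolic decay;
- :func:`make_fiber_image` — sinusoidal "elastin fibers" of known analytic
  rectilinearity (chord over arc length, by numerical quadrature);
- histology image builders (two-class stained sections, annular layer
  masks, planted nuclei) for the quantification module.

All generators take explicit integer seeds and never touch global RNG
state; identical seeds and parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from vasomech.hemodynamics import AreaTimeCurve, PWVRecord
from vasomech.pressure import (
    DEFAULT_PRESSURES_MMHG,
    PressureDiameterSeries,
)
from vasomech.units import MMHG_TO_DYN_PER_CM2
from vasomech.wire import WireMyoCurve

__all__ = [
    "VesselModel",
    "FiberSpec",
    "GenerationError",
    "make_pressure_series",
    "make_wire_curve",
    "make_area_waveform",
    "make_pwv_record",
    "make_fiber_image",
    "sine_rectilinearity",
    "make_two_class_image",
    "make_annulus_masks",
    "make_nuclei_image",
]


class GenerationError(RuntimeError):
    """A generator could not produce self-consistent data."""


@dataclass(frozen=True)
class VesselModel:
    """Ground-truth passive vessel for pressure-myography emulation.

    The wall obeys ``sigma = sigma_orig * exp(beta * eps)`` with strain
    ``eps = (Di - d00)/d00`` referenced to ``d00``, the inner diameter at
    3 mmHg. The wall cross-sectional area is constant across pressures
    (incompressible wall), so the wall thickness at inner diameter Di is
    ``WT(Di) = (sqrt(Di^2 + 4*A/pi) - Di)/2``.

    ``sigma_orig=None`` (recommended) derives the unloaded stress from the
    3 mmHg force balance, which places d00 exactly at the 3 mmHg
    equilibrium and makes the noiseless series an exact round trip through
    the analysis formulas. An explicit ``sigma_orig`` is honoured as given;
    if it is inconsistent with the 3 mmHg force balance, the generated
    3 mmHg diameter (the analysis' strain reference) shifts away from
    ``d00`` accordingly.
    """

    d00_um: float = 200.0
    wall_csa_um2: float = 30_000.0
    beta: float = 5.0
    sigma_orig: float | None = None
    noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d00_um <= 0 or self.wall_csa_um2 <= 0 or self.beta <= 0:
            raise ValueError("d00, wall_csa and beta must be positive")
        if self.sigma_orig is not None and self.sigma_orig <= 0:
            raise ValueError("sigma_orig must be positive")

    def wall_thickness_um(self, di_um: float | np.ndarray) -> float | np.ndarray:
        return (np.sqrt(di_um**2 + 4.0 * self.wall_csa_um2 / np.pi) - di_um) / 2.0

    def resolved_sigma_orig(self) -> float:
        """The stress at d00, derived at 3 mmHg when not set explicitly."""
        if self.sigma_orig is not None:
            return self.sigma_orig
        wt = self.wall_thickness_um(self.d00_um)
        return 3.0 * MMHG_TO_DYN_PER_CM2 * self.d00_um / (2.0 * wt)

    def equilibrium_diameter_um(self, pressure_mmhg: float) -> float:
        """Inner diameter solving wall-model stress == Laplace stress at P."""
        sigma0 = self.resolved_sigma_orig()
        p_dyn = pressure_mmhg * MMHG_TO_DYN_PER_CM2

        def imbalance(di: float) -> float:
            eps = (di - self.d00_um) / self.d00_um
            laplace = p_dyn * di / (2.0 * self.wall_thickness_um(di))
            return sigma0 * np.exp(self.beta * eps) - laplace

        lo, hi = self.d00_um, 10.0 * self.d00_um
        f_lo = imbalance(lo)
        if abs(f_lo) < 1e-9 * sigma0:
            return lo
        if f_lo * imbalance(hi) > 0:
            raise GenerationError(
                f"equilibrium root not bracketed in ({lo:.3g}, {hi:.3g}) um "
                f"at P={pressure_mmhg} mmHg (beta={self.beta}, "
                f"sigma_orig={sigma0:.3g} dyn/cm^2)"
            )
        return float(brentq(imbalance, lo, hi, xtol=1e-6))


def make_pressure_series(
    model: VesselModel,
    pressures_mmhg: tuple[float, ...] = DEFAULT_PRESSURES_MMHG,
    animal_id: str = "synthetic",
) -> PressureDiameterSeries:
    """Generate a passive pressure-diameter series from a vessel model.

    For each pressure the equilibrium inner diameter is found by bracketed
    root finding; the outer diameter follows from wall incompressibility.
    Gaussian noise of sd ``model.noise_sd_um`` is added independently to
    both diameter channels.
    """
    pressures = np.asarray(pressures_mmhg, dtype=float)
    if not np.all(np.diff(pressures) > 0) or not np.isclose(pressures[0], 3.0):
        raise ValueError("pressures must be strictly increasing and start at 3 mmHg")
    di = np.array([model.equilibrium_diameter_um(p) for p in pressures])
    de = di + 2.0 * model.wall_thickness_um(di)
    if model.noise_sd_um > 0:
        rng = np.random.default_rng(model.seed)
        di = di + rng.normal(0.0, model.noise_sd_um, di.shape)
        de = de + rng.normal(0.0, model.noise_sd_um, de.shape)
    return PressureDiameterSeries(
        pressures_mmhg=pressures, di_um=di, de_um=de, animal_id=animal_id
    )


def make_wire_curve(
    slope: float,
    y0_um: float,
    n_steps: int = 10,
    step_um: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    segment_id: str = "synthetic",
    segment_length_mm: float = 2.0,
) -> WireMyoCurve:
    """Linear diameter-tension recording: ``T = slope*(d - y0) + noise``.

    Diameters are equally spaced above ``y0_um``; slope in mN/mm per um.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if n_steps < 3:
        raise ValueError("need at least 3 steps")
    d = y0_um + step_um * np.arange(1, n_steps + 1, dtype=float)
    t = slope * (d - y0_um)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        t = t + rng.normal(0.0, noise_sd, t.shape)
    return WireMyoCurve(
        segment_id=segment_id,
        segment_length_mm=segment_length_mm,
        diameters_um=d,
        tensions_mn_per_mm=t,
    )


def make_area_waveform(
    a_dia_mm2: float = 1.0,
    a_sys_mm2: float = 1.2,
    rise_ms: float = 20.0,
    period_ms: float = 180.0,
    n_samples: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    animal_id: str = "synthetic",
    slice_id: str = "upper",
) -> AreaTimeCurve:
    """Pulsatile lumen-area curve with known initial slope.

    A linear rise from diastolic to systolic area over ``rise_ms`` (true
    ascending slope ``(a_sys - a_dia)/rise_ms``) followed by a smooth
    half-cosine decay back to the diastolic level by end of cycle.
    """
    if a_sys_mm2 < a_dia_mm2:
        raise ValueError("systolic area must be >= diastolic area")
    if rise_ms < 20.0:
        raise ValueError("rise time must be at least 20 ms")
    times = np.linspace(0.0, period_ms, n_samples, endpoint=False)
    amp = a_sys_mm2 - a_dia_mm2
    areas = np.empty_like(times)
    rising = times <= rise_ms
    areas[rising] = a_dia_mm2 + amp * times[rising] / rise_ms
    tau = (times[~rising] - rise_ms) / (period_ms - rise_ms)
    areas[~rising] = a_dia_mm2 + amp * (1.0 + np.cos(np.pi * tau)) / 2.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        areas = areas + rng.normal(0.0, noise_sd, areas.shape)
        areas = np.clip(areas, 1e-6, None)
    return AreaTimeCurve(
        times_ms=times,
        areas_mm2=areas,
        animal_id=animal_id,
        slice_id=slice_id,
        heart_period_ms=period_ms,
    )


def make_pwv_record(
    pwv_m_per_s: float,
    path_distance_mm: float = 40.0,
    t_aorta_ms: float = 4.0,
    animal_id: str = "synthetic",
) -> PWVRecord:
    """PWV record with the transit time implied by a target velocity."""
    if pwv_m_per_s <= 0:
        raise ValueError("target PWV must be positive")
    tt = path_distance_mm / pwv_m_per_s  # mm / (m/s) = ms
    return PWVRecord(
        path_distance_mm=path_distance_mm,
        t_aorta_ms=t_aorta_ms,
        t_femoral_ms=t_aorta_ms + tt,
        animal_id=animal_id,
    )


@dataclass(frozen=True)
class FiberSpec:
    """Sinusoidal-fiber image specification with analytic ground truth."""

    amplitude_um: float = 10.0
    wavelength_um: float = 60.0
    thickness_px: int = 3
    n_fibers: int = 5
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be >= 0")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")


def sine_rectilinearity(
    amplitude_um: float, wavelength_um: float, span_um: float
) -> float:
    """Analytic chord/arc-length ratio of ``y = a sin(2 pi x / lambda)``
    over a horizontal span, by numerical quadrature.

    For amplitude 0 this is exactly 1; for ``a = lambda/(2 pi)`` (unit peak
    slope) it is about 0.822.
    """
    if amplitude_um == 0:
        return 1.0
    k = 2.0 * np.pi / wavelength_um
    arc, _ = quad(
        lambda x: np.sqrt(1.0 + (amplitude_um * k * np.cos(k * x)) ** 2),
        0.0,
        span_um,
        limit=400,
    )
    chord = np.hypot(
        span_um, amplitude_um * (np.sin(k * span_um) - np.sin(0.0))
    )
    return float(chord / arc)


def make_fiber_image(spec: FiberSpec) -> tuple[np.ndarray, list[float], bool]:
    """Draw wavy fibers of known rectilinearity on a noisy background.

    Each fiber is a full-width sinusoid ``y = y0 + a sin(2 pi x/lambda +
    phase)`` drawn as a polyline of the requested thickness; fibers are
    stacked at distinct vertical offsets with random phases. Background is
    additive Gaussian noise with sd = foreground/snr.

    Returns ``(image float in [0, ~1], per-fiber ground-truth
    rectilinearity, overlap_flag)``. Fibers that would overlap are allowed
    but flagged.
    """
    h, w = spec.image_shape
    a_px = spec.amplitude_um / spec.pixel_size_um
    margin = a_px + spec.thickness_px + 2
    if 2 * margin >= h:
        raise ValueError("fibers do not fit inside the image with margin")
    rng = np.random.default_rng(spec.seed)
    offsets = np.linspace(margin, h - margin, spec.n_fibers)
    lane = (h - 2 * margin) / max(spec.n_fibers - 1, 1) if spec.n_fibers > 1 else h
    overlap = spec.n_fibers > 1 and lane < 2 * (a_px + spec.thickness_px)
    canvas = np.zeros((h, w), dtype=bool)
    truths = []
    k = 2.0 * np.pi / (spec.wavelength_um / spec.pixel_size_um)
    for y0 in offsets:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        xs = np.arange(w)
        ys = y0 + a_px * np.sin(k * xs + phase)
        ys_px = np.clip(np.round(ys).astype(int), 0, h - 1)
        for i in range(w - 1):
            rr, cc = draw_line(ys_px[i], xs[i], ys_px[i + 1], xs[i + 1])
            canvas[rr, cc] = True
        # analytic truth over the drawn span, phase-shifted sine
        span_um = (w - 1) * spec.pixel_size_um
        k_um = 2.0 * np.pi / spec.wavelength_um
        if spec.amplitude_um == 0:
            truths.append(1.0)
        else:
            arc, _ = quad(
                lambda x: np.sqrt(
                    1.0 + (spec.amplitude_um * k_um * np.cos(k_um * x + phase)) ** 2
                ),
                0.0,
                span_um,
                limit=400,
            )
            chord = np.hypot(
                span_um,
                spec.amplitude_um
                * (np.sin(k_um * span_um + phase) - np.sin(phase)),
            )
            truths.append(float(chord / arc))
    if spec.thickness_px > 1:
        canvas = dilation(canvas, disk(spec.thickness_px // 2))
    fg = 1.0
    img = canvas.astype(float) * fg
    img = img + rng.normal(0.0, fg / spec.snr, img.shape)
    return img, truths, overlap


def make_two_class_image(
    frac_class_a: float,
    hue_a_deg: float,
    hue_b_deg: float,
    shape: tuple[int, int] = (128, 128),
    hue_jitter_deg: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """RGB image whose pixels belong to two hue classes in known proportion.

    Used as ground truth for trichrome and polarized picrosirius
    quantification: a fraction ``frac_class_a`` of pixels get hue A (with
    Gaussian jitter), the rest hue B; saturation and value are fixed high.
    """
    if not 0.0 <= frac_class_a <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    n_a = int(round(frac_class_a * n))
    hues = np.full(n, hue_b_deg, dtype=float)
    idx = rng.permutation(n)[:n_a]
    hues[idx] = hue_a_deg
    hues = hues + rng.normal(0.0, hue_jitter_deg, n)
    hsv = np.stack(
        [
            (hues % 360.0) / 360.0,
            np.full(n, 0.9),
            np.full(n, 0.9),
        ],
        axis=-1,
    ).reshape(*shape, 3)
    from skimage.color import hsv2rgb

    return hsv2rgb(hsv)


def make_annulus_masks(
    inner_radius_um: float,
    outer_radius_um: float,
    pixel_size_um: float = 1.0,
    pad_px: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """(media_mask, lumen_mask) for a circular vessel cross-section."""
    if not 0 < inner_radius_um < outer_radius_um:
        raise ValueError("need 0 < inner radius < outer radius")
    r_out = outer_radius_um / pixel_size_um
    size = int(np.ceil(2 * r_out)) + 2 * pad_px
    center = (size / 2.0, size / 2.0)
    lumen = np.zeros((size, size), dtype=bool)
    outer = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk(center, inner_radius_um / pixel_size_um, shape=lumen.shape)
    lumen[rr, cc] = True
    rr, cc = draw_disk(center, r_out, shape=outer.shape)
    outer[rr, cc] = True
    return outer & ~lumen, lumen


def make_nuclei_image(
    n_nuclei: int,
    radius_px: int = 4,
    shape: tuple[int, int] = (128, 128),
    intensity: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Grayscale image with ``n_nuclei`` disjoint bright disks."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 10_000:
            raise GenerationError("could not place disjoint nuclei")
        r = rng.integers(radius_px + 2, shape[0] - radius_px - 2)
        c = rng.integers(radius_px + 2, shape[1] - radius_px - 2)
        if all(np.hypot(r - r0, c - c0) > 2.5 * radius_px for r0, c0 in centers):
            centers.append((int(r), int(c)))
    for r0, c0 in centers:
        rr, cc = draw_disk((r0, c0), radius_px, shape=shape)
        img[rr, cc] = intensity
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    return np.clip(img, 0.0, None)
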