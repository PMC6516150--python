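"""Stained-section quantification of the arterial wall.

Covers the image-derived readouts of wall composition and morphometry:

- **Masson's trichrome** area fractions in the medial layer — collagen
  stains green, vascular smooth muscle red; both are expressed as a
  percentage of the medial area (they need not sum to 100).
- **Morphometry** — medial thickness and lumen perimeter from layer masks.
- **Picrosirius red under polarized light** — birefringent collagen
  bundles classified by hue: dense/thick bundles appear yellow-orange,
  thin bundles green; quantified in the adventitia, the only layer where
  birefringent bundles are detected.
- **Immunofluorescence intensity** — mean intensity in a region, or (for
  channels with diffuse background) the Kapur maximum-entropy threshold to
  select positive pixels followed by integrated density; either readout is
  normalized to the median of a designated control group.
- **Second-harmonic generation texture** — amount and density of the
  collagen signal plus Pearson kurtosis and skewness of the intensity
  distribution (a normal distribution has kurtosis 3 and skewness 0).
- **Nuclei counts** from the DAPI channel.

Hue bands and saturation/value floors are configurable; the defaults are
stated in degrees on the HSV circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "HueBands",
    "PicrosiriusClasses",
    "ShgTexture",
    "hue_mask",
    "trichrome_fractions",
    "media_morphometry",
    "picrosirius_classes",
    "maxent_threshold",
    "if_intensity",
    "normalize_to_control",
    "shg_texture",
    "count_nuclei",
]

SAT_FLOOR = 0.15
VAL_FLOOR = 0.15


@dataclass(frozen=True)
class HueBands:
    """Hue windows in degrees on the HSV circle, with chroma floors.

    Red wraps around zero, so it is a union of two windows.
    """

    red: tuple[tuple[float, float], ...] = ((0.0, 30.0), (330.0, 360.0))
    green: tuple[tuple[float, float], ...] = ((70.0, 170.0),)
    orange: tuple[tuple[float, float], ...] = ((20.0, 60.0),)
    sat_floor: float = SAT_FLOOR
    val_floor: float = VAL_FLOOR


DEFAULT_BANDS = HueBands()


@dataclass(frozen=True)
class PicrosiriusClasses:
    """Polarized-light collagen classes within the analyzed layer."""

    pct_orange_thick: float
    pct_green_thin: float
    birefringent_area_um2: float


@dataclass(frozen=True)
class ShgTexture:
    signal_area_px: int
    density: float  # mean supra-threshold intensity
    kurtosis: float  # Pearson; normal distribution -> 3
    skewness: float


def _hsv(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if img.dtype != np.float64 and img.dtype != np.float32:
        img = img.astype(float) / np.iinfo(img.dtype).max
    return color.rgb2hsv(img)


def hue_mask(
    img: np.ndarray,
    windows: tuple[tuple[float, float], ...],
    sat_floor: float = SAT_FLOOR,
    val_floor: float = VAL_FLOOR,
) -> np.ndarray:
    """Pixels whose hue (degrees) falls in any window, above chroma floors."""
    hsv = _hsv(img)
    hue_deg = hsv[..., 0] * 360.0
    sel = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in windows:
        sel |= (hue_deg >= lo) & (hue_deg <= hi)
    return sel & (hsv[..., 1] >= sat_floor) & (hsv[..., 2] >= val_floor)


def trichrome_fractions(
    img: np.ndarray, media_mask: np.ndarray, bands: HueBands = DEFAULT_BANDS
) -> tuple[float, float]:
    """(%collagen, %muscle) of the medial area in a trichrome section.

    Green pixels are counted as collagen and red pixels as smooth muscle,
    each as a percentage of the media mask area.
    """
    media_mask = np.asarray(media_mask, dtype=bool)
    n_media = int(media_mask.sum())
    if n_media == 0:
        raise ValueError("empty media mask")
    green = hue_mask(img, bands.green, bands.sat_floor, bands.val_floor)
    red = hue_mask(img, bands.red, bands.sat_floor, bands.val_floor)
    pct_collagen = 100.0 * np.count_nonzero(green & media_mask) / n_media
    pct_muscle = 100.0 * np.count_nonzero(red & media_mask) / n_media
    return pct_collagen, pct_muscle


def _contour_length_px(mask: np.ndarray, subsample: int = 5) -> float:
    """Length of the longest iso-contour of a binary mask.

    The marching-squares contour is subsampled into an inscribed polygon
    before measuring, which removes the stair-step overestimate of pixelated
    boundaries (closed polygon, so the wrap-around segment is included).
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    contour = max(contours, key=len)
    pts = contour[:: max(1, subsample)]
    if not np.array_equal(pts[-1], contour[-1]):
        pts = np.vstack([pts, contour[-1]])
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


def media_morphometry(
    media_mask: np.ndarray, lumen_mask: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float]:
    """(media thickness um, lumen perimeter um) from layer masks.

    The lumen perimeter is the marching-contour length of the lumen
    boundary. Media thickness is the media area divided by the midline
    length, with the midline approximated by the mean of the inner (lumen)
    and outer (media+lumen hull) contour lengths — robust to irregular
    sections compared with per-ray measurements.
    """
    media_mask = np.asarray(media_mask, dtype=bool)
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    n_lumen_parts = measure.label(lumen_mask, connectivity=2).max()
    if n_lumen_parts != 1:
        raise ValueError(f"lumen must be a single component, found {n_lumen_parts}")
    inner_len = _contour_length_px(lumen_mask)
    outer_len = _contour_length_px(media_mask | lumen_mask)
    midline = (inner_len + outer_len) / 2.0
    area_px = float(media_mask.sum())
    thickness = area_px / midline * pixel_size_um
    return thickness, inner_len * pixel_size_um


def picrosirius_classes(
    img: np.ndarray,
    adventitia_mask: np.ndarray,
    pixel_size_um: float = 1.0,
    bands: HueBands = DEFAULT_BANDS,
) -> PicrosiriusClasses:
    """Classify birefringent collagen by hue within the adventitia.

    Percentages are of the adventitia mask area; the total birefringent
    area (orange plus green pixels) is returned in um^2.
    """
    adventitia_mask = np.asarray(adventitia_mask, dtype=bool)
    n = int(adventitia_mask.sum())
    if n == 0:
        raise ValueError("empty adventitia mask")
    orange = hue_mask(img, bands.orange, bands.sat_floor, bands.val_floor) & adventitia_mask
    green = hue_mask(img, bands.green, bands.sat_floor, bands.val_floor) & adventitia_mask
    total_px = np.count_nonzero(orange | green)
    return PicrosiriusClasses(
        pct_orange_thick=100.0 * np.count_nonzero(orange) / n,
        pct_green_thin=100.0 * np.count_nonzero(green) / n,
        birefringent_area_um2=total_px * pixel_size_um**2,
    )


def maxent_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Kapur maximum-entropy threshold of an intensity sample.

    The histogram is split at a candidate threshold t; the Shannon
    entropies of the normalized sub- and supra-threshold class histograms
    are summed, and the t maximizing that sum is returned (as the upper
    edge value of bin t: pixels strictly above are "positive"). Ties take
    the lowest threshold.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("single-valued histogram: threshold undefined")
    if np.issubdtype(values.dtype, np.integer) and vmax - vmin + 1 <= nbins:
        edges = np.arange(vmin - 0.5, vmax + 1.5)
    else:
        edges = np.linspace(vmin, vmax, nbins + 1)
    counts, edges = np.histogram(values, bins=edges)
    p = counts / counts.sum()
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]
    # candidate t splits classes {0..t} / {t+1..}; both must be non-empty
    cp = cum_p[:-1]
    valid = (cp > 0) & (cp < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_below = np.log(cp) - cum_plogp[:-1] / cp
        h_above = np.log(1 - cp) - (total_plogp - cum_plogp[:-1]) / (1 - cp)
    h_total = np.where(valid, h_below + h_above, -np.inf)
    t = int(np.argmax(h_total))
    # threshold value: upper edge of bin t
    return float(edges[t + 1])


def if_intensity(
    img: np.ndarray, roi_mask: np.ndarray, mode: str = "mean"
) -> float:
    """Raw immunofluorescence readout inside a region of interest.

    ``mode="mean"``: mean intensity. ``mode="maxent"``: Kapur
    maximum-entropy threshold on the in-mask histogram, then integrated
    density (sum of intensities over supra-threshold pixels). Normalize to
    the control group afterwards with :func:`normalize_to_control`.
    """
    img = np.asarray(img, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = img[roi_mask]
    if vals.size == 0:
        raise ValueError("empty region of interest")
    if mode == "mean":
        return float(vals.mean())
    if mode == "maxent":
        t = maxent_threshold(vals)
        return float(vals[vals > t].sum())
    raise ValueError("mode must be 'mean' or 'maxent'")


def normalize_to_control(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    control_label: str,
) -> np.ndarray:
    """Divide every value by the median of the control group.

    By construction the median of the normalized control group is exactly 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ctrl = values[groups == control_label]
    if ctrl.size == 0:
        raise ValueError(f"no values for control group {control_label!r}")
    med = float(np.median(ctrl))
    if med == 0:
        raise ValueError("control median is zero; cannot normalize")
    return values / med


def shg_texture(
    img: np.ndarray, mask: np.ndarray | None = None, threshold: float | None = None
) -> ShgTexture:
    """Second-harmonic generation signal amount, density and histogram shape.

    Kurtosis and skewness are the Pearson central-moment ratios
    ``m4/m2^2`` (normal -> 3) and ``m3/m2^1.5`` (symmetric -> 0) of the
    in-mask intensity histogram. ``signal_area_px`` counts supra-threshold
    pixels and ``density`` is their mean intensity; when no threshold is
    given the maximum-entropy threshold is used.
    """
    img = np.asarray(img, dtype=float)
    vals = img[np.asarray(mask, dtype=bool)] if mask is not None else img.ravel()
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("need at least two distinct intensity values")
    m = vals.mean()
    m2 = np.mean((vals - m) ** 2)
    if m2 == 0:
        raise ValueError("zero intensity variance")
    m3 = np.mean((vals - m) ** 3)
    m4 = np.mean((vals - m) ** 4)
    if threshold is None:
        threshold = maxent_threshold(vals)
    signal = vals[vals > threshold]
    return ShgTexture(
        signal_area_px=int(signal.size),
        density=float(signal.mean()) if signal.size else 0.0,
        kurtosis=float(m4 / m2**2),
        skewness=float(m3 / m2**1.5),
    )


def count_nuclei(
    dapi_img: np.ndarray,
    mask: np.ndarray | None = None,
    min_area_px: int = 20,
    split_touching: bool = False,
) -> int:
    """Count DAPI-stained nuclei: Otsu threshold, size filter, components.

    ``split_touching=True`` adds a distance-transform watershed to separate
    touching nuclei.
    """
    img = np.asarray(dapi_img, dtype=float)
    if mask is not None:
        work = np.where(np.asarray(mask, dtype=bool), img, 0.0)
    else:
        work = img
    if work.max() == work.min():
        return 0
    binary = work > filters.threshold_otsu(work)
    binary = morphology.remove_small_objects(binary, max_size=min_area_px - 1)
    if not binary.any():
        return 0
    if split_touching:
        distance = ndimage.distance_transform_edt(binary)
        peaks = peak_local_max(
            distance, labels=binary, min_distance=3, exclude_border=False
        )
        markers = np.zeros(binary.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers = morphology.dilation(markers, morphology.disk(1))
        labels = segmentation.watershed(-distance, markers, mask=binary)
        return int(len(np.unique(labels)) - (1 if 0 in labels else 0))
    return int(measure.label(binary, connectivity=2).max())
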