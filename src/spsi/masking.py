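"""Background removal: classify pixels as wheat (green) vs background.

Two criteria are thresholded jointly: reflectance in the green band (530 nm)
and the visible atmospherically resistant index

    VARI = (R530 - R675) / (R530 + R675 - R450),

which is sensitive to vegetation fraction and suppresses soil.  A pixel is
wheat iff it is valid and exceeds both thresholds strictly (default
combination rule ``and``; ``or`` is available for sensitivity studies).
Default thresholds 0.063 (green band) and 0.08 (VARI) suit a reflectance-
calibrated scene; they are per-scene parameters in practice because canopy
brightness drifts across dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import PlotROI, ReflectanceImage, roi_pixel_mask

__all__ = ["GreenMask", "compute_vari", "build_green_mask", "mask_summary"]

DEFAULT_T_GREEN = 0.063
DEFAULT_T_VARI = 0.08


@dataclass(frozen=True)
class GreenMask:
    """Per-pixel wheat/background classification with its thresholds."""

    mask: np.ndarray          # 2-D bool, True = wheat pixel
    t_green: float
    t_vari: float
    rule: str = "and"


def compute_vari(image: ReflectanceImage) -> np.ndarray:
    """Per-pixel VARI raster; NaN where the denominator is zero or invalid."""
    blue = image.band(450.0)
    green = image.band(530.0)
    red = image.band(675.0)
    denom = green + red - blue
    with np.errstate(divide="ignore", invalid="ignore"):
        vari = np.where(denom != 0, (green - red) / denom, np.nan)
    vari[~image.valid] = np.nan
    return vari


def build_green_mask(image: ReflectanceImage,
                     t_green: float = DEFAULT_T_GREEN,
                     t_vari: float = DEFAULT_T_VARI,
                     rule: str = "and") -> GreenMask:
    """Threshold the green band and VARI into a wheat mask.

    Strict inequalities: a pixel exactly at a threshold is background.
    """
    if not (np.isfinite(t_green) and np.isfinite(t_vari)):
        raise ValueError("thresholds must be finite")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    green_ok = image.band(530.0) > t_green
    vari = compute_vari(image)
    with np.errstate(invalid="ignore"):
        vari_ok = vari > t_vari          # NaN compares False
    combined = (green_ok & vari_ok) if rule == "and" else (green_ok | vari_ok)
    return GreenMask(combined & image.valid, t_green, t_vari, rule)


def mask_summary(mask: GreenMask, roi: PlotROI, image: ReflectanceImage) -> float:
    """Fraction of in-ROI valid pixels classified as wheat; NaN if none."""
    sel = roi_pixel_mask(roi, image.transform, image.shape) & image.valid
    n = int(sel.sum())
    if n == 0:
        return float("nan")
    return float(mask.mask[sel].sum()) / n
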