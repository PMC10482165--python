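"""Windowed gray-level co-occurrence matrix (GLCM) texture engine.

Per band the raster is min-max quantized to a fixed number of gray levels
over the eligible pixels of the whole scene (global quantization, so all
windows share one gray scale), then a small window slides over every pixel
whose window fits inside the raster.  Within each window, pixel pairs at a
fixed offset are accumulated into a normalized co-occurrence matrix and the
eight standard Haralick/Conners features are evaluated:

    MEA = sum_ij i P_ij                     (gray-level mean, level units)
    VAR = sum_ij (i - MEA)^2 P_ij
    HOM = sum_ij P_ij / (1 + (i - j)^2)     (homogeneity / IDM)
    CON = sum_ij (i - j)^2 P_ij             (contrast)
    DIS = sum_ij |i - j| P_ij               (dissimilarity)
    ENT = -sum_ij P_ij ln P_ij              (entropy, 0 ln 0 = 0)
    SEM = sum_ij P_ij^2                     (angular second moment)
    COR = sum_ij (i - mu_i)(j - mu_j) P_ij / (sigma_i sigma_j)

COR is missing where sigma_i sigma_j vanishes (uniform window).

Offset convention: angle 0 is (0, +1) (rightwards), 45 is (-1, +1)
(up-right), 90 is (-1, 0), 135 is (-1, -1), each scaled by the pixel
distance.  With ``symmetric=True`` every pair is accumulated in both
orders.  In masked (green-pixel) mode, background pixels are excluded both
from the quantization statistics and from co-occurrence: a pair counts only
if both of its pixels are green.  Windows with no countable pair produce
missing texture.  Windows are never padded: border pixels of half-window
width are invalid.

The sliding evaluation is vectorized: for the default 3x3 window at
distance 1 each centre owns at most four pair origins, gathered as shifted
array slices, and all eight features are computed from those per-centre
pair lists without materializing per-window matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bands import BandSet
from .raster import GeoTransform, PlotROI, ReflectanceImage, roi_pixel_mask

__all__ = [
    "FEATURES",
    "GlcmConfig",
    "TextureCube",
    "TextureStats",
    "quantize",
    "glcm_window",
    "glcm_features",
    "sliding_features",
    "texture_image",
    "zonal_texture",
    "texture_table",
]

FEATURES: tuple[str, ...] = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEM", "COR")

#: angle (degrees) -> unit (drow, dcol) offset
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: quantization sentinel for ineligible pixels
QUANT_SENTINEL = -1

_COR_VAR_EPS = 1e-20   # sigma_i * sigma_j below this is treated as zero


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM configuration.

    Defaults follow common practice for centimetre-scale canopy imagery:
    the smallest (3x3) window with 1-pixel distance keeps texture local to
    the leaf scale, 45 degrees matches a south-north row orientation, and
    64 gray levels avoid sparse matrices.
    """

    window: int = 3
    distance: int = 1
    angle: int = 45
    levels: int = 64
    symmetric: bool = True
    masked: bool = False
    clip_percentiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.angle not in _ANGLE_OFFSETS:
            raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = _ANGLE_OFFSETS[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass
class TextureCube:
    """Per-band, per-feature texture rasters ([band, feature, row, col])."""

    values: np.ndarray
    features: tuple[str, ...]
    bands: BandSet
    transform: GeoTransform = field(default_factory=GeoTransform)
    pixel_mode: str = "all"

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def plane(self, wavelength: float, feature: str) -> np.ndarray:
        b = self.bands.index_of(wavelength)
        return self.values[b, self.features.index(feature)]


@dataclass(frozen=True)
class TextureStats:
    """Zonal texture summary for one plot: (wavelength, feature) -> mean."""

    plot_id: str
    values: Mapping[tuple[float, str], float]
    pixel_mode: str = "all"

    def get(self, wavelength: float, feature: str) -> float:
        for (wl, feat), val in self.values.items():
            if feat == feature and abs(wl - wavelength) <= 15.0:
                return float(val)
        raise KeyError(f"no {feature} value near {wavelength} nm")


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(band_image: np.ndarray, valid: np.ndarray, levels: int,
             clip_percentiles: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max quantize a band to integer levels in [0, levels-1].

    ``level = floor((x - min) / (max - min) * levels)`` clamped to
    ``levels - 1``; the min/max are taken over valid pixels of the whole
    raster (optionally percentile-clipped).  A constant image maps to level
    0 everywhere.  Ineligible pixels carry the sentinel -1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    x = np.asarray(band_image, dtype=float)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if not valid.any():
        raise ValueError("quantize: no valid pixels")
    sample = x[valid]
    if clip_percentiles is not None:
        lo, hi = np.percentile(sample, clip_percentiles)
    else:
        lo, hi = float(sample.min()), float(sample.max())
    q = np.full(x.shape, QUANT_SENTINEL, dtype=np.int64)
    if hi == lo:
        q[valid] = 0
        return q
    scaled = np.floor((x[valid] - lo) / (hi - lo) * levels)
    q[valid] = np.clip(scaled, 0, levels - 1).astype(np.int64)
    return q


# ---------------------------------------------------------------------------
# single-window GLCM (reference-style path, also used by the CLI on demand)
# ---------------------------------------------------------------------------

def glcm_window(q: np.ndarray, valid: np.ndarray,
                cfg: GlcmConfig) -> np.ndarray | None:
    """Normalized co-occurrence matrix of one window; None if no pair.

    ``q`` is a quantized ``cfg.window``-sized square; ``valid`` marks the
    pixels eligible for pairing (both ends of a pair must be valid).
    """
    q = np.asarray(q)
    valid = np.asarray(valid, dtype=bool) & (q != QUANT_SENTINEL)
    if q.shape != (cfg.window, cfg.window):
        raise ValueError("window shape mismatch")
    dr, dc = cfg.offset
    P = np.zeros((cfg.levels, cfg.levels), dtype=float)
    n = 0
    for r in range(cfg.window):
        for c in range(cfg.window):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < cfg.window and 0 <= c2 < cfg.window):
                continue
            if not (valid[r, c] and valid[r2, c2]):
                continue
            P[q[r, c], q[r2, c2]] += 1.0
            if cfg.symmetric:
                P[q[r2, c2], q[r, c]] += 1.0
            n += 1
    if n == 0:
        return None
    return P / P.sum()


def glcm_features(P: np.ndarray, tol: float = 1e-8) -> dict[str, float]:
    """Evaluate the eight features on an explicit normalized GLCM."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0) or abs(P.sum() - 1.0) > tol:
        raise ValueError("P must be a normalized co-occurrence matrix")
    k = P.shape[0]
    i = np.arange(k, dtype=float)[:, None]
    j = np.arange(k, dtype=float)[None, :]
    mea = float((i * P).sum())
    var = float(((i - mea) ** 2 * P).sum())
    hom = float((P / (1.0 + (i - j) ** 2)).sum())
    con = float(((i - j) ** 2 * P).sum())
    dis = float((np.abs(i - j) * P).sum())
    nz = P[P > 0]
    ent = float(-(nz * np.log(nz)).sum())
    sem = float((P ** 2).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(k) * pi).sum())
    mu_j = float((np.arange(k) * pj).sum())
    var_i = float(((np.arange(k) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(k) - mu_j) ** 2 * pj).sum())
    if var_i * var_j <= _COR_VAR_EPS:
        cor = float("nan")
    else:
        cov = float(((i - mu_i) * (j - mu_j) * P).sum())
        cor = cov / np.sqrt(var_i * var_j)
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con,
            "DIS": dis, "ENT": ent, "SEM": sem, "COR": cor}


# ---------------------------------------------------------------------------
# sliding-window engine
# ---------------------------------------------------------------------------

def _pair_slices(q: np.ndarray, eligible: np.ndarray, cfg: GlcmConfig):
    """Per-centre pair lists as stacked shifted slices.

    Returns (I, J, OK) of shape [K, H', W'] where K is the number of pair
    origins a window can hold and (H', W') the interior centre grid, plus
    the half-window h.
    """
    h = cfg.window // 2
    dr, dc = cfg.offset
    H, W = q.shape
    Hi, Wi = H - 2 * h, W - 2 * h
    if Hi <= 0 or Wi <= 0:
        raise ValueError("raster smaller than the GLCM window")

    # pair arrays indexed by pair origin (r, c); endpoint (r+dr, c+dc)
    pi = np.full((H, W), 0, dtype=np.int64)
    pj = np.full((H, W), 0, dtype=np.int64)
    pok = np.zeros((H, W), dtype=bool)
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    pi[src] = q[src]
    pj[src] = q[dst]
    pok[src] = eligible[src] & eligible[dst]

    # relative origin offsets whose pair fits in a window centred at 0
    ro_lo, ro_hi = -h + max(0, -dr), h - max(0, dr)
    co_lo, co_hi = -h + max(0, -dc), h - max(0, dc)
    I, J, OK = [], [], []
    for ro in range(ro_lo, ro_hi + 1):
        for co in range(co_lo, co_hi + 1):
            rs = slice(h + ro, h + ro + Hi)
            cs = slice(h + co, h + co + Wi)
            I.append(pi[rs, cs])
            J.append(pj[rs, cs])
            OK.append(pok[rs, cs])
    return np.stack(I), np.stack(J), np.stack(OK), h


def _features_from_pairs(I: np.ndarray, J: np.ndarray, OK: np.ndarray,
                         cfg: GlcmConfig) -> np.ndarray:
    """All eight feature planes from per-centre pair lists ([F, H', W'])."""
    if cfg.symmetric:
        A = np.concatenate([I, J]).astype(float)
        B = np.concatenate([J, I]).astype(float)
        OK2 = np.concatenate([OK, OK])
    else:
        A, B, OK2 = I.astype(float), J.astype(float), OK
    total = OK2.sum(axis=0)
    has = total > 0
    totsafe = np.where(has, total, 1.0)
    w = OK2 / totsafe                      # per-entry probability weight

    def wsum(x):
        return (w * x).sum(axis=0)

    mea = wsum(A)
    mu_b = wsum(B)
    da, db = A - mea, B - mu_b
    var = wsum(da ** 2)
    var_b = wsum(db ** 2)
    cov = wsum(da * db)
    diff = A - B
    con = wsum(diff ** 2)
    dis = wsum(np.abs(diff))
    hom = wsum(1.0 / (1.0 + diff ** 2))

    # Cell-level sums (ENT, SEM) via O(M^2) duplicate counting of (i, j)
    # codes: an entry in a cell of count c has cell probability p = c/total,
    # so  ENT = -sum_cells p ln p = -sum_m ln(p_m)/total  and
    #     SEM =  sum_cells p^2   =  sum_m c_m/total^2.
    codes = (A * cfg.levels + B).astype(np.int64)
    codes = np.where(OK2, codes, -np.arange(1, codes.shape[0] + 1)[:, None, None])
    M = codes.shape[0]
    count = np.zeros(codes.shape, dtype=np.int64)
    for m in range(M):
        count += codes[m][None] == codes
    p_m = np.where(OK2, count, 1.0) / totsafe
    ent = -(np.log(p_m) / totsafe * OK2).sum(axis=0)
    sem = (np.where(OK2, count, 0) / totsafe ** 2).sum(axis=0)

    sig2 = var * var_b
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.where(sig2 > _COR_VAR_EPS, cov / np.sqrt(sig2), np.nan)

    out = np.stack([mea, var, hom, con, dis, ent, sem, cor])
    out[:, ~has] = np.nan
    return out


def sliding_features(q: np.ndarray, eligible: np.ndarray,
                     cfg: GlcmConfig) -> np.ndarray:
    """All eight GLCM feature planes for one quantized band.

    ``q`` is a quantized raster (sentinel -1 for ineligible pixels) and
    ``eligible`` the pixels allowed to form pairs.  Returns ``[feature,
    row, col]`` with NaN at border pixels (half-window width) and at
    centres whose window holds no countable pair.
    """
    H, W = q.shape
    I, J, OK, h = _pair_slices(q, eligible & (q != QUANT_SENTINEL), cfg)
    out = np.full((len(FEATURES), H, W), np.nan)
    out[:, h:H - h, h:W - h] = _features_from_pairs(I, J, OK, cfg)
    return out


def texture_image(image: ReflectanceImage, mask=None,
                  cfg: GlcmConfig = GlcmConfig()) -> TextureCube:
    """Sliding-window GLCM features for every band of a scene.

    In masked (green-pixel) mode ``mask`` supplies the wheat classification;
    quantization statistics and co-occurrence pairs are then restricted to
    green pixels.  Centre pixels whose window holds no countable pair - and
    all border pixels of half-window width - are missing (NaN).
    """
    from .masking import GreenMask

    if cfg.masked:
        if mask is None:
            raise ValueError("masked mode requires a GreenMask")
        green = mask.mask if isinstance(mask, GreenMask) else np.asarray(mask, bool)
        if green.shape != image.shape:
            raise ValueError("mask shape does not match image")
        eligible = image.valid & green
    else:
        eligible = image.valid

    H, W = image.shape
    cube = np.full((len(image.bands), len(FEATURES), H, W), np.nan)
    for b in range(len(image.bands)):
        q = quantize(image.pixels[b], eligible, cfg.levels, cfg.clip_percentiles)
        cube[b] = sliding_features(q, eligible, cfg)
    return TextureCube(cube, FEATURES, image.bands, image.transform,
                       "green" if cfg.masked else "all")


# ---------------------------------------------------------------------------
# zonal summaries
# ---------------------------------------------------------------------------

def zonal_texture(cube: TextureCube, roi: PlotROI) -> TextureStats:
    """ROI-mean of every (band, feature) texture plane for one plot."""
    shape = cube.values.shape[2:]
    sel = roi_pixel_mask(roi, cube.transform, shape)
    if not sel.any():
        raise ValueError(f"ROI {roi.plot_id!r} does not intersect the raster")
    values: dict[tuple[float, str], float] = {}
    for b, wl in enumerate(cube.bands.centers):
        for f, feat in enumerate(cube.features):
            plane = cube.values[b, f]
            ok = sel & np.isfinite(plane)
            values[(wl, feat)] = float(plane[ok].mean()) if ok.any() else float("nan")
    return TextureStats(roi.plot_id, values, cube.pixel_mode)


def texture_table(cube: TextureCube, rois: list[PlotROI]):
    """Per-plot zonal texture means as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for roi in rois:
        stats = zonal_texture(cube, roi)
        rec: dict = {"plot_id": roi.plot_id, "pixel_mode": stats.pixel_mode}
        for (wl, feat), val in stats.values.items():
            rec[f"T{int(round(wl))}_{feat}"] = val
        rows.append(rec)
    return pd.DataFrame(rows)
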