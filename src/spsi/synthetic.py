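"""Synthetic wheat-canopy scene generator.

Generates six-band reflectance orthomosaics with the statistical structure
the index pipeline assumes, so every stage can be exercised and validated
without field imagery:

* plots laid out on a grid, each with a latent plant density drawn from a
  common range; the trait (panicle number per unit area, x10^4/ha) follows
  a logarithmic density response plus noise;
* within each plot the canopy is drawn as north-south row stripes whose
  cover fraction increases with density; inter-row pixels are soil;
* canopy reflectance responds to density through a saturating curve
  (linear up to a knee, then exponentially flattening), so red-edge/NIR
  spectral indices lose sensitivity at high density - the spectral
  saturation the composite index exists to counter;
* within-canopy reflectance carries a spatially autocorrelated texture
  field whose NIR (850 nm) autocorrelation keeps increasing with density
  past the knee, while the red-edge (730 nm) autocorrelation stays flat
  and the visible bands fluctuate plot-to-plot independently of density.
  GLCM correlation (COR) therefore remains informative after the spectral
  signal saturates, and the (850, 730) pair is the planted optimum;
* optionally, a field-margin strip of green vegetation with an extreme
  730/850 nm value range is painted outside all ROIs.  It stretches the
  scene's global quantization range, which offsets level-based texture
  features (MEA, VAR) scene-wide without touching zonal reflectance or
  the scale-free COR feature - emulating how texture levels stratify
  across independently quantized campaigns.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .bands import CAMERA_BANDS, BandSet
from .raster import GeoTransform, PlotROI, ReflectanceImage

__all__ = ["SceneConfig", "Scene", "generate_scene", "generate_experiment_pair"]

# per-band within-canopy texture amplitude (reflectance units), 450..850 nm
_TEXTURE_SD = (0.006, 0.010, 0.010, 0.008, 0.022, 0.030)


@dataclass(frozen=True)
class SceneConfig:
    """Study-condition parameters of a generated experiment.

    Defaults emulate a two-experiment campaign: a 48-plot multi-cultivar
    trial (VE-like) and an 81-plot multi-density trial (SE-like) sharing
    spectra and density range, with plant density spanning 100-900
    plants/m^2, a spectral saturation knee at 400 and a trait span of
    roughly 200-800 x10^4/ha.
    """

    n_plots_ve: int = 48
    n_plots_se: int = 81
    plot_shape: tuple[int, int] = (24, 32)
    row_spacing: int = 5
    density_range: tuple[float, float] = (100.0, 900.0)
    saturation_knee: float = 400.0
    saturation_flat_scale: float = 300.0
    texture_gain: float = 0.13
    nir_weight_base: float = 0.84
    nir_weight_jitter: float = 0.008
    rededge_weight: float = 0.93
    rededge_weight_jitter: float = 0.004
    vis_weight: float = 0.90
    vis_weight_jitter: float = 0.08
    noise_sd: float = 0.003
    pnpa_log_slope: float = 270.0
    pnpa_log_intercept: float = -1050.0
    pnpa_noise_sd: float = 35.0
    spectral_jitter: float = 0.05
    band_jitter_730: float = 0.010
    band_jitter_850: float = 0.022
    soil_spectrum: tuple[float, ...] = (0.045, 0.055, 0.065, 0.085, 0.11, 0.14)
    canopy_spectrum: tuple[float, ...] = (0.035, 0.09, 0.11, 0.055, 0.17, 0.26)
    margin_730_range: tuple[float, float] = (0.30, 0.80)
    margin_850_range: tuple[float, float] = (0.25, 0.55)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_range[0] <= 0 or self.density_range[1] <= self.density_range[0]:
            raise ValueError("density_range must be positive and increasing")
        if any(not (0 < s < 1) for s in self.soil_spectrum + self.canopy_spectrum):
            raise ValueError("spectra must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Scene:
    """A generated scene: imagery, ROIs and per-plot ground truth."""

    image: ReflectanceImage
    rois: list[PlotROI]
    truth: pd.DataFrame      # plot_id, dataset_label, density, cover, pnpa
    label: str = "VE"


def saturating_response(density: np.ndarray, knee: float,
                        flat_scale: float) -> np.ndarray:
    """Canopy spectral response u(density) in [0, 1]: linear to the knee,
    then exponentially flattening (the planted saturation)."""
    d = np.asarray(density, dtype=float)
    below = 0.8 * d / knee
    above = 0.8 + 0.2 * (1.0 - np.exp(-(d - knee) / flat_scale))
    return np.where(d <= knee, below, above)


def canopy_cover(density: np.ndarray) -> np.ndarray:
    """Fraction of ground covered by canopy rows, saturating with density."""
    return 0.35 + 0.55 * (1.0 - np.exp(-np.asarray(density, float) / 300.0))


def _canopy_reflectance(u: float, base: tuple[float, ...]) -> np.ndarray:
    """Per-band canopy reflectance at saturation state u (450..850 nm)."""
    b = np.asarray(base)
    resp = np.array([0.0, 0.02, 0.02, -0.015, 0.03, 0.26])
    return b + resp * u


def _grid_layout(n_plots: int, plot_shape: tuple[int, int], gap: int,
                 border: int) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    ph, pw = plot_shape
    ncols = int(np.ceil(np.sqrt(n_plots)))
    nrows = int(np.ceil(n_plots / ncols))
    origins = []
    for k in range(n_plots):
        r, c = divmod(k, ncols)
        origins.append((border + r * (ph + gap), border + c * (pw + gap)))
    H = border * 2 + nrows * (ph + gap) - gap
    W = border * 2 + ncols * (pw + gap) - gap
    return origins, (H, W)


def _diagonal_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance field constant along up-right (r+c) diagonals.

    Emulates obliquely oriented canopy row micro-structure: pixel pairs at
    the 45-degree GLCM offset (-1, +1) stay on one diagonal and are fully
    correlated, while pairs across diagonals are independent - exactly the
    local dependency the 45-degree windowed COR feature measures.  The
    realized diagonal variance is standardized so the structured-to-white
    variance ratio is controlled by the mixing weight alone.
    """
    H, W = shape
    block = 8        # rows per independent band: structures stay local
    out = np.empty(shape)
    for r0 in range(0, H, block):
        h = min(block, H - r0)
        g = rng.standard_normal(h + W - 1)
        g = (g - g.mean()) / g.std()
        idx = np.add.outer(np.arange(h), np.arange(W))
        out[r0:r0 + h] = g[idx]
    return out


def generate_scene(cfg: SceneConfig, label: str = "VE",
                   n_plots: int | None = None,
                   margin_strip: bool = False,
                   seed: int | None = None) -> Scene:
    """Generate one experiment scene.

    ``margin_strip`` paints the quantization-stretching vegetation strip
    along the top border (outside every ROI).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = n_plots if n_plots is not None else (
        cfg.n_plots_ve if label == "VE" else cfg.n_plots_se)
    gap, border = 4, 10
    origins, (H, W) = _grid_layout(n, cfg.plot_shape, gap, border)
    ph, pw = cfg.plot_shape

    bands: BandSet = CAMERA_BANDS
    nb = len(bands)
    soil = np.asarray(cfg.soil_spectrum)
    pixels = np.empty((nb, H, W))
    pixels[:] = soil[:, None, None]
    pixels += rng.normal(0.0, 0.004, size=(nb, H, W))   # soil grain

    white = rng.standard_normal((nb, H, W))

    lo, hi = cfg.density_range
    density = rng.uniform(lo, hi, size=n)
    pnpa = (cfg.pnpa_log_slope * np.log(density) + cfg.pnpa_log_intercept
            + rng.normal(0.0, cfg.pnpa_noise_sd, size=n))
    cover = canopy_cover(density)
    u = saturating_response(density, cfg.saturation_knee, cfg.saturation_flat_scale)
    # plot-level spectral state jitter (cultivar / nitrogen effects):
    # a common shift of the whole response curve plus independent
    # red-edge/NIR reflectance offsets per plot
    u = np.clip(u + rng.normal(0.0, cfg.spectral_jitter, size=n), 0.0, 1.1)
    j730 = rng.normal(0.0, cfg.band_jitter_730, size=n)
    j850 = rng.normal(0.0, cfg.band_jitter_850, size=n)

    # Per-plot, per-band oriented-vs-isotropic texture weights (COR
    # drivers).  All weights stay above ~0.5 so that zonal COR remains
    # positive scene-wide (the 3x3-window estimator carries a negative
    # small-sample offset); only the NIR weight tracks density.
    w_nir = np.clip(cfg.nir_weight_base
                    + cfg.texture_gain * np.log(density / lo) / np.log(hi / lo)
                    + rng.normal(0.0, cfg.nir_weight_jitter, size=n),
                    0.60, 0.99)
    w_rededge = np.clip(cfg.rededge_weight
                        + rng.normal(0.0, cfg.rededge_weight_jitter, size=n),
                        0.60, 0.995)
    w_vis = np.clip(cfg.vis_weight
                    + rng.normal(0.0, cfg.vis_weight_jitter, size=(n, 4)),
                    0.60, 0.98)

    rois: list[PlotROI] = []
    records = []
    tex_sd = np.asarray(_TEXTURE_SD)
    for k, (r0, c0) in enumerate(origins):
        # north-south row stripes; fractional cover realized by cumulative
        # (Bresenham) rounding of per-period stripe widths, so columns are
        # fully canopy or fully soil and realized cover tracks the target
        # within half a column
        width = cover[k] * cfg.row_spacing
        cols = np.arange(pw)
        period_idx = cols // cfg.row_spacing
        phase = cols % cfg.row_spacing
        w_cum = np.round((period_idx + 1) * width) - np.round(period_idx * width)
        col_is_canopy = phase < w_cum
        canopy_cols = np.repeat(col_is_canopy[None, :], ph, axis=0)

        spec = _canopy_reflectance(u[k], cfg.canopy_spectrum)
        spec[4] += j730[k]
        spec[5] += j850[k]
        weights = np.empty(nb)
        weights[:4] = w_vis[k]
        weights[4] = w_rededge[k]
        weights[5] = w_nir[k]
        sl = (slice(r0, r0 + ph), slice(c0, c0 + pw))
        for b in range(nb):
            # independent oriented field per plot and band, so plot-level
            # texture estimates are uncorrelated across plots
            diag = _diagonal_field(rng, (ph, pw))
            tex = (np.sqrt(weights[b]) * diag
                   + np.sqrt(1.0 - weights[b]) * white[b][sl])
            plot_plane = spec[b] + tex_sd[b] * tex
            pixels[b][sl] = np.where(canopy_cols, plot_plane, pixels[b][sl])

        pid = f"{label}{k + 1:03d}"
        inset = 0.25
        rois.append(PlotROI(pid, box(c0 + inset, H - (r0 + ph) + inset,
                                     c0 + pw - inset, H - r0 - inset)))
        records.append({"plot_id": pid, "dataset_label": label,
                        "density": density[k], "cover": cover[k],
                        "pnpa": pnpa[k]})

    if margin_strip:
        strip = (slice(1, 6), slice(0, W))
        base = _canopy_reflectance(0.5, cfg.canopy_spectrum)
        for b in range(4):
            pixels[b][strip] = base[b] + rng.normal(0.0, 0.005, size=(5, W))
        pixels[4][strip] = rng.uniform(*cfg.margin_730_range, size=(5, W))
        pixels[5][strip] = rng.uniform(*cfg.margin_850_range, size=(5, W))

    pixels += rng.normal(0.0, cfg.noise_sd, size=pixels.shape)
    np.clip(pixels, 1e-4, 0.999, out=pixels)

    image = ReflectanceImage(pixels, bands,
                             transform=GeoTransform(0.0, float(H), 1.0, 1.0))
    return Scene(image, rois, pd.DataFrame(records), label)


def generate_experiment_pair(cfg: SceneConfig) -> tuple[Scene, Scene, pd.DataFrame]:
    """Generate the VE-like and SE-like scenes plus the pooled trait table.

    The two scenes share spectra and density range; the SE scene carries
    the margin strip so that level-based (MEA) textural indices stratify
    across the pooled data while COR-based ones do not.
    """
    root = np.random.default_rng(cfg.seed)
    seed_ve, seed_se = root.integers(0, 2 ** 31 - 1, size=2)
    ve = generate_scene(cfg, "VE", cfg.n_plots_ve, margin_strip=False,
                        seed=int(seed_ve))
    se = generate_scene(cfg, "SE", cfg.n_plots_se, margin_strip=True,
                        seed=int(seed_se))
    pooled = pd.concat([ve.truth, se.truth], ignore_index=True)
    return ve, se, pooled
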