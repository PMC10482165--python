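"""Raster and vector I/O, radiometric calibration, zonal statistics.

Rasters are multi-band TIFFs (band, row, col) accompanied by a small JSON
sidecar (``<file>.json``) that records band centre wavelengths, the affine
geotransform, the nodata value and the ground sampling distance.  ROIs are
GeoJSON polygon features in the raster's world coordinates.

Conventions
-----------
* Arrays are ``[band, row, col]`` with row 0 at the top of the scene.
* The geotransform maps pixel centres to world coordinates:
  ``x = x0 + (col + 0.5) * dx``, ``y = y0 - (row + 0.5) * dy`` (north-up).
* A pixel contributes to a zonal statistic iff its centre falls strictly
  inside the ROI polygon and the pixel is valid.  Centres exactly on the
  boundary do not contribute.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .bands import BandSet

__all__ = [
    "GeoTransform",
    "ReflectanceImage",
    "PlotROI",
    "CalibrationSpec",
    "read_reflectance",
    "write_reflectance",
    "calibrate_dn",
    "read_rois",
    "write_rois",
    "zonal_mean",
    "zonal_mean_table",
]


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine transform from pixel indices to world coordinates."""

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = 1.0

    def pixel_centers(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of every pixel centre, as (X, Y) 2-D arrays."""
        cols = self.x0 + (np.arange(n_cols) + 0.5) * self.dx
        rows = self.y0 - (np.arange(n_rows) + 0.5) * self.dy
        return np.meshgrid(cols, rows)

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy}


@dataclass
class ReflectanceImage:
    """Multi-band surface-reflectance raster with a validity mask.

    ``pixels`` is ``[band, row, col]`` reflectance (dimensionless, nominally
    0-1); ``valid`` is ``[row, col]`` and marks pixels that carry data in
    every band.  ``pixel_size`` is the ground sampling distance in cm and is
    metadata only.
    """

    pixels: np.ndarray
    bands: BandSet
    valid: np.ndarray | None = None
    transform: GeoTransform = field(default_factory=GeoTransform)
    pixel_size: float = 1.35

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be [band, row, col]")
        if self.pixels.shape[0] != len(self.bands):
            raise ValueError(
                f"{self.pixels.shape[0]} band planes but {len(self.bands)} "
                "bands declared"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.pixels).all(axis=0)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.pixels.shape[1:]:
            raise ValueError("valid mask shape must equal spatial shape")
        if not np.isfinite(self.pixels[:, self.valid]).all():
            raise ValueError("non-finite reflectance inside valid region")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def band(self, wavelength: float) -> np.ndarray:
        """The 2-D reflectance plane for the band nearest ``wavelength`` nm."""
        return self.pixels[self.bands.index_of(wavelength)]


@dataclass(frozen=True)
class PlotROI:
    """A plot region of interest: an id plus a polygon in world coordinates."""

    plot_id: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry.is_empty:
            raise ValueError(f"ROI {self.plot_id!r}: empty geometry")
        if not self.geometry.is_valid:
            raise ValueError(f"ROI {self.plot_id!r}: invalid geometry "
                             "(self-intersection?)")


@dataclass(frozen=True)
class CalibrationSpec:
    """Single-panel radiometric calibration.

    ``panel_dn`` holds the per-band mean digital number over the grey
    reference panel and ``ref_coeff`` the panel's known reflectance per band
    (fraction, e.g. 0.08433 at 850 nm).  ``dark_offset`` is an optional
    per-band dark-current DN subtracted from both image and panel, default 0.
    """

    panel_dn: tuple[float, ...]
    ref_coeff: tuple[float, ...]
    dark_offset: tuple[float, ...] | float = 0.0

    def __post_init__(self) -> None:
        if len(self.panel_dn) != len(self.ref_coeff):
            raise ValueError("panel_dn and ref_coeff length mismatch")
        if any(d <= 0 for d in self.panel_dn):
            raise ValueError("panel DN values must be positive")
        if any(not (0.0 < c < 1.0) for c in self.ref_coeff):
            raise ValueError("reference coefficients must lie in (0, 1)")


#: Per-band reference-panel reflectance of the camera, ordered 450..850 nm.
PANEL_REF_COEFF: tuple[float, ...] = (
    0.07008, 0.07291, 0.07239, 0.07442, 0.07667, 0.08433,
)


def calibrate_dn(dn_image: np.ndarray, spec: CalibrationSpec,
                 bands: BandSet) -> ReflectanceImage:
    """Convert a raw digital-number cube to reflectance.

    Uses the single-point empirical line through the origin:
    ``reflectance = (DN - dark) / (DN_panel - dark) * ref_coeff`` per band.
    """
    dn = np.asarray(dn_image, dtype=float)
    if dn.ndim != 3 or dn.shape[0] != len(spec.panel_dn):
        raise ValueError("dn_image must be [band, row, col] matching the spec")
    if np.nanmin(dn) < 0:
        raise ValueError("negative digital numbers")
    dark = np.asarray(spec.dark_offset, dtype=float)
    dark = np.broadcast_to(dark, (dn.shape[0],))
    panel = np.asarray(spec.panel_dn, dtype=float) - dark
    if np.any(panel <= 0):
        raise ValueError("panel DN must exceed the dark offset")
    coeff = np.asarray(spec.ref_coeff, dtype=float)
    refl = (dn - dark[:, None, None]) / panel[:, None, None] * coeff[:, None, None]
    return ReflectanceImage(refl, bands)


# ---------------------------------------------------------------------------
# raster I/O (TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_reflectance(image: ReflectanceImage, path: str | Path,
                      nodata: float = float("nan")) -> Path:
    """Write a ReflectanceImage as multi-band TIFF plus JSON sidecar."""
    import tifffile

    path = Path(path)
    data = image.pixels.copy()
    data[:, ~image.valid] = nodata
    tifffile.imwrite(path, data.astype(np.float64), photometric="minisblack")
    meta = {
        "wavelengths_nm": list(image.bands.centers),
        "band_names": list(image.bands.names),
        "transform": image.transform.to_dict(),
        "nodata": None if math.isnan(nodata) else nodata,
        "pixel_size_cm": image.pixel_size,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_reflectance(path: str | Path,
                     wavelengths: list[float] | None = None) -> ReflectanceImage:
    """Read a multi-band reflectance TIFF written by :func:`write_reflectance`.

    ``wavelengths`` overrides the sidecar band centres (required when the
    sidecar is absent).  Nodata pixels (sidecar ``nodata`` value, or NaN)
    are marked invalid.
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    centers = wavelengths or meta.get("wavelengths_nm")
    if centers is None:
        raise ValueError(f"{path}: band wavelengths not in sidecar and not supplied")
    if len(centers) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} bands in file, {len(centers)} wavelengths"
        )
    bands = BandSet(tuple(centers), tuple(meta.get("band_names", ())))
    nodata = meta.get("nodata")
    valid = np.isfinite(data).all(axis=0)
    if nodata is not None:
        valid &= ~(data == nodata).any(axis=0)
        data = np.where(data == nodata, np.nan, data)
    if not valid.any():
        raise ValueError(f"{path}: raster is entirely nodata")
    tr = GeoTransform(**meta["transform"]) if "transform" in meta else GeoTransform()
    return ReflectanceImage(data, bands, valid, tr,
                            meta.get("pixel_size_cm", 1.35))


# ---------------------------------------------------------------------------
# vector I/O
# ---------------------------------------------------------------------------

def read_rois(path: str | Path, id_property: str = "plot_id") -> list[PlotROI]:
    """Read plot ROIs from a GeoJSON feature collection."""
    path = Path(path)
    doc = json.loads(path.read_text())
    features = doc.get("features", [])
    if not features:
        raise ValueError(f"{path}: empty feature collection")
    rois: list[PlotROI] = []
    seen: set[str] = set()
    for feat in features:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"{path}: feature missing {id_property!r} property")
        pid = str(props[id_property])
        if pid in seen:
            raise ValueError(f"{path}: duplicate plot id {pid!r}")
        seen.add(pid)
        geom = shapely_shape(feat["geometry"])
        rois.append(PlotROI(pid, geom))  # validity enforced by PlotROI
    return rois


def write_rois(rois: list[PlotROI], path: str | Path,
               id_property: str = "plot_id") -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {id_property: roi.plot_id},
            "geometry": shapely.geometry.mapping(roi.geometry),
        }
        for roi in rois
    ]
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
    return path


# ---------------------------------------------------------------------------
# zonal statistics
# ---------------------------------------------------------------------------

def roi_pixel_mask(roi: PlotROI, transform: GeoTransform,
                   shape: tuple[int, int]) -> np.ndarray:
    """Boolean [row, col] mask of pixels whose centres lie inside the ROI."""
    n_rows, n_cols = shape
    xs, ys = transform.pixel_centers(n_rows, n_cols)
    inside = shapely.contains_xy(roi.geometry, xs.ravel(), ys.ravel())
    return inside.reshape(shape)


def zonal_mean(values: np.ndarray, valid: np.ndarray, roi: PlotROI,
               transform: GeoTransform = GeoTransform(),
               ) -> tuple[float, int]:
    """Mean of ``values`` over valid pixels with centres inside the ROI.

    Returns ``(mean, n)``; ``(nan, 0)`` when no pixel contributes.
    """
    values = np.asarray(values, dtype=float)
    sel = roi_pixel_mask(roi, transform, values.shape) & np.asarray(valid, bool)
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(values[sel].mean()), n


def zonal_mean_table(image: ReflectanceImage, rois: list[PlotROI],
                     extra_valid: np.ndarray | None = None):
    """Per-plot mean reflectance of every band; returns a pandas DataFrame.

    ``extra_valid`` (e.g. a green mask) further restricts contributing pixels.
    """
    import pandas as pd

    valid = image.valid if extra_valid is None else image.valid & extra_valid
    rows = []
    for roi in rois:
        sel = roi_pixel_mask(roi, image.transform, image.shape) & valid
        n = int(sel.sum())
        rec: dict = {"plot_id": roi.plot_id, "n_pixels": n}
        for c in image.bands.centers:
            plane = image.band(c)
            rec[f"R{int(round(c))}"] = float(plane[sel].mean()) if n else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)
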