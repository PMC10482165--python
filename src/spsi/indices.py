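"""Spectral-index registry and per-plot index computation.

Indices are evaluated on the ROI-mean green-pixel reflectance (index of
means, not mean of per-pixel indices): zonal averaging first removes most
within-plot noise and mirrors how plot-scale trait models are built.  Zero
denominators yield NaN (missing), never infinities.

The registry ships the nine standard forms used for pre-heading wheat
canopies (NDVI, NDRE, EVI2, CI_green, CI_red_edge, NEI, OSAVI, DATT, TBVI),
all expressed on the camera's band centres.  Additional formulas can be
registered at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "IndexDefinition",
    "SpectralVector",
    "SI_REGISTRY",
    "compute_si",
    "compute_all_sis",
    "register_index",
]


def _safe_div(num: float, den: float) -> float:
    if den == 0 or not np.isfinite(den) or not np.isfinite(num):
        return float("nan")
    return num / den


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral-index formula over reflectances keyed by nm."""

    name: str
    required_centers: tuple[float, ...]
    formula: Callable[[Mapping[float, float]], float]

    def __call__(self, r: Mapping[float, float]) -> float:
        return self.formula(r)


@dataclass(frozen=True)
class SpectralVector:
    """Per-plot mean green-pixel reflectance keyed by wavelength (nm)."""

    values: Mapping[float, float]
    plot_id: str = ""
    n_pixels: int = 1

    def __getitem__(self, wavelength: float) -> float:
        for key, val in self.values.items():
            if abs(key - wavelength) <= 15.0:
                return float(val)
        raise KeyError(f"spectral vector has no band near {wavelength} nm")


SI_REGISTRY: dict[str, IndexDefinition] = {}


def register_index(name: str, centers: tuple[float, ...],
                   formula: Callable[[Mapping[float, float]], float]) -> IndexDefinition:
    if name in SI_REGISTRY:
        raise ValueError(f"index {name!r} already registered")
    defn = IndexDefinition(name, centers, formula)
    SI_REGISTRY[name] = defn
    return defn


register_index("NDVI", (675.0, 850.0),
               lambda r: _safe_div(r[850] - r[675], r[850] + r[675]))
register_index("NDRE", (730.0, 850.0),
               lambda r: _safe_div(r[850] - r[730], r[850] + r[730]))
register_index("EVI2", (675.0, 850.0),
               lambda r: _safe_div(2.5 * (r[850] - r[675]),
                                   1.0 + r[850] + 2.4 * r[675]))
register_index("CI_green", (530.0, 850.0),
               lambda r: _safe_div(r[850], r[530]) - 1.0)
register_index("CI_red_edge", (730.0, 850.0),
               lambda r: _safe_div(r[850], r[730]) - 1.0)
register_index("NEI", (675.0, 730.0, 850.0),
               lambda r: _safe_div((1.8 + _safe_div(r[675], r[850])) * r[730]
                                   + r[675], r[850] + r[675]))
register_index("OSAVI", (675.0, 850.0),
               lambda r: _safe_div(r[850] - r[675], r[850] + r[675] + 0.16))
register_index("DATT", (675.0, 730.0, 850.0),
               lambda r: _safe_div(r[850] - r[730], r[850] - r[675]))
register_index("TBVI", (450.0, 730.0, 850.0),
               lambda r: _safe_div(r[850] - r[730] + 2.0 * r[450],
                                   r[850] + r[730] - 2.0 * r[450]))


class _VectorView:
    """Adapter letting formulas index a SpectralVector with nominal nm keys."""

    def __init__(self, v: SpectralVector):
        self._v = v

    def __getitem__(self, wavelength: float) -> float:
        return self._v[wavelength]


def compute_si(defn: IndexDefinition, v: SpectralVector) -> float:
    """Evaluate one index on a plot's mean reflectance; NaN on 0/0."""
    for c in defn.required_centers:
        try:
            v[c]
        except KeyError:
            raise KeyError(
                f"{defn.name}: spectral vector missing band at {c} nm"
            ) from None
    val = defn(_VectorView(v))
    return float(val) if np.isfinite(val) else float("nan")


def compute_all_sis(v: SpectralVector,
                    names: list[str] | None = None) -> dict[str, float]:
    """Evaluate every registered index (or the named subset) on one vector.

    Missing values (zero denominators) propagate as NaN without aborting
    the batch.
    """
    out: dict[str, float] = {}
    for name in (names or list(SI_REGISTRY)):
        out[name] = compute_si(SI_REGISTRY[name], v)
    return out
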