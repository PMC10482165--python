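"""Textural indices, the NDTI_COR family, band-pair search, and SPSI.

A textural index (TI) re-uses a spectral-index formula with per-band zonal
texture values substituted for reflectances, e.g. the NDRE form on the GLCM
correlation feature:

    NDTI_COR(l1, l2) = (T_l1 - T_l2) / (T_l1 + T_l2)

with T the zonal-mean COR of each band.  The composite index is the exact
sum of the optimal spectral index and the optimal NDTI_COR:

    SPSI = SI_opt + NDTI_COR_opt

where the optimal band pair is found by exhaustively regressing the trait
on NDTI_COR of every ordered wavelength pair and keeping the strongest
positive- and negative-correlated pairs.  The sign of the chosen pair must
match the sign of the SI-trait correlation before summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .indices import SI_REGISTRY, SpectralVector, compute_si
from .texture import TextureStats

__all__ = [
    "TIValue",
    "BandSearchResult",
    "compute_ti",
    "ndti_cor",
    "band_search",
    "spsi",
]


@dataclass(frozen=True)
class TIValue:
    """A textural index value: SI form x texture feature x pixel mode."""

    form: str
    feature: str
    pixel_mode: str
    value: float


@dataclass
class BandSearchResult:
    """Exhaustive NDTI_COR band-pair search over ordered wavelength pairs.

    ``r2`` and ``sign`` are square matrices over the band list; the diagonal
    is invalid (NaN).  ``best_positive``/``best_negative`` are the max-R2
    pairs among positive/negative-slope fits (ties broken by smallest
    wavelength, first then second).
    """

    wavelengths: tuple[float, ...]
    r2: np.ndarray
    sign: np.ndarray
    best_positive: tuple[float, float] | None
    best_negative: tuple[float, float] | None

    def r2_of(self, l1: float, l2: float) -> float:
        i = self.wavelengths.index(l1)
        j = self.wavelengths.index(l2)
        return float(self.r2[i, j])


def compute_ti(form: str, feature: str, stats: TextureStats) -> TIValue:
    """Evaluate a registered SI formula on one plot's zonal texture values."""
    defn = SI_REGISTRY[form]
    values = {wl: stats.get(wl, feature) for wl in defn.required_centers}
    v = SpectralVector(values, plot_id=stats.plot_id)
    return TIValue(form, feature, stats.pixel_mode, compute_si(defn, v))


def ndti_cor(stats: TextureStats, l1: float, l2: float) -> float:
    """Normalized-difference texture index on the COR feature (NaN on 0/0)."""
    if l1 == l2:
        raise ValueError("NDTI_COR needs two distinct wavelengths")
    t1 = stats.get(l1, "COR")
    t2 = stats.get(l2, "COR")
    den = t1 + t2
    if den == 0 or not np.isfinite(den) or not np.isfinite(t1 - t2):
        return float("nan")
    return (t1 - t2) / den


def _slr_r2_sign(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(R2, slope sign) of a simple linear regression, or None if degenerate."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, float(np.sign(r))


def band_search(plots: Sequence[tuple[TextureStats, float]],
                wavelengths: Sequence[float] | None = None) -> BandSearchResult:
    """Fit trait ~ NDTI_COR(l1, l2) for every ordered band pair.

    ``plots`` pairs each plot's zonal texture stats with its measured trait.
    Returns the full R2/sign matrices plus the strongest positively and
    negatively correlated pairs.
    """
    if len(plots) < 3:
        raise ValueError("band_search needs at least 3 plots")
    if wavelengths is None:
        wavelengths = sorted({wl for (stats, _) in plots[:1]
                              for (wl, feat) in stats.values if feat == "COR"})
    wls = tuple(float(w) for w in wavelengths)
    if len(wls) < 2:
        raise ValueError("band_search needs at least 2 bands")
    y = np.array([trait for _, trait in plots], dtype=float)
    k = len(wls)
    r2 = np.full((k, k), np.nan)
    sign = np.full((k, k), np.nan)
    best_pos: tuple[float, tuple[float, float]] | None = None
    best_neg: tuple[float, tuple[float, float]] | None = None
    for i, l1 in enumerate(wls):
        for j, l2 in enumerate(wls):
            if i == j:
                continue
            x = np.array([ndti_cor(stats, l1, l2) for stats, _ in plots])
            fit = _slr_r2_sign(x, y)
            if fit is None:
                continue
            r2[i, j], sign[i, j] = fit
            key = (r2[i, j], (l1, l2))
            if sign[i, j] > 0:
                if best_pos is None or key[0] > best_pos[0] + 1e-15 or (
                        abs(key[0] - best_pos[0]) <= 1e-15 and key[1] < best_pos[1]):
                    best_pos = key
            elif sign[i, j] < 0:
                if best_neg is None or key[0] > best_neg[0] + 1e-15 or (
                        abs(key[0] - best_neg[0]) <= 1e-15 and key[1] < best_neg[1]):
                    best_neg = key
    return BandSearchResult(
        wls, r2, sign,
        best_pos[1] if best_pos else None,
        best_neg[1] if best_neg else None,
    )


def spsi(si_opt: float, ndti_opt: float) -> float:
    """The composite spectral-textural index: the exact sum of its parts."""
    if not (np.isfinite(si_opt) and np.isfinite(ndti_opt)):
        return float("nan")
    return float(si_opt) + float(ndti_opt)
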