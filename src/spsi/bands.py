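"""Band bookkeeping for the six-band multispectral camera.

The camera carries six 10 nm filters centred at 450, 530, 570, 675, 730 and
850 nm.  All indices in this package address bands by their nominal centre
wavelength in nanometres; :func:`BandSet.index_of` resolves a requested
wavelength to a band position with a small tolerance so that slightly
off-nominal metadata (e.g. 849 nm written by a converter) still binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BandSet", "CAMERA_CENTERS", "CAMERA_BANDS"]

#: Nominal filter centres (nm) of the six-band camera.
CAMERA_CENTERS: tuple[float, ...] = (450.0, 530.0, 570.0, 675.0, 730.0, 850.0)

#: Matching tolerance when binding a requested wavelength to a band (nm).
WAVELENGTH_TOL_NM = 15.0


@dataclass(frozen=True)
class BandSet:
    """An ordered set of spectral bands identified by centre wavelength.

    Parameters
    ----------
    centers
        Band centre wavelengths in nm, strictly increasing, all positive.
    names
        Unique band labels; defaults to ``"B450"``-style labels.
    """

    centers: tuple[float, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.centers)
        object.__setattr__(self, "centers", centers)
        if len(centers) < 2:
            raise ValueError("a BandSet needs at least 2 bands")
        if any(c <= 0 for c in centers):
            raise ValueError("band centers must be positive")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        names = self.names or tuple(f"B{int(round(c))}" for c in centers)
        if len(names) != len(centers):
            raise ValueError("names and centers length mismatch")
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        object.__setattr__(self, "names", tuple(names))

    def __len__(self) -> int:
        return len(self.centers)

    def index_of(self, wavelength: float, tol: float = WAVELENGTH_TOL_NM) -> int:
        """Return the band index whose centre is nearest ``wavelength``.

        Raises ``KeyError`` if the nearest centre is farther than ``tol`` nm.
        """
        diffs = [abs(c - wavelength) for c in self.centers]
        i = min(range(len(diffs)), key=diffs.__getitem__)
        if diffs[i] > tol:
            raise KeyError(
                f"no band within {tol} nm of {wavelength} nm "
                f"(centers: {self.centers})"
            )
        return i


#: The camera's default band set.
CAMERA_BANDS = BandSet(CAMERA_CENTERS)
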