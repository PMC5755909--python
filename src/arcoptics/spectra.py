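"""Wavelength-indexed spectra.

The :class:`Spectrum` container underlies every optical quantity handled by
the package: optical densities and transmittances from the filterpad bench,
absorbance from the CDOM spectrometer, constituent absorption coefficients
(m^-1), remote-sensing reflectance (sr^-1) and radiometric quantities.
Values between grid points are obtained by linear interpolation; queries
outside the measured grid are an error, never an extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Recognised constituent tags and the physical quantity they label.
CONSTITUENTS = frozenset(
    {
        "od",            # optical density (dimensionless)
        "transmittance",  # (0, 1]
        "absorbance",    # decadic absorbance (dimensionless)
        "ap",            # total particulate absorption (m^-1)
        "anap",          # non-algal particle absorption (m^-1)
        "aph",           # phytoplankton absorption (m^-1)
        "acdom",         # CDOM absorption (m^-1)
        "atw",           # total non-water absorption (m^-1)
        "rrs",           # remote-sensing reflectance (sr^-1)
        "ed",            # downwelling irradiance (W m^-2 nm^-1)
        "lu",            # upwelling radiance (W m^-2 nm^-1 sr^-1)
    }
)

#: Absorption-like tags for which small negative values are tolerated but flagged.
_ABSORPTION_TAGS = frozenset({"ap", "anap", "aph", "acdom", "atw"})

#: Tolerance below which negative absorption triggers a warning (m^-1).
NEGATIVE_ABSORPTION_WARN = -1e-3


class SpectrumError(ValueError):
    """Invalid spectral data or query."""


@dataclass(frozen=True)
class Spectrum:
    """A spectral quantity on a strictly ascending wavelength grid.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing wavelength grid in nanometres.
    values:
        One value per wavelength. Units depend on ``constituent``.
    constituent:
        One of :data:`CONSTITUENTS`.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    constituent: str
    flags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise SpectrumError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if self.constituent not in CONSTITUENTS:
            raise SpectrumError(f"unknown constituent tag {self.constituent!r}")
        if self.constituent == "transmittance":
            finite = vals[np.isfinite(vals)]
            if np.any(finite <= 0) or np.any(finite > 1):
                raise SpectrumError("transmittance values must lie in (0, 1]")
        if self.constituent in _ABSORPTION_TAGS:
            finite = vals[np.isfinite(vals)]
            if finite.size and finite.min() < NEGATIVE_ABSORPTION_WARN:
                self.flags["negative_values"] = int(np.sum(finite < 0))
                warnings.warn(
                    f"{self.constituent} spectrum has values below "
                    f"{NEGATIVE_ABSORPTION_WARN} m^-1 (min {finite.min():.4g}); "
                    "retained, not clipped",
                    stacklevel=2,
                )
            elif finite.size and finite.min() < 0:
                self.flags["negative_values"] = int(np.sum(finite < 0))

    # -- queries -----------------------------------------------------------

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    def at(self, wavelength_nm):
        """Value at one or more wavelengths by linear interpolation.

        Raises
        ------
        SpectrumError
            If any requested wavelength falls outside the measured grid.
        """
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wl_min) or np.any(wl > self.wl_max):
            raise SpectrumError(
                f"wavelength query outside grid [{self.wl_min}, {self.wl_max}] nm"
            )
        out = np.interp(wl, self.wavelengths_nm, self.values)
        return float(out) if np.isscalar(wavelength_nm) else out

    def covers(self, wavelength_nm: float) -> bool:
        return self.wl_min <= wavelength_nm <= self.wl_max

    # -- grid alignment ----------------------------------------------------

    def with_values(self, values, constituent: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm.copy(), values,
                        constituent or self.constituent)


def common_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Intersection grid of two spectra.

    The overlap interval is gridded with the points of whichever spectrum is
    finer (more samples) inside the overlap; the coarser spectrum is later
    interpolated onto it.
    """
    lo = max(a.wl_min, b.wl_min)
    hi = min(a.wl_max, b.wl_max)
    if lo > hi:
        raise SpectrumError("spectra have disjoint wavelength ranges")
    ga = a.wavelengths_nm[(a.wavelengths_nm >= lo) & (a.wavelengths_nm <= hi)]
    gb = b.wavelengths_nm[(b.wavelengths_nm >= lo) & (b.wavelengths_nm <= hi)]
    grid = ga if ga.size >= gb.size else gb
    if grid.size == 0:
        raise SpectrumError("no common wavelength support")
    return grid


def on_common_grid(*spectra: Spectrum) -> tuple[np.ndarray, list[np.ndarray]]:
    """Interpolate several spectra onto their shared intersection grid."""
    if len(spectra) < 2:
        raise SpectrumError("need at least two spectra")
    grid = common_grid(spectra[0], spectra[1])
    for s in spectra[2:]:
        lo, hi = max(grid[0], s.wl_min), min(grid[-1], s.wl_max)
        if lo > hi:
            raise SpectrumError("spectra have disjoint wavelength ranges")
        grid = grid[(grid >= lo) & (grid <= hi)]
        if grid.size == 0:
            raise SpectrumError("no common wavelength support")
    return grid, [s.at(grid) for s in spectra]
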