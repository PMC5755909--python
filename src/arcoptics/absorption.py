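"""Constituent absorption coefficients from raw spectrophotometry.

Implements the quantitative filterpad technique (particulate and non-algal
particle absorption with a path-length amplification factor beta = 1/4.5),
CDOM absorption from cuvette absorbance with a 600 nm baseline, the total
non-water absorption budget, and power-law couplings between pigment and
absorption (e.g. aph(443) = 0.0513 Chl^0.6675 for this data set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import Spectrum, SpectrumError, on_common_grid

#: Default path-length amplification correction for filterpad measurements.
DEFAULT_BETA = 1.0 / 4.5

#: CDOM reference bands: the visible band used throughout the station tables,
#: and the UV band used for comparison with DOC/lignin work.
CDOM_VIS_NM = 443.0
CDOM_UV_NM = 350.0

#: Wavelength at which CDOM absorption is assumed negligible (baseline).
CDOM_BASELINE_NM = 600.0

#: ln(10): decadic absorbance to Napierian absorption.
LN10 = 2.303

#: Fitted pigment-absorption power laws for this region (coefficient, exponent).
APH443_CHL_POWER_LAW = (0.0513, 0.6675)
AP443_CHL_POWER_LAW = (0.0595, 0.5603)

#: Threshold below which negative phytoplankton absorption triggers a warning.
NEGATIVE_APH_WARN = -1e-3


@dataclass(frozen=True)
class FilterPadSample:
    """A filterpad optical-density scan with its filtration geometry.

    ``clearance_area_m2`` is the filter clearance area A, ``volume_m3`` the
    filtered sample volume V and ``beta`` the path-length amplification
    multiplier (default 1/4.5). ``bleached`` marks NaOCl-bleached filters,
    whose absorption is attributed to non-algal particles.
    """

    od: Spectrum
    clearance_area_m2: float
    volume_m3: float
    beta: float = DEFAULT_BETA
    bleached: bool = False

    def __post_init__(self) -> None:
        if self.od.constituent != "od":
            raise SpectrumError("FilterPadSample.od must carry constituent 'od'")
        if not (self.clearance_area_m2 > 0 and self.volume_m3 > 0):
            raise ValueError("clearance area and volume must be positive")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class CDOMSample:
    """A CDOM decadic absorbance spectrum and the cuvette path length (m)."""

    absorbance: Spectrum
    pathlength_m: float

    def __post_init__(self) -> None:
        if self.absorbance.constituent != "absorbance":
            raise SpectrumError("CDOMSample.absorbance must carry constituent 'absorbance'")
        if self.pathlength_m <= 0:
            raise ValueError("cuvette path length must be positive")
        if not self.absorbance.covers(CDOM_BASELINE_NM):
            raise SpectrumError(
                f"absorbance grid must cover {CDOM_BASELINE_NM:.0f} nm for the baseline correction"
            )


@dataclass
class StationAbsorption:
    """Assembled absorption budget for one station."""

    station_id: str
    ap: Spectrum
    anap: Spectrum
    aph: Spectrum
    acdom: Spectrum
    atw: Spectrum
    chl_mg_m3: float | None = None


@dataclass(frozen=True)
class PowerLawFit:
    """y = coefficient * x**exponent, fitted by OLS in log10-log10 space."""

    coefficient: float
    exponent: float
    r2: float
    n: int


# ---------------------------------------------------------------------------
# Filterpad absorption
# ---------------------------------------------------------------------------

def transmittance_from_od(od: Spectrum, decadic: bool = False) -> Spectrum:
    """Transmittance T(lambda) from optical density.

    By default OD is treated as natural-log optical density, T = exp(-OD).
    Set ``decadic=True`` for spectrophotometers reporting decadic OD,
    T = 10**(-OD).
    """
    if od.constituent != "od":
        raise SpectrumError("expected an 'od' spectrum")
    vals = od.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("optical density contains non-finite values")
    t = np.power(10.0, -vals) if decadic else np.exp(-vals)
    return od.with_values(t, "transmittance")


def particulate_absorption(sample: FilterPadSample, decadic: bool = False) -> Spectrum:
    """Particulate absorption a_p (or a_NAP for bleached filters), m^-1.

    a(lambda) = -ln T(lambda) * A * beta / V, with A the clearance area,
    V the filtered volume and beta the amplification multiplier.
    """
    t = transmittance_from_od(sample.od, decadic=decadic)
    if np.any(t.values <= 0):
        raise ValueError("non-positive transmittance")
    a = -np.log(t.values) * sample.clearance_area_m2 * sample.beta / sample.volume_m3
    tag = "anap" if sample.bleached else "ap"
    return Spectrum(sample.od.wavelengths_nm.copy(), a, tag)


def phytoplankton_absorption(ap: Spectrum, anap: Spectrum) -> Spectrum:
    """a_ph = a_p - a_NAP on the common grid.

    Negative values (over-bleaching artifacts) are retained and flagged,
    never clipped; values below -0.001 m^-1 additionally raise a warning.
    """
    if ap.constituent != "ap" or anap.constituent != "anap":
        raise SpectrumError("expected 'ap' and 'anap' spectra")
    grid, (vap, vnap) = on_common_grid(ap, anap)
    aph = vap - vnap
    with warnings.catch_warnings():
        # Spectrum itself warns below the same threshold; avoid doubling up.
        warnings.simplefilter("ignore")
        out = Spectrum(grid, aph, "aph")
    if aph.min() < NEGATIVE_APH_WARN:
        warnings.warn(
            f"aph has values below {NEGATIVE_APH_WARN} m^-1 "
            f"(min {aph.min():.4g}); retained, not clipped",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# CDOM absorption
# ---------------------------------------------------------------------------

def cdom_absorption(sample: CDOMSample) -> Spectrum:
    """Napierian CDOM absorption from decadic absorbance.

    a_CDOM(lambda) = 2.303 * (A(lambda) - A(600)) / L, the 600 nm offset
    removing residual scattering/instrument baseline under the assumption of
    negligible CDOM absorption at 600 nm. a_CDOM(600) is exactly zero.
    """
    a600 = sample.absorbance.at(CDOM_BASELINE_NM)
    vals = LN10 * (sample.absorbance.values - a600) / sample.pathlength_m
    return Spectrum(sample.absorbance.wavelengths_nm.copy(), vals, "acdom")


# ---------------------------------------------------------------------------
# Absorption budget
# ---------------------------------------------------------------------------

def total_nonwater(aph: Spectrum, anap: Spectrum, acdom: Spectrum) -> Spectrum:
    """Total non-water absorption a_tw = a_ph + a_NAP + a_CDOM."""
    grid, (vph, vnap, vcdom) = on_common_grid(aph, anap, acdom)
    return Spectrum(grid, vph + vnap + vcdom, "atw")


def contribution_shares(
    aph: Spectrum, anap: Spectrum, acdom: Spectrum, wavelength_nm: float = CDOM_VIS_NM
) -> dict[str, float]:
    """Fractional contributions of the three absorbers to a_tw at one band.

    The shares sum to one. A zero total is degenerate and raises.
    """
    parts = {
        "aph": aph.at(wavelength_nm),
        "anap": anap.at(wavelength_nm),
        "acdom": acdom.at(wavelength_nm),
    }
    total = sum(parts.values())
    if total == 0:
        raise ValueError(f"a_tw({wavelength_nm:g}) = 0: contribution shares undefined")
    return {k: v / total for k, v in parts.items()}


def assemble_station(
    station_id: str,
    ap: Spectrum,
    anap: Spectrum,
    acdom: Spectrum,
    chl_mg_m3: float | None = None,
) -> StationAbsorption:
    """Derive aph and atw from measured ap/anap/acdom and bundle per station."""
    aph = phytoplankton_absorption(ap, anap)
    atw = total_nonwater(aph, anap, acdom)
    return StationAbsorption(station_id, ap, anap, aph, acdom, atw, chl_mg_m3)


# ---------------------------------------------------------------------------
# Power-law couplings
# ---------------------------------------------------------------------------

def power_law_fit(x, y) -> PowerLawFit:
    """Fit y = a * x**b by ordinary least squares in log10-log10 space.

    Bio-optical parameters are log-normally distributed, so correlations
    between pairs of them are evaluated with power functions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    for name, arr in (("x", x), ("y", y)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(f"non-positive {name} value at index {bad[0]}")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        coefficient=float(10.0 ** res.intercept),
        exponent=float(res.slope),
        r2=float(res.rvalue**2),
        n=int(x.size),
    )


def evaluate_power_law(fit: PowerLawFit, chl: float) -> float:
    """Evaluate a fitted power law at a pigment concentration (mg m^-3)."""
    if chl < 0:
        raise ValueError("Chl-a concentration must be non-negative")
    if chl == 0:
        return 0.0 if fit.exponent > 0 else float("inf") if fit.exponent < 0 else fit.coefficient
    return float(fit.coefficient * chl**fit.exponent)
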