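"""Ocean-color algorithms: empirical band-ratio Chl-a and semi-analytical
inversion of Rrs.

Empirical algorithms map the base-10 log of a maximum blue/green band ratio
through a polynomial: the MODIS OC3M and SeaWiFS OC4V6 global quartics, the
Arctic OC4L linear form, and the western-Arctic retuned OC3M-mod/OC4V6-mod
quartics.

The semi-analytical route is a GIOP-class spectral-matching inversion: the
forward operator composes total absorption a(lambda) = a_w + aph443 *
aph_shape(lambda) + adg443 * exp(-S_dg (lambda - 443)) and total backscatter
b_b(lambda) = b_bw + bbp555 * (555/lambda)**eta, maps u = b_b / (a + b_b)
through the quadratic rrs = g1 u + g2 u^2 and lifts it above the surface;
bounded nonlinear least squares recovers the three eigenvalues aph(443),
adg(443) and bbp(555) from multispectral Rrs. Chl-a follows from aph(443)
with the factor 0.055. A GSM-style partition optionally splits adg(443)
into NAP and CDOM parts through a bbp(555)-based NAP parametrization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectra import Spectrum

# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

#: SeaWiFS/MODIS-Aqua operational wavelengths used by the inversion (nm).
OPERATIONAL_BANDS = (412.0, 443.0, 490.0, 510.0, 555.0, 670.0)

#: MODIS aliases used by the OC3M band-ratio pair (nm).
MODIS_BLUE, MODIS_GREEN = 488.0, 551.0

#: Red reference band and threshold of the turbidity screen (sr^-1).
TURBIDITY_BAND = 676.0
TURBIDITY_THRESHOLD = 0.00042

#: Chl factor converting aph(443) to Chl-a (m^-1 per mg m^-3).
CHL_FACTOR = 0.055

#: Overflow guard for empirical retrievals (mg m^-3).
CHL_CAP = 1000.0


@dataclass
class BandSet:
    """Rrs sampled at discrete bands (sr^-1), keyed by wavelength in nm."""

    values: dict[float, float]
    station_id: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values() if np.isfinite(v)):
            self.flags["negative_bands"] = sorted(
                wl for wl, v in self.values.items() if np.isfinite(v) and v < 0
            )

    def get(self, band: float) -> float | None:
        return self.values.get(float(band))

    @classmethod
    def from_spectrum(cls, rrs: Spectrum, bands=None, station_id=None) -> "BandSet":
        """Extract band Rrs from hyperspectral Rrs by linear interpolation."""
        if bands is None:
            bands = OPERATIONAL_BANDS + (MODIS_BLUE, MODIS_GREEN, TURBIDITY_BAND)
        vals = {}
        for b in bands:
            if rrs.covers(b):
                vals[float(b)] = rrs.at(b)
        return cls(vals, station_id=station_id)


# ---------------------------------------------------------------------------
# Empirical maximum-band-ratio algorithms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalCoefficients:
    """Polynomial coefficients (constant first) and band-ratio scheme."""

    name: str
    coefficients: tuple[float, ...]
    scheme: str  # "three_band" (443/488 over 551) or "four_band" (443/490/510 over 555)

    def __post_init__(self) -> None:
        if self.scheme not in ("three_band", "four_band"):
            raise ValueError(f"unknown band-ratio scheme {self.scheme!r}")
        n = len(self.coefficients)
        if self.name == "oc4l":
            if n != 2:
                raise ValueError("OC4L carries exactly 2 coefficients")
        elif n != 5:
            raise ValueError(f"{self.name} requires 5 polynomial coefficients, got {n}")


#: Published algorithm coefficient sets. OC3M/OC4V6 are the global MODIS and
#: SeaWiFS quartics, OC4L the Arctic linear form, *-mod the western-Arctic
#: retuned quartics.
EMPIRICAL_ALGORITHMS: dict[str, EmpiricalCoefficients] = {
    "oc3m": EmpiricalCoefficients(
        "oc3m", (0.2830, -2.753, 1.457, 0.659, -1.403), "three_band"),
    "oc4v6": EmpiricalCoefficients(
        "oc4v6", (0.366, -3.067, 1.930, 0.649, -1.532), "four_band"),
    "oc4l": EmpiricalCoefficients(
        "oc4l", (0.592, -3.607), "four_band"),
    "oc3m_mod": EmpiricalCoefficients(
        "oc3m_mod", (-0.32, -2.33, 4.02, -31.64, 48.54), "three_band"),
    "oc4v6_mod": EmpiricalCoefficients(
        "oc4v6_mod", (-0.35, -1.52, -2.44, -12.80, 30.48), "four_band"),
}

_SCHEME_BANDS = {
    "three_band": ((443.0, MODIS_BLUE), MODIS_GREEN),
    "four_band": ((443.0, 490.0, 510.0), 555.0),
}


def max_band_ratio(bands: BandSet, scheme: str) -> float:
    """log10 of the maximum blue-to-green band ratio of the scheme.

    Non-positive numerator bands are excluded from the maximum; a
    non-positive denominator, or no usable numerator, is an error.
    """
    numerators, denominator = _SCHEME_BANDS[scheme]
    denom = bands.get(denominator)
    if denom is None or not np.isfinite(denom) or denom <= 0:
        raise ValueError(f"denominator band {denominator:g} nm missing or non-positive")
    ratios = [
        bands.get(b) / denom
        for b in numerators
        if bands.get(b) is not None and np.isfinite(bands.get(b)) and bands.get(b) > 0
    ]
    if not ratios:
        raise ValueError("no positive numerator band available for the band ratio")
    return float(np.log10(max(ratios)))


def chl_empirical(r: float, coeffs: EmpiricalCoefficients) -> float:
    """Chl-a (mg m^-3) = 10**polynomial(R), capped at 1000 with a warning."""
    exponent = sum(c * r**i for i, c in enumerate(coeffs.coefficients))
    # guard 10**x overflow for wild band ratios
    if exponent > 300:
        chl = np.inf
    else:
        chl = 10.0**exponent
    if chl > CHL_CAP:
        warnings.warn(
            f"{coeffs.name}: retrieval {chl:.3g} mg m^-3 capped at {CHL_CAP:g}",
            stacklevel=2,
        )
        return CHL_CAP
    return float(chl)


def chl_from_bands(bands: BandSet, algorithm: str) -> float:
    """Convenience: maximum band ratio + polynomial for a named algorithm."""
    coeffs = EMPIRICAL_ALGORITHMS[algorithm]
    return chl_empirical(max_band_ratio(bands, coeffs.scheme), coeffs)


def turbidity_flag(bands: BandSet) -> bool | None:
    """True if Rrs at the red reference band strictly exceeds 0.00042 sr^-1.

    Returns None (indeterminate) if the red band is unavailable.
    """
    red = bands.get(TURBIDITY_BAND)
    if red is None or not np.isfinite(red):
        return None
    return bool(red > TURBIDITY_THRESHOLD)


# ---------------------------------------------------------------------------
# Pure-water IOPs and the phytoplankton basis shape (configuration tables)
# ---------------------------------------------------------------------------

#: Pure-water absorption (m^-1) at 10 nm steps, 400-700 nm (standard
#: laboratory values; interpolated linearly in between).
_WATER_ABS_WL = np.arange(400.0, 701.0, 10.0)
_WATER_ABS = np.array([
    0.00663, 0.00473, 0.00454, 0.00495, 0.00635, 0.00922, 0.00979, 0.0106,
    0.0127, 0.0150, 0.0204, 0.0325, 0.0409, 0.0434, 0.0474, 0.0565,
    0.0619, 0.0695, 0.0896, 0.1351, 0.2224, 0.2644, 0.2755, 0.2916,
    0.3108, 0.340, 0.410, 0.439, 0.465, 0.516, 0.624,
])


def water_absorption(wavelength_nm) -> np.ndarray:
    """Pure-water absorption coefficient a_w(lambda), m^-1."""
    return np.interp(np.asarray(wavelength_nm, dtype=float), _WATER_ABS_WL, _WATER_ABS)


def water_backscatter(wavelength_nm) -> np.ndarray:
    """Pure seawater backscattering b_bw(lambda) = 0.0038 (400/lambda)^4.32, m^-1."""
    wl = np.asarray(wavelength_nm, dtype=float)
    return 0.0038 * (400.0 / wl) ** 4.32


#: Normalized phytoplankton absorption basis (Bricaud-class shape), unity at
#: 443 nm: a blue absorption maximum, a green-yellow minimum and a secondary
#: red Chl-a peak near 675 nm.
_APH_SHAPE_WL = np.array([
    400.0, 412.0, 425.0, 443.0, 455.0, 470.0, 490.0, 510.0, 530.0, 555.0,
    580.0, 600.0, 620.0, 640.0, 660.0, 670.0, 675.0, 686.0, 700.0,
])
_APH_SHAPE = np.array([
    0.69, 0.79, 0.90, 1.00, 0.95, 0.85, 0.65, 0.45, 0.30, 0.18,
    0.14, 0.12, 0.12, 0.13, 0.22, 0.28, 0.32, 0.22, 0.06,
])


def aph_basis_shape(wavelength_nm) -> np.ndarray:
    """Normalized aph basis vector, aph_shape(443) = 1 exactly."""
    return np.interp(np.asarray(wavelength_nm, dtype=float), _APH_SHAPE_WL, _APH_SHAPE)


# ---------------------------------------------------------------------------
# GIOP-class semi-analytical inversion
# ---------------------------------------------------------------------------

@dataclass
class GIOPConfig:
    """Configuration of the semi-analytical forward/inverse model.

    Defaults are the standard GIOP settings: S_dg = 0.018 nm^-1, eta = 1,
    Gordon quadratic coefficients g1 = 0.0949, g2 = 0.0794, a Bricaud-shaped
    aph basis normalized at 443 nm and standard pure-water IOP tables.
    """

    sdg_per_nm: float = 0.018
    eta: float = 1.0
    g1: float = 0.0949
    g2: float = 0.0794
    chl_factor: float = CHL_FACTOR
    aph_shape: object = None          # callable wavelength -> normalized shape
    water_absorption: object = None   # callable wavelength -> a_w (m^-1)
    water_backscatter: object = None  # callable wavelength -> b_bw (m^-1)
    initial_guess: tuple[float, float, float] = (0.01, 0.1, 0.001)
    xtol: float = 1e-8
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if self.aph_shape is None:
            self.aph_shape = aph_basis_shape
        if self.water_absorption is None:
            self.water_absorption = water_absorption
        if self.water_backscatter is None:
            self.water_backscatter = water_backscatter
        if abs(float(np.asarray(self.aph_shape(443.0))) - 1.0) > 1e-9:
            raise ValueError("aph_shape must equal 1 at 443 nm")
        if self.chl_factor <= 0:
            raise ValueError("chl_factor must be positive")


@dataclass
class InversionResult:
    """Retrieved eigenvalues and diagnostics of one spectral-matching fit."""

    aph443: float
    adg443: float
    bbp555: float
    chl: float
    residual_rms: float
    converged: bool
    iterations: int
    station_id: str | None = None


def giop_forward(
    aph443: float,
    adg443: float,
    bbp555: float,
    config: GIOPConfig | None = None,
    wavelengths_nm=OPERATIONAL_BANDS,
) -> np.ndarray:
    """Above-surface Rrs (sr^-1) from the three eigenvalues.

    a(l) = a_w + aph443 * shape(l) + adg443 * exp(-S_dg (l - 443));
    b_b(l) = b_bw + bbp555 * (555/l)**eta; u = b_b / (a + b_b);
    rrs- = g1 u + g2 u^2; Rrs = 0.52 rrs- / (1 - 1.7 rrs-).
    """
    if config is None:
        config = GIOPConfig()
    if aph443 < 0 or adg443 < 0 or bbp555 < 0:
        raise ValueError("eigenvalues must be non-negative")
    wl = np.asarray(wavelengths_nm, dtype=float)
    a = (
        config.water_absorption(wl)
        + aph443 * config.aph_shape(wl)
        + adg443 * np.exp(-config.sdg_per_nm * (wl - 443.0))
    )
    bb = config.water_backscatter(wl) + bbp555 * (555.0 / wl) ** config.eta
    u = bb / (a + bb)
    rrs_sub = config.g1 * u + config.g2 * u**2
    return 0.52 * rrs_sub / (1.0 - 1.7 * rrs_sub)


def giop_invert(
    bands: BandSet, config: GIOPConfig | None = None
) -> InversionResult:
    """Fit the forward model to band Rrs by bounded nonlinear least squares.

    Needs at least 4 valid (finite, positive) operational bands. Returns the
    eigenvalues with Chl-a = aph(443) / 0.055, the RMS spectral residual and a
    convergence flag; non-convergence is reported, not raised.
    """
    if config is None:
        config = GIOPConfig()
    wl, rrs = [], []
    for b in OPERATIONAL_BANDS:
        v = bands.get(b)
        if v is not None and np.isfinite(v) and v > 0:
            wl.append(b)
            rrs.append(v)
    if len(wl) < 4:
        raise ValueError(f"need >= 4 valid bands for inversion, got {len(wl)}")
    wl = np.asarray(wl)
    rrs = np.asarray(rrs)

    def residuals(p):
        return giop_forward(p[0], p[1], p[2], config, wl) - rrs

    fit = least_squares(
        residuals,
        x0=np.asarray(config.initial_guess, dtype=float),
        bounds=(0.0, np.inf),
        xtol=config.xtol,
        ftol=config.xtol,
        gtol=None,
        max_nfev=config.max_iterations,
    )
    aph443, adg443, bbp555 = (float(v) for v in fit.x)
    return InversionResult(
        aph443=aph443,
        adg443=adg443,
        bbp555=bbp555,
        chl=chl_from_aph(aph443, config.chl_factor),
        residual_rms=float(np.sqrt(np.mean(fit.fun**2))),
        converged=bool(fit.success),
        iterations=int(fit.nfev),
        station_id=bands.station_id,
    )


def chl_from_aph(aph443: float, factor: float = CHL_FACTOR) -> float:
    """Chl-a (mg m^-3) from aph(443) via the fixed conversion factor."""
    if factor <= 0:
        raise ValueError("chl factor must be positive")
    if aph443 < 0:
        raise ValueError("aph(443) must be non-negative")
    return float(aph443 / factor)


# ---------------------------------------------------------------------------
# GSM-style NAP/CDOM partition of adg
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GSMMatsuokaConfig:
    """NAP parametrization splitting adg(443) via bbp(555).

    ``k_nap`` is the NAP absorption at 443 nm per unit bbp(555); the default
    0 is an explicit pass-through (all of adg attributed to CDOM) until a
    regional coefficient is configured.
    """

    k_nap: float = 0.0
    s_nap_per_nm: float = 0.011

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_nap) or self.k_nap < 0:
            raise ValueError("k_nap must be finite and non-negative")


def gsm_matsuoka_partition(
    adg443: float, bbp555: float, config: GSMMatsuokaConfig | None = None
) -> tuple[float, float]:
    """Split adg(443) into (anap443, acdom443) via the bbp-based NAP model.

    anap443 = min(k_nap * bbp555, adg443); acdom443 is the remainder, so the
    partition conserves adg exactly.
    """
    if config is None:
        config = GSMMatsuokaConfig()
    if adg443 < 0 or bbp555 < 0:
        raise ValueError("adg443 and bbp555 must be non-negative")
    anap443 = min(config.k_nap * bbp555, adg443)
    return float(anap443), float(adg443 - anap443)
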