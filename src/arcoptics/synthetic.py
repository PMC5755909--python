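"""Synthetic cruise generator.

Emulates the statistical structure of a central-eastern Arctic surface
bio-optics survey: seven station clusters with prescribed means, standard
deviations and station counts for temperature, salinity, a_CDOM(443),
a_NAP(443) and a_ph(443); Chl-a tied to a_ph(443) through the regional power
law aph(443) = 0.0513 Chl^0.6675 (so Chl covaries with phytoplankton
absorption but not with CDOM); exponential CDOM/NAP absorption spectra and a
Bricaud-shaped phytoplankton spectrum; hyperspectral Rrs produced by the same
semi-analytical forward operator the inversion assumes; and exponentially
attenuated Ed/Lu depth profiles with optional multiplicative noise.

All randomness flows from one cruise-level seed; there is no hidden global
state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .absorption import APH443_CHL_POWER_LAW
from .ocean_color import GIOPConfig, giop_forward
from .radiometry import RRS_TRANSFER
from .spectra import Spectrum

#: Hyperspectral grid of the generator (nm).
FULL_GRID = np.arange(400.0, 701.0)


@dataclass(frozen=True)
class ProvinceDefinition:
    """Per-cluster mean/SD of the five environmental variables plus count."""

    name: str
    temperature_c: tuple[float, float]
    salinity: tuple[float, float]
    acdom443: tuple[float, float]
    anap443: tuple[float, float]
    aph443: tuple[float, float]
    count: int
    area: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("province needs at least one station")
        for f in ("temperature_c", "salinity", "acdom443", "anap443", "aph443"):
            if getattr(self, f)[1] < 0:
                raise ValueError(f"{f} SD must be non-negative")


#: The seven environmental clusters of the study region (mean, SD, n):
#: Laptev Sea Shelf (Lena-influenced), Transpolar Drift (2, 5), Beaufort
#: Gyre, Eurasian Basin (4, 7) and the pelagic Laptev Sea.
_TABLE_PROVINCES = (
    ProvinceDefinition("cluster1", (2.95, 0.15), (25.2, 2.1), (1.04, 0.15), (0.04, 0.001), (0.02, 0.001), 2, "LSS"),
    ProvinceDefinition("cluster2", (-1.54, 0.05), (29.2, 1.0), (0.45, 0.08), (0.003, 0.002), (0.01, 0.002), 10, "TPD"),
    ProvinceDefinition("cluster3", (-1.47, 0.03), (28.9, 0.1), (0.09, 0.05), (0.002, 0.0004), (0.006, 0.001), 6, "BG"),
    ProvinceDefinition("cluster4", (-1.71, 0.03), (32.9, 0.4), (0.16, 0.12), (0.001, 0.001), (0.01, 0.004), 5, "EB"),
    ProvinceDefinition("cluster5", (-1.55, 0.23), (31.0, 0.5), (0.19, 0.11), (0.005, 0.002), (0.02, 0.004), 16, "TPD"),
    ProvinceDefinition("cluster6", (0.99, 0.80), (30.7, 0.2), (0.23, 0.13), (0.01, 0.003), (0.02, 0.005), 11, "LS"),
    ProvinceDefinition("cluster7", (-1.66, 0.14), (32.4, 0.5), (0.09, 0.06), (0.005, 0.003), (0.04, 0.01), 12, "EB"),
)


def default_provinces() -> list[ProvinceDefinition]:
    """The seven study-region clusters (62 stations in total)."""
    return list(_TABLE_PROVINCES)


@dataclass
class ForwardConfig:
    """Spectral shapes and couplings of the generator.

    CDOM and NAP absorption decay exponentially from their 443 nm anchors
    with slopes ``s_cdom_per_nm`` / ``s_nap_per_nm``; particulate backscatter
    is tied linearly to NAP absorption, bbp555 = c_b * anap443 + b0, so the
    NAP/CDOM partition has recoverable structure. ``kd_mu`` is the mean
    cosine converting total attenuance to diffuse attenuation in the profile
    model. Noise levels are multiplicative lognormal sigmas.
    """

    s_cdom_per_nm: float = 0.018
    s_nap_per_nm: float = 0.011
    c_b: float = 0.5
    b0: float = 5e-4
    kd_mu: float = 0.75
    ed0: float = 1.2  # flat surface irradiance, W m^-2 nm^-1
    records_per_stop: int = 3
    rrs_noise: float = 0.0
    profile_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.s_cdom_per_nm <= 0 or self.s_nap_per_nm <= 0:
            raise ValueError("spectral slopes must be positive")


@dataclass
class SyntheticStation:
    """One generated station: environmental values, pigment and spectra."""

    station_id: str
    province: str
    lat: float
    lon: float
    temperature_c: float
    salinity: float
    acdom443: float
    anap443: float
    aph443: float
    chl_mg_m3: float
    acdom: Spectrum | None = None
    anap: Spectrum | None = None
    aph: Spectrum | None = None
    bbp555: float | None = None
    rrs: Spectrum | None = None

    @property
    def adg443(self) -> float:
        return self.acdom443 + self.anap443


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw rejected-and-resampled until strictly positive."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated-normal sampling failed to find a positive draw")


def sample_cruise(
    provinces: list[ProvinceDefinition] | None = None,
    seed: int | None = None,
    sd_scale: float = 1.0,
) -> list[SyntheticStation]:
    """Draw a synthetic cruise: per province, ``count`` independent stations.

    Temperature and salinity are Gaussian; the three absorption anchors are
    truncated Gaussian (strictly positive). Chl-a is derived from aph(443) by
    inverting the regional power law, chl = (aph443 / 0.0513)**(1 / 0.6675),
    which reproduces the key structural fact that Chl covaries with
    phytoplankton absorption but not with CDOM.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic sampling")
    if sd_scale < 0:
        raise ValueError("sd_scale must be non-negative")
    if provinces is None:
        provinces = default_provinces()
    coeff, expo = APH443_CHL_POWER_LAW
    rng = np.random.default_rng(seed)
    stations: list[SyntheticStation] = []
    i = 0
    for p_idx, prov in enumerate(provinces):
        for _ in range(prov.count):
            i += 1
            t = float(rng.normal(prov.temperature_c[0], sd_scale * prov.temperature_c[1]))
            s = float(rng.normal(prov.salinity[0], sd_scale * prov.salinity[1]))
            acdom = _truncated_normal(rng, prov.acdom443[0], sd_scale * prov.acdom443[1])
            anap = _truncated_normal(rng, prov.anap443[0], sd_scale * prov.anap443[1])
            aph = _truncated_normal(rng, prov.aph443[0], sd_scale * prov.aph443[1])
            chl = float((aph / coeff) ** (1.0 / expo))
            stations.append(
                SyntheticStation(
                    station_id=f"S{i:03d}",
                    province=prov.name,
                    lat=float(76.0 + p_idx + rng.uniform(0, 1)),
                    lon=float(30.0 + 15 * p_idx + rng.uniform(0, 5)),
                    temperature_c=t,
                    salinity=s,
                    acdom443=acdom,
                    anap443=anap,
                    aph443=aph,
                    chl_mg_m3=chl,
                )
            )
    return stations


def build_spectra(
    station: SyntheticStation, config: ForwardConfig | None = None,
    giop_config: GIOPConfig | None = None,
) -> SyntheticStation:
    """Attach full 400-700 nm constituent spectra and bbp(555) to a station.

    a_CDOM(l) = acdom443 exp(-s_cdom (l - 443)); a_NAP analogous with s_nap;
    a_ph(l) = aph443 * normalized basis shape; bbp555 = c_b * anap443 + b0.
    """
    if config is None:
        config = ForwardConfig()
    if giop_config is None:
        giop_config = GIOPConfig()
    wl = FULL_GRID
    station.acdom = Spectrum(wl, station.acdom443 * np.exp(-config.s_cdom_per_nm * (wl - 443.0)), "acdom")
    station.anap = Spectrum(wl, station.anap443 * np.exp(-config.s_nap_per_nm * (wl - 443.0)), "anap")
    station.aph = Spectrum(wl, station.aph443 * np.asarray(giop_config.aph_shape(wl)), "aph")
    station.bbp555 = float(config.c_b * station.anap443 + config.b0)
    return station


def forward_rrs(
    station: SyntheticStation,
    giop_config: GIOPConfig | None = None,
    config: ForwardConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Hyperspectral Rrs from the semi-analytical forward operator.

    The generator and the inversion share one operator: the station enters
    through its eigenvalues (aph443, adg443 = acdom443 + anap443, bbp555).
    Optional multiplicative lognormal noise requires an explicit generator.
    """
    if giop_config is None:
        giop_config = GIOPConfig()
    if config is None:
        config = ForwardConfig()
    if station.bbp555 is None:
        build_spectra(station, config, giop_config)
    rrs = giop_forward(station.aph443, station.adg443, station.bbp555, giop_config, FULL_GRID)
    if config.rrs_noise > 0:
        if rng is None:
            raise ValueError("noisy Rrs generation requires an explicit rng")
        rrs = rrs * np.exp(rng.normal(0.0, config.rrs_noise, size=rrs.size))
    station.rrs = Spectrum(FULL_GRID.copy(), rrs, "rrs")
    return station.rrs


def forward_profile(
    station: SyntheticStation,
    config: ForwardConfig | None = None,
    giop_config: GIOPConfig | None = None,
    depth_max: float = 100.0,
    wavelength_step: float = 5.0,
    rng: np.random.Generator | None = None,
    inclination_deg: float | None = None,
) -> pd.DataFrame:
    """Raw radiometric records for one station (long format).

    Kd(l) = (a_total(l) + b_b(l)) / kd_mu with the operator's IOPs;
    Ed(l, z) = Ed0 exp(-Kd z); Lu(l, z) = Rrs(l) Ed(l, z) / 0.519 with
    Ku = Kd, so the measured-data radiometric chain reproduces the generating
    Rrs exactly in the noise-free case. Inclination defaults to a small
    jitter (or zero without an rng); pass ``inclination_deg`` to inject QC
    failures.
    """
    if config is None:
        config = ForwardConfig()
    if giop_config is None:
        giop_config = GIOPConfig()
    if station.rrs is None:
        forward_rrs(station, giop_config, config, rng=None)
    wl = np.arange(400.0, 700.0 + wavelength_step, wavelength_step)
    a = (
        giop_config.water_absorption(wl)
        + station.aph443 * giop_config.aph_shape(wl)
        + station.adg443 * np.exp(-giop_config.sdg_per_nm * (wl - 443.0))
    )
    bb = giop_config.water_backscatter(wl) + station.bbp555 * (555.0 / wl) ** giop_config.eta
    kd = (a + bb) / config.kd_mu
    rrs = station.rrs.at(wl)
    ed0 = config.ed0
    lu0 = rrs * ed0 / RRS_TRANSFER

    # One stop per depth bin (5 m bins to 30 m, 10 m below), several records
    # per stop, mirroring the at-depth stops of a profiling radiometer cast.
    stops = np.concatenate([
        np.arange(2.5, 30.0, 5.0),
        np.arange(35.0, depth_max, 10.0),
    ])
    depths = np.repeat(stops, config.records_per_stop)
    rows = []
    for z in depths:
        if inclination_deg is not None:
            inc = float(inclination_deg)
        elif rng is not None:
            inc = float(rng.uniform(0.0, 10.0))
        else:
            inc = 0.0
        ed = ed0 * np.exp(-kd * z)
        lu = lu0 * np.exp(-kd * z)
        if config.profile_noise > 0:
            if rng is None:
                raise ValueError("noisy profile generation requires an explicit rng")
            ed = ed * np.exp(rng.normal(0.0, config.profile_noise, size=ed.size))
            lu = lu * np.exp(rng.normal(0.0, config.profile_noise, size=lu.size))
        rows.append(
            pd.DataFrame(
                {
                    "station_id": station.station_id,
                    "depth_m": z,
                    "inclination_deg": inc,
                    "wavelength_nm": wl,
                    "ed": ed,
                    "lu": lu,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def expected_kd(
    station: SyntheticStation,
    wavelength_nm,
    config: ForwardConfig | None = None,
    giop_config: GIOPConfig | None = None,
) -> np.ndarray:
    """The Kd(lambda) the profile generator uses, for closure checks."""
    if config is None:
        config = ForwardConfig()
    if giop_config is None:
        giop_config = GIOPConfig()
    wl = np.asarray(wavelength_nm, dtype=float)
    a = (
        giop_config.water_absorption(wl)
        + station.aph443 * giop_config.aph_shape(wl)
        + station.adg443 * np.exp(-giop_config.sdg_per_nm * (wl - 443.0))
    )
    bb = giop_config.water_backscatter(wl) + station.bbp555 * (555.0 / wl) ** giop_config.eta
    return (a + bb) / config.kd_mu


def cruise_to_frame(stations: list[SyntheticStation]) -> pd.DataFrame:
    """Station summary table (one row per station)."""
    return pd.DataFrame(
        {
            "station_id": [s.station_id for s in stations],
            "lat": [s.lat for s in stations],
            "lon": [s.lon for s in stations],
            "temperature_c": [s.temperature_c for s in stations],
            "salinity": [s.salinity for s in stations],
            "chl_mg_m3": [s.chl_mg_m3 for s in stations],
            "acdom443": [s.acdom443 for s in stations],
            "anap443": [s.anap443 for s in stations],
            "aph443": [s.aph443 for s in stations],
            "province": [s.province for s in stations],
        }
    )
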