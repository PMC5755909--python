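"""In-water radiometric profiles to remote-sensing reflectance.

Depth profiles of downwelling irradiance Ed(lambda, z) and upwelling radiance
Lu(lambda, z) are quality-controlled on sensor inclination, depth-binned,
regressed in log space over a fixed depth window to obtain the diffuse
attenuation coefficients Kd and Ku, extrapolated to just below the surface,
and propagated through the air-sea interface with a flat transfer coefficient
of 0.519 to give Rrs(lambda) = 0.519 * Lu-(lambda, 0) / Ed-(lambda, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum

#: Records with tilt at or above this are excluded from all computations (deg).
MAX_INCLINATION_DEG = 14.0

#: Depth window used for the attenuation regressions (m, positive down).
DEFAULT_Z_RANGE = (10.0, 30.0)

#: Upper limit of the fine (5 m) binning region; 10 m bins below (m).
FINE_BIN_LIMIT = 30.0
FINE_BIN_WIDTH = 5.0
COARSE_BIN_WIDTH = 10.0

#: Water-air transfer coefficient applied to subsurface Lu/Ed.
RRS_TRANSFER = 0.519

#: Required columns of the long-format profile table.
PROFILE_COLUMNS = ("station_id", "depth_m", "inclination_deg", "wavelength_nm", "ed", "lu")


class RadiometryQCError(ValueError):
    """Raised when quality control leaves no usable radiometric data."""


@dataclass
class RadiometricProfile:
    """Depth-binned Ed/Lu profile for one station.

    ``ed`` and ``lu`` are (n_depths, n_wavelengths) arrays; ``depths_m`` holds
    bin centres (mean depth of the surviving records in each bin), positive
    down with 0 at the surface.
    """

    station_id: str
    wavelengths_nm: np.ndarray
    depths_m: np.ndarray
    ed: np.ndarray
    lu: np.ndarray
    n_rejected_inclination: int = 0
    qc_flags: dict = field(default_factory=dict)


@dataclass
class AttenuationResult:
    """Per-wavelength Kd/Ku regression results over a depth window.

    ``ln_ed0`` / ``ln_lu0`` are the regression intercepts at z = 0 (the log of
    the extrapolated subsurface values). Wavelengths with fewer than 3 usable
    bins are NaN.
    """

    wavelengths_nm: np.ndarray
    kd: np.ndarray
    ku: np.ndarray
    ln_ed0: np.ndarray
    ln_lu0: np.ndarray
    fit_r2_ed: np.ndarray
    fit_r2_lu: np.ndarray
    n_points: np.ndarray
    z_range: tuple[float, float] = DEFAULT_Z_RANGE
    n_negative_dropped: int = 0

    def kd_spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.kd)
        return self.wavelengths_nm[ok], self.kd[ok]


@dataclass
class SubsurfaceOptics:
    """Extrapolated subsurface Ed-(lambda, 0 m) and Lu-(lambda, 0 m)."""

    station_id: str
    wavelengths_nm: np.ndarray
    ed0: np.ndarray
    lu0: np.ndarray


def _bin_edges(max_depth: float) -> np.ndarray:
    fine = np.arange(0.0, FINE_BIN_LIMIT + FINE_BIN_WIDTH, FINE_BIN_WIDTH)
    if max_depth <= FINE_BIN_LIMIT:
        return fine
    coarse = np.arange(
        FINE_BIN_LIMIT + COARSE_BIN_WIDTH,
        max_depth + COARSE_BIN_WIDTH,
        COARSE_BIN_WIDTH,
    )
    return np.concatenate([fine, coarse])


def bin_profile(
    records: pd.DataFrame, max_inclination_deg: float = MAX_INCLINATION_DEG
) -> RadiometricProfile:
    """Inclination QC and depth binning of raw radiometric records.

    Records with inclination >= ``max_inclination_deg`` are removed; the rest
    are averaged in 5 m bins over 0-30 m and 10 m bins below. The reported bin
    centre is the mean depth of the records in the bin, so that noise-free
    exponential profiles regress identically before and after binning.
    """
    missing = [c for c in PROFILE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    stations = records["station_id"].unique()
    if len(stations) != 1:
        raise ValueError("bin_profile expects records from a single station")
    station_id = str(stations[0])

    keep = records[records["inclination_deg"] < max_inclination_deg]
    n_rejected = int(
        records[["depth_m", "inclination_deg"]].drop_duplicates().shape[0]
        - keep[["depth_m", "inclination_deg"]].drop_duplicates().shape[0]
    )
    if keep.empty:
        raise RadiometryQCError(
            f"station {station_id}: no records below {max_inclination_deg} deg inclination"
        )

    wavelengths = np.sort(keep["wavelength_nm"].unique())
    edges = _bin_edges(float(keep["depth_m"].max()))
    idx = np.digitize(keep["depth_m"].to_numpy(), edges) - 1

    keep = keep.assign(_bin=idx)
    grouped = keep.groupby("_bin")
    centers, ed_rows, lu_rows = [], [], []
    for _, g in sorted(grouped, key=lambda kv: kv[0]):
        centers.append(float(g["depth_m"].mean()))
        wide = g.pivot_table(index="wavelength_nm", values=["ed", "lu"], aggfunc="mean")
        wide = wide.reindex(wavelengths)
        ed_rows.append(wide["ed"].to_numpy())
        lu_rows.append(wide["lu"].to_numpy())

    return RadiometricProfile(
        station_id=station_id,
        wavelengths_nm=wavelengths.astype(float),
        depths_m=np.asarray(centers),
        ed=np.vstack(ed_rows),
        lu=np.vstack(lu_rows),
        n_rejected_inclination=n_rejected,
    )


def _fit_log_profile(z: np.ndarray, v: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of ln(v) on z. Returns (K, ln_v0, r2, n) with K = -slope."""
    ok = np.isfinite(v) & (v > 0)
    z, v = z[ok], v[ok]
    n = z.size
    if n < 3:
        return np.nan, np.nan, np.nan, n
    ln_v = np.log(v)
    slope, intercept = np.polyfit(z, ln_v, 1)
    pred = slope * z + intercept
    ss_res = float(np.sum((ln_v - pred) ** 2))
    ss_tot = float(np.sum((ln_v - ln_v.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return -float(slope), float(intercept), r2, n


def attenuation_coefficients(
    profile: RadiometricProfile, z_range: tuple[float, float] = DEFAULT_Z_RANGE
) -> AttenuationResult:
    """Diffuse attenuation Kd (from Ed) and Ku (from Lu) over a depth window.

    Per wavelength, Kd is minus the slope of the OLS regression of ln Ed on z
    restricted to bins inside ``z_range`` (default 10-30 m, avoiding the
    wave-affected upper metres); Ku analogously from Lu. Non-positive binned
    values are set missing before the log regression and counted.
    """
    z_lo, z_hi = z_range
    sel = (profile.depths_m >= z_lo) & (profile.depths_m <= z_hi)
    z = profile.depths_m[sel]
    n_wl = profile.wavelengths_nm.size
    kd = np.full(n_wl, np.nan)
    ku = np.full(n_wl, np.nan)
    ln_ed0 = np.full(n_wl, np.nan)
    ln_lu0 = np.full(n_wl, np.nan)
    r2_ed = np.full(n_wl, np.nan)
    r2_lu = np.full(n_wl, np.nan)
    n_points = np.zeros(n_wl, dtype=int)

    ed = profile.ed[sel]
    lu = profile.lu[sel]
    n_negative = int(np.sum(ed <= 0) + np.sum(lu <= 0))
    for j in range(n_wl):
        kd[j], ln_ed0[j], r2_ed[j], n_ed = _fit_log_profile(z, ed[:, j])
        ku[j], ln_lu0[j], r2_lu[j], n_lu = _fit_log_profile(z, lu[:, j])
        n_points[j] = min(n_ed, n_lu)

    if not np.any(np.isfinite(kd)):
        raise RadiometryQCError(
            f"station {profile.station_id}: no wavelength has >= 3 usable bins in "
            f"z = [{z_lo}, {z_hi}] m"
        )
    return AttenuationResult(
        wavelengths_nm=profile.wavelengths_nm.copy(),
        kd=kd, ku=ku, ln_ed0=ln_ed0, ln_lu0=ln_lu0,
        fit_r2_ed=r2_ed, fit_r2_lu=r2_lu, n_points=n_points,
        z_range=(float(z_lo), float(z_hi)),
        n_negative_dropped=n_negative,
    )


def extrapolate_surface(
    profile: RadiometricProfile, attenuation: AttenuationResult
) -> SubsurfaceOptics:
    """Subsurface Ed-(0 m) and Lu-(0 m) from the regression intercepts.

    The value at z = 0 of each log-linear fit uses all points of the depth
    window, consistent with the regression-based Kd/Ku.
    """
    return SubsurfaceOptics(
        station_id=profile.station_id,
        wavelengths_nm=attenuation.wavelengths_nm.copy(),
        ed0=np.exp(attenuation.ln_ed0),
        lu0=np.exp(attenuation.ln_lu0),
    )


def remote_sensing_reflectance(sub: SubsurfaceOptics) -> Spectrum:
    """Rrs(lambda) = 0.519 * Lu-(lambda, 0 m) / Ed-(lambda, 0 m), sr^-1.

    Wavelengths whose Ed-(0) is missing or non-positive are dropped from the
    output grid (a per-wavelength failure, not a station failure).
    """
    ok = np.isfinite(sub.ed0) & (sub.ed0 > 0) & np.isfinite(sub.lu0)
    if not np.any(ok):
        raise RadiometryQCError(
            f"station {sub.station_id}: no wavelength with positive subsurface Ed"
        )
    rrs = RRS_TRANSFER * sub.lu0[ok] / sub.ed0[ok]
    spec = Spectrum(sub.wavelengths_nm[ok], rrs, "rrs")
    if np.any(rrs < 0):
        spec.flags["negative_rrs"] = int(np.sum(rrs < 0))
    return spec


def process_profile(
    records: pd.DataFrame,
    z_range: tuple[float, float] = DEFAULT_Z_RANGE,
    max_inclination_deg: float = MAX_INCLINATION_DEG,
) -> tuple[RadiometricProfile, AttenuationResult, SubsurfaceOptics, Spectrum]:
    """Full radiometric chain: QC + binning -> Kd/Ku -> surface -> Rrs."""
    profile = bin_profile(records, max_inclination_deg=max_inclination_deg)
    att = attenuation_coefficients(profile, z_range=z_range)
    sub = extrapolate_surface(profile, att)
    rrs = remote_sensing_reflectance(sub)
    return profile, att, sub, rrs
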