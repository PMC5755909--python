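"""Delimited-text readers/writers, configuration and the pipeline driver.

All interchange formats are plain text: station summary tables and long
profile tables as CSV, spectra as wide CSV (first column ``wavelength_nm``,
one column per station) or long CSV (``station_id, constituent,
wavelength_nm, value``). Units are fixed by convention and embedded in the
column names: wavelengths nm, depths m positive down, absorption m^-1,
Rrs sr^-1, Chl-a mg m^-3.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, ocean_color, provinces, radiometry, synthetic
from .ocean_color import BandSet, GIOPConfig, GSMMatsuokaConfig
from .spectra import Spectrum
from .synthetic import ForwardConfig

STATION_COLUMNS = ("station_id", "lat", "lon", "temperature_c", "salinity", "chl_mg_m3")
NUMERIC_STATION_COLUMNS = ("lat", "lon", "temperature_c", "salinity", "chl_mg_m3")


class SchemaError(ValueError):
    """A file does not match the expected delimited-text schema."""


# ---------------------------------------------------------------------------
# Station tables
# ---------------------------------------------------------------------------

def read_station_table(path) -> pd.DataFrame:
    """Read a station summary CSV, validating headers and numeric cells.

    Malformed numeric cells are rejected with their 1-based file line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    numeric_cols = [
        c for c in df.columns
        if c in NUMERIC_STATION_COLUMNS or c.startswith(("a", "bbp", "temperature", "salinity", "chl"))
    ]
    for col in numeric_cols:
        raw = df[col].str.strip()
        parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = raw.index[(raw != "") & parsed.isna()]
        if len(bad):
            line = int(bad[0]) + 2  # header + 1-based
            raise SchemaError(f"{path}: non-numeric value {raw[bad[0]]!r} in column "
                              f"{col!r} at line {line}")
        df[col] = parsed
    return df


def write_station_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_wide_spectra(spectra: dict[str, Spectrum], path) -> None:
    """Wide CSV: first column wavelength_nm, one column per station.

    All spectra must share one wavelength grid.
    """
    ids = list(spectra)
    grid = spectra[ids[0]].wavelengths_nm
    for sid in ids[1:]:
        if not np.array_equal(spectra[sid].wavelengths_nm, grid):
            raise SchemaError("wide format requires a shared wavelength grid")
    out = pd.DataFrame({"wavelength_nm": grid})
    for sid in ids:
        out[sid] = spectra[sid].values
    out.to_csv(path, index=False)


def read_wide_spectra(path, constituent: str) -> dict[str, Spectrum]:
    df = pd.read_csv(path)
    if "wavelength_nm" != df.columns[0]:
        raise SchemaError(f"{path}: first column must be 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return {
        sid: Spectrum(wl, df[sid].to_numpy(dtype=float), constituent)
        for sid in df.columns[1:]
    }


def write_long_spectra(spectra: dict[str, Spectrum], path) -> None:
    """Long CSV: station_id, constituent, wavelength_nm, value."""
    frames = [
        pd.DataFrame(
            {
                "station_id": sid,
                "constituent": s.constituent,
                "wavelength_nm": s.wavelengths_nm,
                "value": s.values,
            }
        )
        for sid, s in spectra.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_long_spectra(path) -> dict[str, dict[str, Spectrum]]:
    """Long CSV to nested {station_id: {constituent: Spectrum}}."""
    df = pd.read_csv(path)
    required = {"station_id", "constituent", "wavelength_nm", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: long spectra need columns {sorted(required)}")
    out: dict[str, dict[str, Spectrum]] = {}
    for (sid, tag), g in df.groupby(["station_id", "constituent"], sort=False):
        g = g.sort_values("wavelength_nm")
        out.setdefault(str(sid), {})[str(tag)] = Spectrum(
            g["wavelength_nm"].to_numpy(dtype=float),
            g["value"].to_numpy(dtype=float),
            str(tag),
        )
    return out


# ---------------------------------------------------------------------------
# Radiometric profiles
# ---------------------------------------------------------------------------

def read_profile_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in radiometry.PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing profile column(s) {missing}")
    return df


def write_profile_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to YAML."""

    seed: int = 1
    sd_scale: float = 1.0
    n_profile_stations: int = 16
    k_clusters: int = 7
    z_lo: float = 10.0
    z_hi: float = 30.0
    max_inclination_deg: float = 14.0
    log_space_mae: bool = False
    giop: dict = field(default_factory=dict)      # numeric GIOPConfig overrides
    gsm: dict = field(default_factory=dict)       # GSMMatsuokaConfig overrides
    forward: dict = field(default_factory=dict)   # ForwardConfig overrides

    _GIOP_KEYS = ("sdg_per_nm", "eta", "g1", "g2", "chl_factor", "xtol", "max_iterations")

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be at least 1")
        for key in self.giop:
            if key not in self._GIOP_KEYS:
                raise SchemaError(f"unknown giop config key {key!r}")
        for key in self.gsm:
            if key not in {f.name for f in dataclasses.fields(GSMMatsuokaConfig)}:
                raise SchemaError(f"unknown gsm config key {key!r}")
        for key in self.forward:
            if key not in {f.name for f in dataclasses.fields(ForwardConfig)}:
                raise SchemaError(f"unknown forward config key {key!r}")

    def giop_config(self) -> GIOPConfig:
        return GIOPConfig(**self.giop)

    def gsm_config(self) -> GSMMatsuokaConfig:
        return GSMMatsuokaConfig(**self.gsm)

    def forward_config(self) -> ForwardConfig:
        return ForwardConfig(**self.forward)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are named in the error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {unknown}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order on a synthetic cruise and write outputs.

    Stages: simulate -> write/read interchange files -> radiometry ->
    retrieval -> evaluation -> clustering. Returns (and writes) a JSON
    report carrying the seed, config hash, QC counts and summary statistics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    giop_cfg = config.giop_config()
    gsm_cfg = config.gsm_config()
    fwd_cfg = config.forward_config()
    rng = np.random.default_rng(config.seed)

    # --- stage 1: simulate -------------------------------------------------
    stations = synthetic.sample_cruise(seed=config.seed, sd_scale=config.sd_scale)
    for st in stations:
        synthetic.build_spectra(st, fwd_cfg, giop_cfg)
        synthetic.forward_rrs(st, giop_cfg, fwd_cfg, rng=rng)
    table = synthetic.cruise_to_frame(stations)
    write_station_table(table, outdir / "stations.csv")

    rrs_spectra = {st.station_id: st.rrs for st in stations}
    write_wide_spectra(rrs_spectra, outdir / "rrs.csv")

    step = max(1, len(stations) // config.n_profile_stations)
    profile_stations = stations[::step][: config.n_profile_stations]
    profile_frames = [
        synthetic.forward_profile(st, fwd_cfg, giop_cfg, rng=rng)
        for st in profile_stations
    ]
    write_profile_table(pd.concat(profile_frames, ignore_index=True),
                        outdir / "profiles.csv")

    # --- stage 2: radiometry (read back what was written) -------------------
    profiles = read_profile_table(outdir / "profiles.csv")
    rrs_from_profiles: dict[str, Spectrum] = {}
    qc_rejected = 0
    for sid, records in profiles.groupby("station_id"):
        prof, _, _, rrs = radiometry.process_profile(
            records,
            z_range=(config.z_lo, config.z_hi),
            max_inclination_deg=config.max_inclination_deg,
        )
        qc_rejected += prof.n_rejected_inclination
        rrs_from_profiles[str(sid)] = rrs

    # --- stage 3: retrieval --------------------------------------------------
    rows = []
    for st in stations:
        bands = BandSet.from_spectrum(st.rrs, station_id=st.station_id)
        turbid = ocean_color.turbidity_flag(bands)
        for name in ocean_color.EMPIRICAL_ALGORITHMS:
            rows.append({
                "station_id": st.station_id, "algorithm": name,
                "chl": ocean_color.chl_from_bands(bands, name),
                "turbid_flag": turbid,
            })
        inv = ocean_color.giop_invert(bands, giop_cfg)
        anap443, acdom443 = ocean_color.gsm_matsuoka_partition(
            inv.adg443, inv.bbp555, gsm_cfg)
        rows.append({
            "station_id": st.station_id, "algorithm": "giop",
            "chl": inv.chl, "aph443": inv.aph443, "adg443": inv.adg443,
            "acdom443": acdom443, "anap443": anap443, "bbp555": inv.bbp555,
            "converged": inv.converged, "turbid_flag": turbid,
        })
    retrievals = pd.DataFrame(rows)
    retrievals.to_csv(outdir / "retrievals.csv", index=False)

    # --- stage 4: evaluation -------------------------------------------------
    stats_rows = []
    chl_true = table.set_index("station_id")["chl_mg_m3"]
    for name, g in retrievals.groupby("algorithm"):
        g = g.set_index("station_id")
        pairs = evaluation.PairedRetrievals.from_arrays(
            g["chl"].to_numpy(), chl_true.loc[g.index].to_numpy(),
            label=f"{name}: Chl vs in-situ Chl")
        stats_rows.append(dataclasses.asdict(
            evaluation.evaluate(pairs, log_space_mae=config.log_space_mae)))
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(outdir / "evaluation.csv", index=False)

    # --- stage 5: clustering -------------------------------------------------
    env, n_dropped = provinces.build_environmental_matrix(table)
    z = provinces.znormalize(env)
    dend = provinces.hca(z)
    assignment = provinces.cut_clusters(dend, config.k_clusters)
    dend.merge_table().to_csv(outdir / "merge_table.csv", index=False)
    labels = pd.DataFrame({
        "station_id": assignment.station_ids,
        "cluster": assignment.labels,
    })
    labels.to_csv(outdir / "cluster_labels.csv", index=False)
    generating = provinces.ClusterAssignment(
        station_ids=list(env.index),
        labels=pd.factorize(table.set_index("station_id").loc[env.index, "province"])[0] + 1,
        k=len(table["province"].unique()),
    )
    ari = provinces.compare_clusterings(assignment, generating)
    coph = provinces.cophenetic_correlation(dend, z)

    report = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_stations": len(stations),
        "n_profiles": len(profile_stations),
        "qc_rejected_records": qc_rejected,
        "env_rows_dropped": n_dropped,
        "cophenetic_correlation": coph,
        "adjusted_rand_vs_generating": ari,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{time.strftime('%Y-%m-%dT%H:%M:%S')} seed={config.seed} "
            f"config={config_hash(config)} stations={len(stations)} "
            f"ari={ari:.3f} cophenetic={coph:.3f}\n"
        )
    return report
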