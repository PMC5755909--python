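"""Bio-optical province clustering.

Stations are grouped two ways: (i) hierarchical clustering (UPGMA average
linkage, Euclidean distance) of a z-normalized environmental matrix of
temperature, salinity, a_CDOM(443), a_NAP(443) and a_ph(443); and (ii) the
same clustering applied to second-derivative spectra of Rrs(lambda)/Rrs(555)
over 435-510 nm, which isolates curvature features of the blue-green
reflectance independent of overall magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kruskal
from sklearn.metrics import adjusted_rand_score

from .spectra import Spectrum

#: Columns of the environmental matrix, in canonical order.
ENV_VARIABLES = ("temperature_c", "salinity", "acdom443", "anap443", "aph443")

#: Consolidation of the seven environmental clusters into the five named
#: bio-optical provinces (analyst mapping, supplied as a constant):
#: Laptev Sea Shelf, Laptev Sea, Transpolar Drift, Beaufort Gyre,
#: Eurasian/Nansen Basin.
PROVINCE_CONSOLIDATION = {1: "LSS", 2: "TPD", 3: "BG", 4: "EB", 5: "TPD", 6: "LS", 7: "EB"}

#: Second-derivative defaults: normalization band, analysis range, smoothing
#: window (all nm).
RRS_NORM_BAND = 555.0
DERIV_RANGE = (435.0, 510.0)
DERIV_SMOOTH_NM = 27


@dataclass
class Dendrogram:
    """An agglomerative merge tree (scipy linkage matrix) plus leaf ids."""

    linkage: np.ndarray
    leaf_ids: list
    method: str = "average"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_table(self) -> pd.DataFrame:
        """Merge sequence as (step, left, right, height, size)."""
        z = self.linkage
        return pd.DataFrame(
            {
                "step": np.arange(1, z.shape[0] + 1),
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "height": z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) per station."""

    station_ids: list
    labels: np.ndarray
    k: int
    method: str = "hca-average-euclidean"


@dataclass
class DerivativeSpectra:
    """Per-station second-derivative of normalized Rrs over the analysis range."""

    station_ids: list
    wavelengths_nm: np.ndarray
    values: np.ndarray  # (n_stations, n_wavelengths)
    smooth_nm: int = DERIV_SMOOTH_NM
    norm_band_nm: float = RRS_NORM_BAND


# ---------------------------------------------------------------------------
# Environmental matrix
# ---------------------------------------------------------------------------

def build_environmental_matrix(stations: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Assemble the station x variable matrix, dropping incomplete rows.

    Returns the complete-case matrix (indexed by station_id) and the number
    of dropped stations.
    """
    missing = [c for c in ENV_VARIABLES if c not in stations.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    mat = stations.set_index("station_id")[list(ENV_VARIABLES)] if "station_id" in stations.columns else stations[list(ENV_VARIABLES)]
    complete = mat.dropna()
    return complete, int(len(mat) - len(complete))


def znormalize(matrix: pd.DataFrame, population_sd: bool = False) -> pd.DataFrame:
    """Column-wise z-scores: subtract the mean, divide by the SD.

    The sample SD (n-1 denominator) is the default; ``population_sd=True``
    switches to the n denominator. A zero-variance column is an error.
    """
    if len(matrix) < 2:
        raise ValueError("normalization needs at least 2 rows")
    ddof = 0 if population_sd else 1
    sd = matrix.std(ddof=ddof)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return (matrix - matrix.mean()) / sd


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hca(matrix) -> Dendrogram:
    """UPGMA (unweighted average linkage) on Euclidean distances."""
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    z = hierarchy.linkage(x, method="average", metric="euclidean")
    return Dendrogram(linkage=z, leaf_ids=ids)


def cophenetic_correlation(dendrogram: Dendrogram, matrix) -> float:
    """Pearson correlation of cophenetic vs original pairwise distances."""
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("cophenetic correlation needs at least 3 points")
    c, _ = hierarchy.cophenet(dendrogram.linkage, pdist(x))
    return float(c)


def cut_clusters(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the merge tree into exactly k groups.

    The number of provinces is an analyst choice, never inferred; an
    unreachable k (ties in merge heights, or k outside 1..n) is an error.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    labels = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise ValueError(f"cannot cut dendrogram into exactly {k} clusters")
    return ClusterAssignment(station_ids=list(dendrogram.leaf_ids), labels=labels, k=k)


def compare_clusterings(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Adjusted Rand index between two partitions of the same stations."""
    if list(a.station_ids) != list(b.station_ids):
        raise ValueError("clusterings cover different station sets")
    return float(adjusted_rand_score(a.labels, b.labels))


def kruskal_wallis(values: np.ndarray, labels: np.ndarray, cluster_a, cluster_b):
    """Kruskal-Wallis H test of one variable between two clusters (thin wrapper)."""
    va = np.asarray(values)[np.asarray(labels) == cluster_a]
    vb = np.asarray(values)[np.asarray(labels) == cluster_b]
    return kruskal(va, vb)


# ---------------------------------------------------------------------------
# Derivative spectroscopy of Rrs
# ---------------------------------------------------------------------------

def _boxcar_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar with a symmetrically shrunk window at the edges.

    The half-width at point i is min(h, i, n-1-i) with h = window // 2, so the
    window stays symmetric everywhere and affine signals pass through exactly.
    """
    n = values.size
    h = window // 2
    out = np.empty(n)
    for i in range(n):
        w = min(h, i, n - 1 - i)
        out[i] = values[i - w : i + w + 1].mean()
    return out


def second_derivative(
    wavelengths_nm: np.ndarray, values: np.ndarray, smooth_nm: int = DERIV_SMOOTH_NM
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed central second finite difference on a 1 nm grid.

    The band separation of the difference stencil equals the smoothing window;
    the derivative is reported only where the full stencil fits inside the
    grid. Constant and linear inputs give exactly zero.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if not np.allclose(np.diff(wl), 1.0):
        raise ValueError("second_derivative expects a 1 nm grid")
    s = _boxcar_smooth(np.asarray(values, dtype=float), smooth_nm)
    h = smooth_nm
    n = s.size
    if n <= 2 * h:
        raise ValueError("grid too short for the derivative stencil")
    idx = np.arange(h, n - h)
    d2 = (s[idx + h] - 2.0 * s[idx] + s[idx - h]) / float(h) ** 2
    return wl[idx], d2


def second_derivative_spectra(
    rrs_spectra: dict[str, Spectrum],
    band_range: tuple[float, float] = DERIV_RANGE,
    smooth_nm: int = DERIV_SMOOTH_NM,
    norm_band_nm: float = RRS_NORM_BAND,
) -> DerivativeSpectra:
    """Second derivative of Rrs(lambda)/Rrs(555) per station.

    Each spectrum is normalized by its value at the 555 nm reference band,
    interpolated to a 1 nm grid over the band-separation range (435-510 nm),
    boxcar-smoothed and differenced with a 27 nm stencil.
    """
    lo, hi = band_range
    grid = np.arange(lo, hi + 1.0)
    ids, rows = [], []
    out_wl = None
    for sid, rrs in rrs_spectra.items():
        norm = rrs.at(norm_band_nm)
        if norm <= 0:
            raise ValueError(f"station {sid}: Rrs({norm_band_nm:g}) <= 0")
        vals = rrs.at(grid) / norm
        wl_d, d2 = second_derivative(grid, vals, smooth_nm)
        out_wl = wl_d
        ids.append(sid)
        rows.append(d2)
    if not rows:
        raise ValueError("no spectra supplied")
    return DerivativeSpectra(
        station_ids=ids,
        wavelengths_nm=out_wl,
        values=np.vstack(rows),
        smooth_nm=smooth_nm,
        norm_band_nm=norm_band_nm,
    )


def aop_cluster(deriv: DerivativeSpectra) -> Dendrogram:
    """Hierarchical clustering of stations by their derivative spectra."""
    frame = pd.DataFrame(deriv.values, index=deriv.station_ids)
    return hca(frame)
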