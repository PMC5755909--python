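"""Clustering, cophenetic fidelity and derivative spectroscopy."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from arcoptics import synthetic
from arcoptics.provinces import (
    ClusterAssignment,
    aop_cluster,
    build_environmental_matrix,
    compare_clusterings,
    cophenetic_correlation,
    cut_clusters,
    hca,
    kruskal_wallis,
    second_derivative,
    second_derivative_spectra,
    znormalize,
)
from arcoptics.synthetic import SyntheticStation


# -- O(n^3) naive agglomeration oracle (explicit loops) -----------------------

def naive_upgma(points):
    """Average-linkage agglomeration by exhaustive search.

    Returns (merge heights in order, full cophenetic matrix).
    """
    pts = [list(map(float, p)) for p in points]
    n = len(pts)

    def dist(i, j):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(pts[i], pts[j])))

    base = [[dist(i, j) for j in range(n)] for i in range(n)]
    clusters = {i: [i] for i in range(n)}
    coph = [[0.0] * n for _ in range(n)]
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = sum(base[p][q] for p in clusters[a] for q in clusters[b])
            d /= len(clusters[a]) * len(clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for p in clusters[a]:
            for q in clusters[b]:
                coph[p][q] = coph[q][p] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights, coph


def scipy_cophenetic_matrix(dend, n):
    from scipy.cluster.hierarchy import cophenet

    condensed = cophenet(dend.linkage)
    out = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = condensed[k]
            k += 1
    return out


# -- exhaustive adjusted Rand oracle ------------------------------------------

def naive_ari(a, b):
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and not sb
        n01 += (not sa) and sb
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


class TestZNormalize:
    def test_hand_z_scores(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 9.0]})
        z = znormalize(m)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])
        assert z.mean().abs().max() < 1e-12
        np.testing.assert_allclose(z.std(ddof=1), 1.0)

    def test_population_sd_option(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = znormalize(m, population_sd=True)
        np.testing.assert_allclose(z["a"], np.array([-1, 0, 1]) * np.sqrt(1.5))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        z = znormalize(m)
        np.testing.assert_allclose(znormalize(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            znormalize(m)


class TestHCA:
    def test_three_point_hand_case(self):
        # collinear points at 0, 1, 3: pair distances {1, 2, 3};
        # UPGMA merges at 1, then at (2 + 3) / 2 = 2.5
        dend = hca(np.array([[0.0], [1.0], [3.0]]))
        np.testing.assert_allclose(dend.linkage[:, 2], [1.0, 2.5])

    def test_duplicated_points_merge_at_zero(self):
        dend = hca(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert dend.linkage[0, 2] == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_oracle_on_random_6_point_instances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        dend = hca(pts)
        heights, coph = naive_upgma(pts)
        np.testing.assert_allclose(dend.linkage[:, 2], heights, atol=1e-10)
        np.testing.assert_allclose(scipy_cophenetic_matrix(dend, 6), coph, atol=1e-10)

    def test_two_blobs_top_split(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(8, 0.2, (10, 2))])
        labels = cut_clusters(hca(pts), 2).labels
        truth = np.array([0] * 10 + [1] * 10)
        assert naive_ari(labels, truth) == 1.0


class TestCophenetic:
    def ultrametric_points(self):
        # two tight pairs, all cross distances equal: exactly ultrametric
        L = 3.0
        return np.array(
            [
                [0.0, 0.5, 0.0],
                [0.0, -0.5, 0.0],
                [L, 0.0, 0.5],
                [L, 0.0, -0.5],
            ]
        )

    def test_ultrametric_input_gives_one(self):
        pts = self.ultrametric_points()
        assert cophenetic_correlation(hca(pts), pts) == pytest.approx(1.0, abs=1e-12)

    def test_four_point_case_against_enumeration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(4, 2))
        dend = hca(pts)
        _, coph = naive_upgma(pts)
        # Pearson correlation by explicit enumeration of the 6 pairs
        orig, cop = [], []
        for i, j in itertools.combinations(range(4), 2):
            orig.append(math.dist(pts[i], pts[j]))
            cop.append(coph[i][j])
        r = np.corrcoef(orig, cop)[0, 1]
        assert cophenetic_correlation(dend, pts) == pytest.approx(r, abs=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        c1 = cophenetic_correlation(hca(pts), pts)
        perm = rng.permutation(8)
        c2 = cophenetic_correlation(hca(pts[perm]), pts[perm])
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_too_few_points(self):
        pts = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            cophenetic_correlation(hca(pts), pts)


class TestCutClusters:
    def test_k_equals_n_and_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        dend = hca(pts)
        assert len(set(cut_clusters(dend, 6).labels)) == 6
        assert len(set(cut_clusters(dend, 1).labels)) == 1

    def test_impossible_k(self):
        dend = hca(np.array([[0.0], [1.0], [3.0]]))
        with pytest.raises(ValueError):
            cut_clusters(dend, 0)
        with pytest.raises(ValueError):
            cut_clusters(dend, 4)


class TestCompareClusterings:
    def test_identity_and_permutation_invariance(self):
        a = ClusterAssignment(list(range(5)), np.array([1, 1, 2, 2, 3]), 3)
        b = ClusterAssignment(list(range(5)), np.array([7, 7, 1, 1, 2]), 3)
        assert compare_clusterings(a, b) == 1.0

    def test_singleton_vs_lumped_matches_pair_counting(self):
        a = [1, 1, 1, 2]
        b = [1, 1, 1, 1]
        ca = ClusterAssignment(list(range(4)), np.array(a), 2)
        cb = ClusterAssignment(list(range(4)), np.array(b), 1)
        assert compare_clusterings(ca, cb) == pytest.approx(naive_ari(a, b))

    def test_station_mismatch(self):
        a = ClusterAssignment([1, 2], np.array([1, 2]), 2)
        b = ClusterAssignment([1, 3], np.array([1, 2]), 2)
        with pytest.raises(ValueError):
            compare_clusterings(a, b)


class TestDerivativeSpectra:
    def rrs_spec(self, fn):
        from arcoptics.spectra import Spectrum

        wl = np.arange(400.0, 701.0)
        return Spectrum(wl, fn(wl), "rrs")

    def test_constant_and_linear_give_zero(self):
        const = self.rrs_spec(lambda wl: np.full(wl.size, 0.002))
        linear = self.rrs_spec(lambda wl: 0.001 + 1e-6 * (wl - 400))
        d = second_derivative_spectra({"c": const, "l": linear})
        np.testing.assert_allclose(d.values, 0.0, atol=1e-18)

    def test_quadratic_curvature_identity_on_interior(self):
        # full stencil (smoothing + difference) interior on a wide grid
        wl = np.arange(400.0, 701.0)
        c = 3e-7
        _, d2 = second_derivative(wl, c * wl**2, smooth_nm=27)
        interior = slice(27 + 13, d2.size - (27 + 13))
        np.testing.assert_allclose(d2[interior], 2 * c, rtol=1e-9)

    def test_reported_range_respects_stencil(self):
        spec = self.rrs_spec(lambda wl: np.full(wl.size, 0.002))
        d = second_derivative_spectra({"s": spec})
        assert d.wavelengths_nm[0] == 435.0 + 27
        assert d.wavelengths_nm[-1] == 510.0 - 27

    def test_nonpositive_reference_band_raises(self):
        spec = self.rrs_spec(lambda wl: np.where(wl == 555.0, 0.0, 0.002))
        # interpolated Rrs(555) is 0 only exactly at the node
        with pytest.raises(ValueError, match="555"):
            second_derivative_spectra({"s": spec})

    def test_top_split_separates_cdom_regimes(self):
        # representative stations spanning the observed AOP clusters:
        # low-CDOM 0.08-0.15 m^-1 vs high-CDOM 0.31-0.60 m^-1
        low = [(0.08, 0.015), (0.10, 0.02), (0.11, 0.025),
               (0.12, 0.018), (0.14, 0.022), (0.15, 0.02)]
        high = [(0.31, 0.02), (0.38, 0.015), (0.45, 0.025),
                (0.52, 0.02), (0.60, 0.018)]
        stations = []
        for grp, defs in (("lo", low), ("hi", high)):
            for i, (acdom, aph) in enumerate(defs):
                s = SyntheticStation(f"{grp}{i}", grp, 80.0, 30.0, -1.3, 31.0,
                                     acdom, 0.005, aph, 1.0)
                synthetic.build_spectra(s)
                synthetic.forward_rrs(s)
                stations.append(s)
        d = second_derivative_spectra({s.station_id: s.rrs for s in stations})
        labels = cut_clusters(aop_cluster(d), 2)
        got = dict(zip(labels.station_ids, labels.labels))
        lo_labels = {got[s.station_id] for s in stations if s.province == "lo"}
        hi_labels = {got[s.station_id] for s in stations if s.province == "hi"}
        assert len(lo_labels) == 1 and len(hi_labels) == 1
        assert lo_labels != hi_labels


class TestEnvironmentalMatrixAndKW:
    def test_incomplete_rows_dropped_and_counted(self):
        df = pd.DataFrame(
            {
                "station_id": ["a", "b", "c"],
                "temperature_c": [1.0, 2.0, np.nan],
                "salinity": [30.0, 31.0, 32.0],
                "acdom443": [0.1, 0.2, 0.3],
                "anap443": [0.01, 0.01, 0.01],
                "aph443": [0.02, 0.03, 0.02],
            }
        )
        env, dropped = build_environmental_matrix(df)
        assert len(env) == 2 and dropped == 1

    def test_kruskal_wallis_wrapper(self):
        values = np.array([1.0, 1.1, 0.9, 5.0, 5.2, 4.9])
        labels = np.array([1, 1, 1, 2, 2, 2])
        stat = kruskal_wallis(values, labels, 1, 2)
        assert stat.pvalue < 0.05
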