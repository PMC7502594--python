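"""Correlation estimators against exhaustive pair-count / distance oracles."""

import numpy as np
import pytest

from space_stomata import (
    CorrelationFunction,
    CotyledonMap,
    Outline,
    RandomEnsemble,
    SectorFilter,
    bootstrap_ci,
    filter_sectors,
    generate_ensemble,
    generate_uniform_points,
    log_bins,
    pool_cotyledons,
    sector_correlation,
    stoma_sector_distances,
    stomata_autocorrelation,
    with_bootstrap_ci,
)

from .conftest import segment_distance_oracle

BIG = Outline.from_points([(-100, -100), (1100, -100), (1100, 1100), (-100, 1100)])
SECTOR = Outline.from_points([(400, 400), (500, 400), (500, 500), (400, 500)])


def naive_sector_zeta(stomata, sector_vertices, random_sets, bins):
    """From-scratch double-loop recomputation of zeta = S/<R> - 1."""

    def dist_list(pts):
        out = []
        for p in pts:
            from .conftest import ray_cast_oracle

            on_or_in = ray_cast_oracle(p, sector_vertices) or segment_distance_oracle(p, sector_vertices) == 0.0
            if not on_or_in:
                out.append(segment_distance_oracle(p, sector_vertices))
        return out

    S = np.histogram(dist_list(stomata), bins=bins)[0]
    R = np.mean([np.histogram(dist_list(r), bins=bins)[0] for r in random_sets], axis=0)
    zeta = np.full(len(bins) - 1, np.nan)
    ok = R > 0
    zeta[ok] = S[ok] / R[ok] - 1.0
    return S, R, zeta


def naive_landy_szalay(stomata, random_sets, bins):
    """From-scratch Landy-Szalay with explicit double loops."""

    def pair_hist(pts):
        d = [np.linalg.norm(pts[i] - pts[j]) for i in range(len(pts)) for j in range(i + 1, len(pts))]
        return np.histogram(d, bins=bins)[0] / (len(pts) * (len(pts) - 1) / 2)

    def cross_hist(a, b):
        d = [np.linalg.norm(p - q) for p in a for q in b]
        return np.histogram(d, bins=bins)[0] / (len(a) * len(b))

    ss = pair_hist(stomata)
    rr = np.mean([pair_hist(r) for r in random_sets], axis=0)
    sr = np.mean([cross_hist(stomata, r) for r in random_sets], axis=0)
    zeta = np.full(len(bins) - 1, np.nan)
    ok = rr > 0
    zeta[ok] = (ss[ok] - 2 * sr[ok] + rr[ok]) / rr[ok]
    return zeta


class TestSectorFilter:
    def _map_with(self, sectors):
        return CotyledonMap(cotyledon=BIG, sectors=sectors)

    def test_area_window(self):
        small = Outline.from_points([(0, 0), (100, 0), (100, 100), (0, 100)])  # 10,000 µm²
        ok = Outline.from_points([(0, 0), (200, 0), (200, 100), (0, 100)])  # 20,000 µm²
        kept = filter_sectors(self._map_with([small, ok]))
        assert kept == [ok]

    def test_close_pair_both_removed(self):
        a = Outline.from_points([(0, 0), (200, 0), (200, 100), (0, 100)])
        b = Outline.from_points([(300, 0), (500, 0), (500, 100), (300, 100)])  # 100 µm apart
        assert filter_sectors(self._map_with([a, b])) == []

    def test_separated_pair_kept(self):
        a = Outline.from_points([(0, 0), (200, 0), (200, 100), (0, 100)])
        b = Outline.from_points([(500, 0), (700, 0), (700, 100), (500, 100)])  # 300 µm apart
        assert len(filter_sectors(self._map_with([a, b]))) == 2

    def test_no_upper_bound(self):
        huge = Outline.from_points([(0, 0), (500, 0), (500, 200), (0, 200)])  # 100,000 µm²
        assert filter_sectors(self._map_with([huge])) == []
        f = SectorFilter(area_max=None)
        assert filter_sectors(self._map_with([huge]), f) == [huge]

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            SectorFilter(area_min=50_000, area_max=40_000)


class TestStomaSectorDistances:
    def test_interior_stomata_excluded_and_oracle_match(self):
        rng = np.random.default_rng(21)
        stomata = rng.uniform(0, 1000, size=(60, 2))
        m = CotyledonMap(cotyledon=BIG, sectors=[SECTOR], stomata=stomata)
        d = stoma_sector_distances(m, [SECTOR])
        from .conftest import ray_cast_oracle

        outside = [p for p in stomata if not ray_cast_oracle(p, SECTOR.vertices)]
        assert len(d) == len(outside)
        expected = sorted(segment_distance_oracle(p, SECTOR.vertices) for p in outside)
        np.testing.assert_allclose(np.sort(d), expected, rtol=1e-9)

    def test_multi_sector_minimum(self):
        s2 = Outline.from_points([(800, 800), (900, 800), (900, 900), (800, 900)])
        m = CotyledonMap(cotyledon=BIG, sectors=[SECTOR, s2], stomata=np.array([[650.0, 650.0]]))
        (d,) = stoma_sector_distances(m, [SECTOR, s2])
        assert d == pytest.approx(np.hypot(150, 150))

    def test_no_sectors_rejected(self):
        m = CotyledonMap(cotyledon=BIG, stomata=np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError):
            stoma_sector_distances(m, [])


class TestSectorCorrelation:
    def test_zeta_arithmetic(self):
        cf = CorrelationFunction(
            bin_edges=np.array([1.0, 2.0, 4.0]),
            S=np.array([10.0, 30.0]),
            R_expected=np.array([10.0, 10.0]),
            zeta=np.array([0.0, 2.0]),
        )
        assert cf.zeta[0] == 0.0 and cf.zeta[1] == 2.0  # zeta = S/<R> - 1

    def test_matches_naive_oracle_small_fixture(self):
        rng = np.random.default_rng(31)
        stomata = rng.uniform(0, 1000, size=(20, 2))
        sets = [rng.uniform(0, 1000, size=(20, 2)) for _ in range(3)]
        m = CotyledonMap(cotyledon=BIG, sectors=[SECTOR], stomata=stomata)
        ens = RandomEnsemble(sets=sets, seed=0)
        bins = log_bins(5, 1000, 10)
        cf = sector_correlation(m, [SECTOR], ens, bins)
        S, R, zeta = naive_sector_zeta(stomata, SECTOR.vertices, sets, bins)
        np.testing.assert_array_equal(cf.S, S)
        np.testing.assert_allclose(cf.R_expected, R, rtol=1e-12)
        np.testing.assert_allclose(cf.zeta, zeta, rtol=1e-12, equal_nan=True)

    def test_count_conservation(self):
        rng = np.random.default_rng(32)
        stomata = rng.uniform(0, 1000, size=(50, 2))
        m = CotyledonMap(cotyledon=BIG, sectors=[SECTOR], stomata=stomata)
        ens = RandomEnsemble(sets=[rng.uniform(0, 1000, size=(50, 2))], seed=0)
        bins = np.array([0.0, 100.0, 1e4])  # covers every possible distance
        cf = sector_correlation(m, [SECTOR], ens, bins)
        n_outside = len(stoma_sector_distances(m, [SECTOR]))
        assert cf.S.sum() == n_outside

    def test_zeta_floor(self, cotyledon, sector):
        pts = generate_uniform_points(100, cotyledon, seed=33)
        m = CotyledonMap(cotyledon=cotyledon, sectors=[sector], stomata=pts)
        ens = generate_ensemble(100, cotyledon, 20, seed=34)
        cf = sector_correlation(m, [sector], ens)
        assert np.all(cf.zeta[cf.defined] >= -1.0)


class TestAutocorrelation:
    def test_identical_data_and_random_sets_near_zero(self):
        """With the random sets equal to the data, the estimator collapses to 2/n.

        ss and rr coincide exactly; the cross count sees each unordered pair
        twice among n^2 ordered pairs, so sr = ss * (n-1)/n and
        zeta = 2 - 2(n-1)/n = 2/n in every populated bin — the duplicate-set
        analogue of the null identity, vanishing as n grows.
        """
        n = 15
        pts = np.random.default_rng(41).uniform(0, 1000, size=(n, 2))
        m = CotyledonMap(cotyledon=BIG, stomata=pts)
        ens = RandomEnsemble(sets=[pts.copy(), pts.copy()], seed=0)
        cf = stomata_autocorrelation(m, ens, log_bins(5, 2000, 12))
        np.testing.assert_allclose(cf.zeta[cf.defined], 2.0 / n, atol=1e-12)

    def test_printed_triangle_fixture(self):
        """3 stomata vs one shifted copy: pair distances {3,4,5} on each side, no cross pair in bin."""
        stomata = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        rand = stomata + np.array([10.0, 0.0])
        m = CotyledonMap(cotyledon=BIG, stomata=stomata)
        ens = RandomEnsemble(sets=[rand], seed=0)
        bins = np.array([2.0, 6.0])
        cf = stomata_autocorrelation(m, ens, bins)
        # ss = rr = 3/3 = 1; all 9 cross distances >= 6 so sr = 0; zeta = (1 - 0 + 1)/1 = 2
        assert cf.SS[0] == pytest.approx(1.0)
        assert cf.RR[0] == pytest.approx(1.0)
        assert cf.SR[0] == pytest.approx(0.0)
        assert cf.zeta[0] == pytest.approx(2.0)

    def test_matches_naive_landy_szalay(self):
        rng = np.random.default_rng(42)
        stomata = rng.uniform(0, 500, size=(18, 2))
        sets = [rng.uniform(0, 500, size=(18, 2)) for _ in range(3)]
        m = CotyledonMap(cotyledon=BIG, stomata=stomata)
        cf = stomata_autocorrelation(m, RandomEnsemble(sets=sets, seed=0), log_bins(5, 1000, 10))
        expected = naive_landy_szalay(stomata, sets, log_bins(5, 1000, 10))
        np.testing.assert_allclose(cf.zeta, expected, rtol=1e-10, equal_nan=True)

    def test_too_few_stomata(self):
        m = CotyledonMap(cotyledon=BIG, stomata=np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError):
            stomata_autocorrelation(m, RandomEnsemble(sets=[np.array([[1.0, 1.0]])], seed=0))


class TestBootstrap:
    def _fixture(self, cotyledon, sector, n=200, seed=60):
        pts = generate_uniform_points(n, cotyledon, seed=seed)
        m = CotyledonMap(cotyledon=cotyledon, sectors=[sector], stomata=pts)
        ens = generate_ensemble(n, cotyledon, 50, seed=seed + 1)
        return sector_correlation(m, [sector], ens)

    def test_deterministic(self, cotyledon, sector):
        cf = self._fixture(cotyledon, sector)
        lo1, hi1 = bootstrap_ci(cf.distances, cf.R_expected, cf.bin_edges, n_boot=100, seed=7)
        lo2, hi2 = bootstrap_ci(cf.distances, cf.R_expected, cf.bin_edges, n_boot=100, seed=7)
        np.testing.assert_array_equal(lo1, lo2)
        np.testing.assert_array_equal(hi1, hi2)

    def test_band_brackets_point_estimate(self, cotyledon, sector):
        cf = with_bootstrap_ci(self._fixture(cotyledon, sector), n_boot=400, seed=8)
        ok = cf.defined & (cf.R_expected >= 5)
        # percentile band from resampling the same data straddles the estimate
        assert np.all(cf.ci_lo[ok] <= cf.zeta[ok] + 1e-9)
        assert np.all(cf.ci_hi[ok] >= cf.zeta[ok] - 1e-9)

    def test_width_shrinks_with_sample_size(self, cotyledon, sector):
        """Quadrupling N shrinks the mean band width roughly twofold (1/sqrt(N) scaling)."""
        small = with_bootstrap_ci(self._fixture(cotyledon, sector, n=150, seed=61), n_boot=400, seed=9)
        big = with_bootstrap_ci(self._fixture(cotyledon, sector, n=600, seed=62), n_boot=400, seed=9)
        ok = small.defined & big.defined & (small.R_expected >= 10) & (big.R_expected >= 10)
        w_small = np.mean((small.ci_hi - small.ci_lo)[ok])
        w_big = np.mean((big.ci_hi - big.ci_lo)[ok])
        assert w_big < w_small
        assert w_small / w_big == pytest.approx(2.0, rel=0.4)

    def test_n_boot_floor(self, cotyledon, sector):
        cf = self._fixture(cotyledon, sector)
        with pytest.raises(ValueError):
            bootstrap_ci(cf.distances, cf.R_expected, cf.bin_edges, n_boot=10)


class TestPooling:
    def _cf(self, cotyledon, sector, seed):
        pts = generate_uniform_points(200, cotyledon, seed=seed)
        m = CotyledonMap(cotyledon=cotyledon, sectors=[sector], stomata=pts)
        ens = generate_ensemble(200, cotyledon, 30, seed=seed + 100)
        return sector_correlation(m, [sector], ens)

    def test_single_input_identity(self, cotyledon, sector):
        cf = self._cf(cotyledon, sector, 70)
        pooled = pool_cotyledons([cf])
        np.testing.assert_allclose(pooled.zeta, cf.zeta, equal_nan=True)

    def test_order_invariance(self, cotyledon, sector):
        a, b = self._cf(cotyledon, sector, 71), self._cf(cotyledon, sector, 72)
        p1 = pool_cotyledons([a, b])
        p2 = pool_cotyledons([b, a])
        np.testing.assert_allclose(p1.zeta, p2.zeta, equal_nan=True)

    def test_identical_cotyledons_same_zeta_narrower_band(self, cotyledon, sector):
        cf = self._cf(cotyledon, sector, 73)
        single = pool_cotyledons([cf], n_boot=400, seed=1)
        double = pool_cotyledons([cf, cf], n_boot=400, seed=1)
        np.testing.assert_allclose(double.zeta, cf.zeta, equal_nan=True)
        ok = single.defined & (single.R_expected / 1 >= 10)
        w1 = np.mean((single.ci_hi - single.ci_lo)[ok])
        w2 = np.mean((double.ci_hi - double.ci_lo)[ok])
        # doubling the pooled distance list: width ratio ~ 1/sqrt(2)
        assert 0.55 < w2 / w1 < 0.85

    def test_mismatched_bins_rejected(self, cotyledon, sector):
        a = self._cf(cotyledon, sector, 74)
        pts = generate_uniform_points(200, cotyledon, seed=75)
        m = CotyledonMap(cotyledon=cotyledon, sectors=[sector], stomata=pts)
        ens = generate_ensemble(200, cotyledon, 10, seed=76)
        b = sector_correlation(m, [sector], ens, log_bins(5, 2000, 12))
        with pytest.raises(ValueError):
            pool_cotyledons([a, b])
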