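"""Genome scans, permutation thresholds, epistasis LRT and rank-sum tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from iciqtl.errors import DegenerateDataError, ParameterError, ValidationError
from iciqtl.qtl import (
    FounderDosageMatrix,
    MarkerMap,
    N1GenotypeMatrix,
    ScanModel,
    epistasis_lrt,
    founder_scan_fn,
    haplotype_group_compare,
    permutation_threshold,
    rank_sum_test,
    scan_binary_marker,
    scan_founder_additive,
)
from iciqtl.simulate import simulate_cc_genomes, simulate_ccf1n1

LN10 = math.log(10.0)


def brute_force_lod(y, x):
    """Independent oracle: explicit lstsq fits for alternative and null."""
    y = np.asarray(y, float)
    n = y.size
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss1 = ((y - x @ beta) ** 2).sum()
    rss0 = ((y - y.mean()) ** 2).sum()
    return 0.5 * n * math.log10(rss0 / max(rss1, 1e-300))


@pytest.fixture(scope="module")
def small_panel():
    fdm, _ = simulate_cc_genomes(20, [(12, 40.0), (12, 40.0)], seed=42)
    return fdm


class TestFounderScan:
    def test_monomorphic_marker_lod_zero(self):
        markers = MarkerMap(np.array(["m1", "m2"]), np.array(["1", "1"]),
                            np.array([0.0, 10.0]))
        dos = np.zeros((12, 2, 8))
        dos[:, 0, 0] = 1.0  # monomorphic
        rng = np.random.default_rng(0)
        dos[np.arange(12), 1, rng.integers(0, 8, 12)] = 1.0
        fdm = FounderDosageMatrix(markers, [f"L{i}" for i in range(12)], dos)
        res = scan_founder_additive(rng.normal(size=12), fdm)
        assert res.lod[0] == pytest.approx(0.0, abs=1e-10)

    def test_constructed_rss_ratio(self):
        # two founder groups of 4; RSS0 = 8, RSS1 = 2 -> LOD = 4 log10(4)
        markers = MarkerMap(np.array(["m1"]), np.array(["1"]),
                            np.array([0.0]))
        dos = np.zeros((8, 1, 8))
        dos[:4, 0, 0] = 1.0
        dos[4:, 0, 1] = 1.0
        fdm = FounderDosageMatrix(markers, [f"L{i}" for i in range(8)], dos)
        m = math.sqrt(3)
        y = np.array([0.5, 0.5, -0.5, -0.5,
                      m + 0.5, m + 0.5, m - 0.5, m - 0.5])
        res = scan_founder_additive(y, fdm)
        assert res.lod[0] == pytest.approx(4 * math.log10(4.0), abs=1e-10)

    def test_affine_phenotype_invariance(self, small_panel):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        lod1 = scan_founder_additive(y, small_panel).lod
        lod2 = scan_founder_additive(2.0 * y + 3.0, small_panel).lod
        np.testing.assert_allclose(lod1, lod2, atol=1e-8)

    def test_matches_brute_force_oracle_everywhere(self, small_panel):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        res = scan_founder_additive(y, small_panel)
        for m in range(small_panel.markers.n_markers):
            assert res.lod[m] == pytest.approx(
                brute_force_lod(y, small_panel.dosages[:, m, :]), abs=1e-8
            )

    def test_lod_nonnegative(self, small_panel):
        rng = np.random.default_rng(3)
        for _ in range(5):
            res = scan_founder_additive(rng.normal(size=20), small_panel)
            assert np.all(res.lod >= 0)

    def test_constant_phenotype_errors(self, small_panel):
        with pytest.raises(DegenerateDataError):
            scan_founder_additive(np.ones(20), small_panel)


@pytest.fixture(scope="module")
def n1_panel():
    fdm, _ = simulate_cc_genomes(4, [(15, 50.0)], seed=7)
    n1, _ = simulate_ccf1n1(fdm, 40, seed=8)
    return n1


class TestBinaryScan:
    def test_equal_group_fractions_lod_zero(self):
        markers = MarkerMap(np.array(["m1"]), np.array(["1"]), np.array([0.0]))
        geno = np.array([[0.0]] * 10 + [[1.0]] * 10)
        n1 = N1GenotypeMatrix(markers, [f"M{i}" for i in range(20)], geno)
        y = np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0, 0, 0] * 2)
        res = scan_binary_marker(y, n1)
        assert res.lod[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_lrt_example(self):
        # groups (n=10, k=2) vs (n=10, k=8)
        markers = MarkerMap(np.array(["m1"]), np.array(["1"]), np.array([0.0]))
        geno = np.array([[0.0]] * 10 + [[1.0]] * 10)
        n1 = N1GenotypeMatrix(markers, [f"M{i}" for i in range(20)], geno)
        y = np.array([1, 1] + [0] * 8 + [1] * 8 + [0, 0], dtype=float)
        res = scan_binary_marker(y, n1)
        ll_full = 2 * (2 * math.log(0.2) + 8 * math.log(0.8))
        ll_null = 20 * math.log(0.5)
        lrt = 2 * (ll_full - ll_null)
        assert lrt == pytest.approx(7.7097, abs=2e-4)
        assert res.lod[0] == pytest.approx(lrt / (2 * LN10), abs=1e-10)

    def test_closed_form_matches_statsmodels_logit(self, n1_panel):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        y = (rng.random(40) < 0.3 + 0.4 * n1_panel.genotype[:, 7]).astype(
            float
        )
        res = scan_binary_marker(y, n1_panel)
        for m in (0, 7, 14):
            g = n1_panel.genotype[:, m]
            if np.unique(y).size < 2 or np.unique(g).size < 2:
                continue
            x = np.column_stack([np.ones(40), g])
            full = sm.Logit(y, x).fit(disp=0)
            null = sm.Logit(y, np.ones((40, 1))).fit(disp=0)
            lod_sm = 2 * (full.llf - null.llf) / (2 * LN10)
            assert res.lod[m] == pytest.approx(lod_sm, abs=1e-6)

    def test_complete_separation_finite_and_flagged(self):
        markers = MarkerMap(np.array(["m1"]), np.array(["1"]), np.array([0.0]))
        geno = np.array([[0.0]] * 6 + [[1.0]] * 6)
        n1 = N1GenotypeMatrix(markers, [f"M{i}" for i in range(12)], geno)
        y = np.array([0.0] * 6 + [1.0] * 6)
        res = scan_binary_marker(y, n1)
        assert np.isfinite(res.lod[0])
        # perfect fit: ll_full = 0, ll_null = 12 ln(1/2)
        assert res.lod[0] == pytest.approx(12 * math.log(2) / LN10,
                                           abs=1e-10)
        assert res.separated_markers == ["m1"]

    def test_gaussian_model_matches_oracle(self, n1_panel):
        rng = np.random.default_rng(10)
        y = rng.normal(size=40) + n1_panel.genotype[:, 5]
        res = scan_binary_marker(y, n1_panel,
                                 model=ScanModel.gaussian_binary_marker)
        for m in (0, 5, 10):
            g = n1_panel.genotype[:, m]
            x = np.column_stack([np.ones(40), g])
            assert res.lod[m] == pytest.approx(brute_force_lod(y, x),
                                               abs=1e-8)

    def test_missing_genotypes_dropped_marker_wise(self):
        markers = MarkerMap(np.array(["m1"]), np.array(["1"]), np.array([0.0]))
        geno = np.array([[0.0]] * 5 + [[1.0]] * 5 + [[np.nan]] * 2)
        n1 = N1GenotypeMatrix(markers, [f"M{i}" for i in range(12)], geno)
        y = np.array([1, 0, 0, 0, 0, 1, 1, 1, 0, 1, 1, 1], dtype=float)
        res = scan_binary_marker(y, n1)
        k0, k1 = 1.0, 4.0
        ll_full = (k0 * math.log(0.2) + 4 * math.log(0.8)
                   + k1 * math.log(0.8) + 1 * math.log(0.2))
        ll_null = 5 * math.log(0.5) + 5 * math.log(0.5)
        assert res.lod[0] == pytest.approx(
            2 * (ll_full - ll_null) / (2 * LN10), abs=1e-10
        )

    def test_constant_trait_errors(self, n1_panel):
        with pytest.raises(DegenerateDataError):
            scan_binary_marker(np.zeros(40), n1_panel)


class TestPermutationThreshold:
    def test_quantile_monotone_in_alpha(self, small_panel):
        rng = np.random.default_rng(11)
        y = rng.normal(size=20)
        fn = founder_scan_fn(small_panel)
        thr_05, nulls = permutation_threshold(fn, y, n_perm=200, alpha=0.05,
                                              seed=12)
        thr_20 = float(np.quantile(nulls, 0.8))
        assert thr_20 <= thr_05

    def test_deterministic_under_seed(self, small_panel):
        rng = np.random.default_rng(13)
        y = rng.normal(size=20)
        fn = founder_scan_fn(small_panel)
        t1, _ = permutation_threshold(fn, y, n_perm=100, alpha=0.05, seed=5)
        t2, _ = permutation_threshold(fn, y, n_perm=100, alpha=0.05, seed=5)
        assert t1 == t2

    def test_unresolvable_alpha_rejected(self, small_panel):
        fn = founder_scan_fn(small_panel)
        with pytest.raises(ParameterError):
            permutation_threshold(fn, np.arange(20.0), n_perm=10, alpha=0.05)

    def test_null_calibration(self, small_panel):
        """Genome-wide type-I error ~ alpha under a null phenotype."""
        fn = founder_scan_fn(small_panel)
        alpha = 0.1
        hits = 0
        n_rep = 150
        for r in range(n_rep):
            rng = np.random.default_rng(100 + r)
            y = rng.normal(size=20)
            thr, _ = permutation_threshold(fn, y, n_perm=150, alpha=alpha,
                                           seed=1000 + r)
            hits += float(np.max(fn(y))) > thr
        rate = hits / n_rep
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * se + 1 / 150


class TestEpistasisLRT:
    @staticmethod
    def _cell_data(counts, n_per_cell=10):
        """Genotypes/outcomes for 2x2 cells with given CR counts."""
        g, y = [], []
        for (g1, g2), k in zip(itertools.product((0, 1), repeat=2), counts):
            for i in range(n_per_cell):
                g.append((g1, g2))
                y.append(1.0 if i < k else 0.0)
        return np.array(g, float), np.array(y)

    def test_equal_cell_fractions_null(self):
        g, y = self._cell_data((5, 5, 5, 5))
        res = epistasis_lrt(g, y, order=2)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_logit_additive_cells_give_zero(self):
        # fractions 0.2/0.5/0.5/0.8 are exactly additive on the logit scale
        g, y = self._cell_data((2, 5, 5, 8))
        res = epistasis_lrt(g, y, order=2)
        assert res.df == 1
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-6)

    def test_interaction_detected(self):
        # fractions 0.1/0.5/0.5/0.1 are maximally anti-additive on the logit
        # scale (additivity predicts ~0.9 in the double-carrier cell)
        g, y = self._cell_data((2, 10, 10, 2), n_per_cell=20)
        res = epistasis_lrt(g, y, order=2)
        assert res.lrt_stat > 10
        assert res.p < 1e-3

    def test_empty_cell_named(self):
        g = np.array([(0, 0), (0, 1), (1, 0)] * 5, dtype=float)
        y = np.tile([1.0, 0.0, 1.0], 5)
        with pytest.raises(DegenerateDataError, match=r"g1=1, g2=1"):
            epistasis_lrt(g, y, order=2)

    def test_three_way_df_one_given_pairwise(self):
        rng = np.random.default_rng(14)
        g = rng.integers(0, 2, size=(160, 3)).astype(float)
        while not all(
            tuple(c) in {tuple(map(int, r)) for r in g}
            for c in itertools.product((0, 1), repeat=3)
        ):
            g = rng.integers(0, 2, size=(160, 3)).astype(float)
        y = (rng.random(160) < 0.4).astype(float)
        res = epistasis_lrt(g, y, order=3)
        assert res.df == 1
        full = epistasis_lrt(g, y, order=3, baseline="additive")
        assert full.df == 4

    def test_matches_statsmodels_lrt(self):
        import statsmodels.api as sm

        g, y = self._cell_data((2, 6, 4, 9), n_per_cell=12)
        res = epistasis_lrt(g, y, order=2)
        x0 = np.column_stack([np.ones(len(y)), g])
        x1 = np.column_stack([x0, g[:, 0] * g[:, 1]])
        lrt = 2 * (sm.Logit(y, x1).fit(disp=0).llf
                   - sm.Logit(y, x0).fit(disp=0).llf)
        assert res.lrt_stat == pytest.approx(lrt, abs=1e-5)
        assert res.p == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-5)


class TestRankSum:
    def test_identical_groups_p_one(self):
        p = rank_sum_test(np.array([0, 1, 0, 1.0]), np.array([1, 0, 1, 0.0]))
        assert p == pytest.approx(1.0)

    def test_exact_binary_example(self):
        p = rank_sum_test(np.zeros(3), np.ones(3))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_hypergeometric_oracle(self):
        """All binary instances up to n=10 against a closed-form oracle."""
        for na in range(1, 6):
            for nb in range(1, 6):
                for ka in range(na + 1):
                    for kb in range(nb + 1):
                        x = np.array([1.0] * ka + [0.0] * (na - ka))
                        y = np.array([1.0] * kb + [0.0] * (nb - kb))
                        p = rank_sum_test(x, y)
                        # oracle: ones allocated to group a ~ Hypergeom
                        n, K = na + nb, ka + kb
                        mean_ka = na * K / n
                        obs = abs(ka - mean_ka)
                        rv = stats.hypergeom(n, K, na)
                        support = np.arange(max(0, K - nb), min(na, K) + 1)
                        if ka / na == kb / nb:
                            p_oracle = 1.0
                        else:
                            devs = np.abs(support - mean_ka)
                            p_oracle = rv.pmf(
                                support[devs >= obs - 1e-9]
                            ).sum()
                        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_sample_matches_permutation_oracle(self):
        rng = np.random.default_rng(15)
        x = (rng.random(40) < 0.3).astype(float)
        y = (rng.random(45) < 0.55).astype(float)
        p = rank_sum_test(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = abs(ranks[:40].sum() - 40 * 86 / 2)
        count = 0
        n_mc = 4000
        for _ in range(n_mc):
            perm = rng.permutation(ranks)
            count += abs(perm[:40].sum() - 40 * 86 / 2) >= obs - 1e-9
        assert p == pytest.approx(count / n_mc, abs=0.03)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test(np.array([]), np.array([1.0]))


class TestHaplotypeGroups:
    def test_pairwise_table(self):
        groups = {
            "R/R": np.array([1, 1, 1, 0.0]),
            "R/NR": np.array([1, 0, 0, 0.0]),
            "NR/NR": np.array([0, 0, 0, 0.0]),
        }
        out = haplotype_group_compare(groups)
        assert len(out) == 3
        assert set(out.columns) == {"group_a", "group_b", "frac_cr_a",
                                    "frac_cr_b", "p"}
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
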