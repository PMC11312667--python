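import numpy as np
import pytest
from scipy import stats

from survgwas.gene_based import (
    burden_test,
    collapse,
    gene_wide_threshold,
    per_variant_cox,
    run_gene_tests,
    skat_test,
    skato_test,
)
from survgwas.gwas import assoc_scan
from survgwas.io_formats import GenotypeMatrix

from conftest import toy_cohort


class TestCollapse:
    def test_all_zero_subject(self):
        G = np.array([[0, 0], [1, 0], [0, 2]], dtype=float)
        np.testing.assert_array_equal(collapse(G), [0, 1, 1])

    def test_homozygote_is_carrier(self):
        assert collapse(np.array([[2.0]]))[0] == 1

    def test_equals_rowwise_any(self, rng):
        G = rng.binomial(1, 0.1, (50, 4)).astype(float)
        np.testing.assert_array_equal(collapse(G), (G > 0).any(axis=1).astype(int))

    def test_missing_counts_as_noncarrier(self):
        G = np.array([[np.nan, 0.0], [np.nan, 1.0]])
        np.testing.assert_array_equal(collapse(G), [0, 1])

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            collapse(np.empty((5, 0)))


class TestBurden:
    def test_single_het_variant_equals_assoc_scan(self, rng):
        n = 500
        g = rng.binomial(1, 0.05, n).astype(float)
        y = rng.standard_normal(n) + 0.4 * g
        beta, se, p = burden_test(y, collapse(g[:, None]))
        G = GenotypeMatrix(g[:, None], np.array([f"S{i}" for i in range(n)]), np.array(["v"]))
        scan = assoc_scan(y, G)
        assert beta == pytest.approx(scan["beta"][0], rel=1e-12)
        assert p == pytest.approx(scan["p"][0], rel=1e-12)

    def test_constant_carrier_errors(self, rng):
        y = rng.standard_normal(20)
        with pytest.raises(ValueError):
            burden_test(y, np.ones(20))

    def test_null_calibration_small(self, rng):
        n, reps = 1000, 400
        hits = 0
        for _ in range(reps):
            c = rng.binomial(1, 0.02, n)
            if 0 < c.sum() < n:
                hits += burden_test(rng.standard_normal(n), c)[2] < 0.05
        assert 0.02 < hits / reps < 0.08  # loose: tight bound lives in the acceptance suite


class TestSkat:
    def test_single_variant_equals_marginal_score_chi2(self, rng):
        """k = 1: the asymptotic SKAT p is the 1-df score chi-square of the
        marginal regression."""
        n = 300
        g = rng.binomial(1, 0.05, n).astype(float)
        y = rng.standard_normal(n) + 0.3 * g
        res = skat_test(y, g[:, None], weights=np.ones(1), null="asymptotic")
        e = y - y.mean()
        s2 = e @ e / (n - 1)
        gc = g - g.mean()
        chi2 = (g @ e) ** 2 / (s2 * (gc @ gc))
        assert res.p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-8)

    def test_exact_close_to_asymptotic_large_n(self, rng):
        n = 5000
        G = rng.binomial(1, 0.01, (n, 5)).astype(float)
        y = rng.standard_normal(n)
        p_ex = skat_test(y, G, null="exact").p
        p_as = skat_test(y, G, null="asymptotic").p
        assert p_ex == pytest.approx(p_as, rel=0.1)

    def test_direction_agnostic_beats_burden_on_opposing_effects(self, rng):
        """Opposing-direction variant effects: SKAT retains power where the
        collapsed burden cancels."""
        n, reps = 600, 120
        skat_hits = burden_hits = 0
        for _ in range(reps):
            G = rng.binomial(1, 0.03, (n, 2)).astype(float)
            y = rng.standard_normal(n) + G @ np.array([0.9, -0.9])
            c = collapse(G)
            if 0 < c.sum() < n:
                burden_hits += burden_test(y, c)[2] < 0.05
            skat_hits += skat_test(y, G).p < 0.05
        assert skat_hits > burden_hits

    def test_zero_variance_kernel_p_one(self):
        res = skat_test(np.random.default_rng(0).standard_normal(30), np.zeros((30, 2)))
        assert res.p == 1.0 and res.method == "degenerate"


class TestSkatO:
    def _toy(self, rng, n=200, k=4, gamma=0.0):
        G = rng.binomial(1, 0.05, (n, k)).astype(float)
        y = rng.standard_normal(n) + gamma * G.sum(axis=1)
        return y, G

    def test_rho_one_is_weighted_burden_score(self, rng):
        y, G = self._toy(rng)
        so = skato_test(y, G, rho_grid=(1.0,))
        assert so.p == so.p_rho[1.0]
        assert so.rho_min == 1.0

    def test_rho_zero_is_skat(self, rng):
        y, G = self._toy(rng)
        so = skato_test(y, G, rho_grid=(0.0,))
        sk = skat_test(y, G)
        assert so.p == pytest.approx(sk.p, rel=1e-9)

    def test_omnibus_bracket(self, rng):
        for gamma in (0.0, 0.5):
            y, G = self._toy(rng, gamma=gamma)
            so = skato_test(y, G)
            minp = min(so.p_rho.values())
            assert minp - 1e-10 <= so.p <= min(1.0, len(so.rho_grid) * minp) + 1e-10

    def test_result_bookkeeping(self, rng):
        y, G = self._toy(rng)
        so = skato_test(y, G)
        assert set(so.p_rho) == set(so.rho_grid)
        assert so.rho_min in so.rho_grid


class TestGeneWideThreshold:
    def test_single_test(self):
        assert gene_wide_threshold(1, 1, 1) == 0.05

    def test_five_hundred_tests(self):
        assert gene_wide_threshold(500) == pytest.approx(1e-4)

    def test_counts_per_class(self):
        # 17,071 + 15,891 + 12,219 genes over LoF/AM/REVEL, 1 method
        thr = gene_wide_threshold([17_071, 15_891, 12_219], n_methods=1)
        assert thr == pytest.approx(0.05 / 45_181)

    def test_published_scale_two_sig_figs(self):
        thr = gene_wide_threshold(67_568)
        assert f"{thr:.1e}" == "7.4e-07"

    def test_zero_tests_error(self):
        with pytest.raises(ValueError):
            gene_wide_threshold(0)


class TestPerVariantCox:
    def _study(self, rng, n=3000):
        cohort = toy_cohort(n, seed=12, frac_events=0.0)
        G = rng.binomial(1, [0.02, 0.004, 0.0005], (n, 3)).astype(float)
        eta = 1.2 * G[:, 0]
        cohort["age"] = rng.exponential(np.exp(-eta)) * 40 + 1
        cohort["event"] = 1
        return cohort, G

    def test_mac_gate_and_threshold(self, rng):
        cohort, G = self._study(rng)
        # force a variant below the MAC >= 3 gate
        G[:, 2] = 0.0
        G[:2, 2] = 1.0
        table, thr = per_variant_cox(cohort, G, ["v0", "v1", "v2"])
        assert "v2" not in set(table["variant_id"])
        assert thr == pytest.approx(0.05 / len(table))

    def test_detects_strong_variant(self, rng):
        cohort, G = self._study(rng)
        table, thr = per_variant_cox(cohort, G, ["v0", "v1", "v2"])
        row = table.loc[table["variant_id"] == "v0"].iloc[0]
        assert row["hr"] > 2.0 and row["p"] < 1e-4


class TestRunGeneTests:
    def test_end_to_end_on_simulated_study(self, small_study):
        from survgwas.simulate import simulate_gene_burden
        from survgwas.survival import cohort_null_residuals
        from survgwas.variant_classes import VariantClass, build_gene_sets

        config, cohort, G, truth = small_study
        _, ann = simulate_gene_burden(config)
        _, resid = cohort_null_residuals(cohort)
        sets = build_gene_sets(G, ann, VariantClass.LOF) + build_gene_sets(
            G, ann, VariantClass.AM
        )
        results = run_gene_tests(resid, G, sets)
        assert {r.gene for r in results} == {"GENE1", "GENE2"}
        for r in results:
            assert 0 < r.burden_p <= 1 and 0 < r.skat_p <= 1 and 0 < r.skato_p <= 1
        harmful = next(r for r in results if r.gene == "GENE1")
        null_gene = next(r for r in results if r.gene == "GENE2")
        assert harmful.burden_p < null_gene.burden_p
        assert harmful.burden_beta > 0  # carriers die earlier: positive residual shift
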