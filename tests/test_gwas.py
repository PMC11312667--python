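import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from survgwas.gwas import (
    GWS_THRESHOLD,
    assoc_scan,
    genomic_inflation,
    hwe_exact_test,
    qc_filter,
    stratified_scan,
)
from survgwas.io_formats import GenotypeMatrix
from survgwas.survival import cohort_null_residuals

from conftest import toy_cohort


def _geno(dosage):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        dosage,
        np.array([f"S{i}" for i in range(dosage.shape[0])]),
        np.array([f"v{j}" for j in range(dosage.shape[1])]),
    )


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_brute_force_enumeration(self):
        """Full enumeration over heterozygote counts with 5 minor alleles
        among 100 subjects (het in {1, 3, 5})."""
        n, minor = 100, 5

        def prob(het):
            hom_min = (minor - het) // 2
            hom_maj = n - het - hom_min
            return (
                comb(n, hom_min, exact=True)
                * comb(n - hom_min, het, exact=True)
                * 2**het
                / comb(2 * n, minor, exact=True)
                * comb(n - hom_min - het, hom_maj, exact=True)
            )

        probs = {h: prob(h) for h in (1, 3, 5)}
        total = sum(probs.values())
        probs = {h: p / total for h, p in probs.items()}
        for het in (1, 3, 5):
            hom_min = (minor - het) // 2
            expected = sum(p for p in probs.values() if p <= probs[het] * (1 + 1e-12))
            got = hwe_exact_test(n - het - hom_min, het, hom_min)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_balanced_common_site_modal(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_extreme_deviation_small_p(self):
        # all homozygotes despite 50/50 alleles: far from equilibrium
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestQcFilter:
    def test_missing_rate_rule(self, rng):
        n = 100
        d = rng.binomial(2, 0.3, (n, 2)).astype(float)
        d[:6, 0] = np.nan  # missing rate 0.06 > 0.05: removed
        d[:5, 1] = np.nan  # missing rate exactly 0.05: kept
        Gq, report = qc_filter(_geno(d))
        assert report.n_removed_missing == 1
        assert "v1" in Gq.variant_ids

    def test_maf_boundary_inclusive(self):
        n = 200
        d = np.zeros((n, 3))
        d[:4, 0] = 1  # MAF 0.01 exactly: retained ("< 1%" removed)
        d[:2, 1] = 1  # MAF 0.005: removed
        # column 2 monomorphic: removed
        Gq, report = qc_filter(_geno(d))
        assert list(Gq.variant_ids) == ["v0"]
        assert report.n_removed_maf == 2

    def test_hwe_rule_removes_outliers(self, rng):
        n = 2000
        good = rng.binomial(2, 0.3, (n, 1)).astype(float)
        bad = np.repeat([0.0, 2.0], n // 2)[:, None]  # no hets at 50% frequency
        Gq, report = qc_filter(_geno(np.column_stack([good, bad])))
        assert report.n_removed_hwe == 1
        assert list(Gq.variant_ids) == ["v0"]

    def test_dosage_data_skips_hwe(self, rng):
        d = rng.uniform(0, 2, (100, 2))
        G = _geno(d)
        G.hard_calls = False
        Gq, report = qc_filter(G)
        assert report.n_removed_hwe == 0

    def test_empty_result_warns_not_errors(self):
        d = np.zeros((50, 1))
        Gq, report = qc_filter(_geno(d))
        assert Gq.n_variants == 0 and report.n_kept == 0


class TestAssocScan:
    def test_orthogonal_residuals_zero_beta(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        y = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        y = y - np.polyval(np.polyfit(g, y, 1), g)  # project out the dosage
        res = assoc_scan(y, _geno(g[:, None]))
        assert res["beta"][0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.1 * g + rng.standard_normal(n)
        res = assoc_scan(y, _geno(g[:, None]))
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert res["beta"][0] == pytest.approx(fit.params[1], rel=1e-10)
        assert res["se"][0] == pytest.approx(fit.bse[1], rel=1e-10)
        assert res["p"][0] == pytest.approx(fit.pvalues[1], rel=1e-10)

    def test_constant_dosage_emits_na(self):
        res = assoc_scan(np.array([0.1, -0.2, 0.3]), _geno(np.ones((3, 1))))
        assert len(res) == 1 and np.isnan(res["p"][0])

    def test_missing_handled_complete_case(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        gm = g.copy()
        gm[:50] = np.nan
        res_full = assoc_scan(y[50:], _geno(g[50:, None]))
        res_miss = assoc_scan(y, _geno(gm[:, None]))
        assert res_miss["beta"][0] == pytest.approx(res_full["beta"][0], rel=1e-10)
        assert res_miss["n"][0] == 150

    def test_intercept_absorbs_residual_shift(self, rng):
        n = 100
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.standard_normal(n)
        r1 = assoc_scan(y, _geno(g[:, None]))
        r2 = assoc_scan(y + 5.0, _geno(g[:, None]))
        assert r1["beta"][0] == pytest.approx(r2["beta"][0], rel=1e-12)

    def test_gws_threshold_value(self):
        assert GWS_THRESHOLD == 5.0e-8


class TestStratifiedScan:
    def _study(self, n=600, seed=4):
        rng = np.random.default_rng(seed)
        cohort = toy_cohort(n, seed=seed)
        G = _geno(rng.binomial(2, 0.3, (n, 5)).astype(float))
        return cohort, G

    def test_all_stratum_equals_plain_scan(self):
        cohort, G = self._study()
        _, resid = cohort_null_residuals(cohort)
        direct = assoc_scan(resid, G)
        strat = stratified_scan(cohort, G, "all")
        pd.testing.assert_frame_equal(direct, strat)

    def test_single_sex_equals_unstratified_without_sex(self):
        cohort, G = self._study()
        males = cohort["sex"] == 1
        sub = cohort.loc[males].reset_index(drop=True)
        Gs = G.subset(subjects=males.to_numpy())
        _, resid = cohort_null_residuals(sub, ["pc1", "pc2", "pc3", "pc4", "pc5"])
        expected = assoc_scan(resid, Gs)
        got = stratified_scan(cohort, G, "male")
        pd.testing.assert_frame_equal(expected, got)

    def test_zero_event_stratum_errors(self):
        cohort, G = self._study()
        cohort.loc[cohort["sex"] == 0, "event"] = 0
        with pytest.raises(ValueError, match="zero events"):
            stratified_scan(cohort, G, "female")


class TestInflation:
    def test_uniform_pvalues_lambda_near_one(self, rng):
        lam = genomic_inflation(rng.uniform(0, 1, 20_000))
        assert lam == pytest.approx(1.0, abs=0.03)
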