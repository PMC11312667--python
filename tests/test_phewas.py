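import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survgwas.phewas import (
    carrier_enrichment,
    filter_phenotypes,
    phewas_threshold,
    run_phewas,
    truncate_sig,
)


def _meta(rows):
    return pd.DataFrame(rows, columns=["phenotype_id", "kind", "code"])


class TestFilterPhenotypes:
    def _matrix(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            {
                "p99": np.r_[np.ones(99), np.zeros(n - 99)],
                "p100": np.r_[np.ones(100), np.zeros(n - 100)],
                "cont100": np.r_[rng.standard_normal(100), np.full(n - 100, np.nan)],
                "cont99": np.r_[rng.standard_normal(99), np.full(n - 99, np.nan)],
                "excluded": np.r_[np.ones(500), np.zeros(n - 500)],
            }
        )
        meta = _meta(
            [
                {"phenotype_id": "p99", "kind": "binary", "code": "C10"},
                {"phenotype_id": "p100", "kind": "binary", "code": "C11"},
                {"phenotype_id": "cont100", "kind": "continuous", "code": ""},
                {"phenotype_id": "cont99", "kind": "continuous", "code": ""},
                {"phenotype_id": "excluded", "kind": "binary", "code": "V01"},
            ]
        )
        return values, meta

    def test_case_count_boundaries_and_chapter_exclusion(self):
        values, meta = self._matrix()
        out_v, out_m = filter_phenotypes(values, meta)
        kept = set(out_m["phenotype_id"])
        # 99 cases removed, 100 retained; <100 non-missing removed; V-chapter removed
        assert kept == {"p100", "cont100"}

    def test_idempotent(self):
        values, meta = self._matrix()
        v1, m1 = filter_phenotypes(values, meta)
        v2, m2 = filter_phenotypes(v1, m1)
        assert list(v1.columns) == list(v2.columns)
        pd.testing.assert_frame_equal(m1, m2)


class TestRunPhewas:
    def test_constant_phenotype_na(self):
        n = 300
        rng = np.random.default_rng(1)
        carrier = rng.binomial(1, 0.2, n)
        values = pd.DataFrame({"flat": np.ones(n)})
        meta = _meta([{"phenotype_id": "flat", "kind": "binary", "code": ""}])
        res = run_phewas(carrier, values, meta)
        assert res[0].model == "na" and np.isnan(res[0].p)

    def test_continuous_effect_recovery(self):
        n = 2000
        rng = np.random.default_rng(2)
        carrier = rng.binomial(1, 0.3, n)
        values = pd.DataFrame({"y": rng.standard_normal(n) + 0.8 * carrier})
        meta = _meta([{"phenotype_id": "y", "kind": "continuous", "code": ""}])
        res = run_phewas(carrier, values, meta)
        assert res[0].model == "linear"
        assert res[0].effect == pytest.approx(0.8, abs=0.15)

    def test_logistic_or_recovery_moderate(self):
        n = 4000
        rng = np.random.default_rng(3)
        carrier = rng.binomial(1, 0.3, n)
        logit = -1.5 + np.log(2.0) * carrier
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        values = pd.DataFrame({"y": y.astype(float)})
        meta = _meta([{"phenotype_id": "y", "kind": "binary", "code": ""}])
        res = run_phewas(carrier, values, meta)
        assert res[0].model == "logistic"
        assert res[0].effect == pytest.approx(2.0, rel=0.25)

    def test_covariate_adjustment_kills_confounded_signal(self):
        n = 3000
        rng = np.random.default_rng(4)
        age = rng.uniform(40, 80, n)
        carrier = (age > 60).astype(int)  # carrier purely a function of age
        y = 0.05 * age + rng.standard_normal(n)
        values = pd.DataFrame({"y": y})
        meta = _meta([{"phenotype_id": "y", "kind": "continuous", "code": ""}])
        adj = run_phewas(carrier, values, meta, covariates=pd.DataFrame({"age": age}))
        raw = run_phewas(carrier, values, meta)
        assert raw[0].p < 1e-10
        assert adj[0].p > 1e-4


class TestThreshold:
    def test_full_phenome_display_value(self):
        full, display = phewas_threshold(1670)
        assert full == pytest.approx(0.05 / 1670)
        assert display == pytest.approx(2.9e-5)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (500, 1e-4)])
    def test_arithmetic(self, n, expected):
        assert phewas_threshold(n)[0] == pytest.approx(expected)

    def test_truncation_not_rounding(self):
        assert truncate_sig(2.994e-5) == pytest.approx(2.9e-5)
        assert truncate_sig(0.0599) == pytest.approx(0.059)

    def test_zero_phenotypes_error(self):
        with pytest.raises(ValueError):
            phewas_threshold(0)


class TestCarrierEnrichment:
    def test_hand_computed_chi_square(self):
        # 2x2 table: in-category 30 carriers / 70 non; others 15 / 85
        carrier = np.r_[np.ones(30), np.zeros(70), np.ones(15), np.zeros(85)].astype(int)
        labels = np.r_[["cat"] * 100, ["other"] * 100]
        table = np.array([[30, 70], [15, 85]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        out = carrier_enrichment(carrier, labels)
        row = out.loc[out["category"] == "cat"].iloc[0]
        assert row["chi2"] == pytest.approx(chi2_hand, rel=1e-12)
        assert row["p"] == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-12)

    def test_equal_proportion_near_zero(self):
        carrier = np.r_[np.ones(20), np.zeros(80), np.ones(20), np.zeros(80)].astype(int)
        labels = np.r_[["a"] * 100, ["b"] * 100]
        out = carrier_enrichment(carrier, labels)
        assert (out["chi2"] < 1e-10).all()
        assert (out["p"] > 0.999).all()

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        carrier = rng.binomial(1, 0.3, 400)
        labels = rng.choice(["x", "y", "z"], 400)
        out1 = carrier_enrichment(carrier, labels)
        out2 = carrier_enrichment(1 - carrier, labels)
        np.testing.assert_allclose(
            out1.sort_values("category")["chi2"], out2.sort_values("category")["chi2"], rtol=1e-10
        )

    def test_degenerate_prevalence_errors(self):
        with pytest.raises(ValueError):
            carrier_enrichment(np.ones(10, dtype=int), np.r_[["a"] * 5, ["b"] * 5])
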