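import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import matrix
from oracles import brute_hypergeom_upper, two_pass_pearson
from peakvar import integrate


class TestBindingModel:
    def test_perfect_linear_fit(self, rng):
        x = rng.normal(size=100)
        fit = integrate.fit_binding_model(2.0 * x, x)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["motif"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_r2_equals_squared_pearson_single_predictor(self, rng):
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        fit = integrate.fit_binding_model(y, x)
        assert fit.r_squared == pytest.approx(two_pass_pearson(x, y) ** 2, abs=1e-10)

    def test_permuted_predictor_explains_nothing(self, rng):
        x = rng.normal(size=5000)
        y = 0.5 * x + rng.normal(size=5000)
        fit = integrate.fit_binding_model(y, rng.permutation(x))
        assert fit.r_squared < 0.01

    def test_extra_noise_predictor_never_decreases_r2(self, rng):
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(size=300)
        noise = rng.normal(size=300)
        single = integrate.fit_binding_model(y, x)
        double = integrate.fit_binding_model(y, x, noise)
        assert double.r_squared >= single.r_squared - 1e-12

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="collinear"):
            integrate.fit_binding_model(x, x, 2.0 * x)

    def test_minimum_observations(self):
        with pytest.raises(ValueError, match=">=10"):
            integrate.fit_binding_model(np.arange(5.0), np.arange(5.0))


class TestDeltaDelta:
    def test_exact_accessibility_driven_change(self, rng):
        bind_a = rng.uniform(1, 20, size=200)
        acc_a = rng.uniform(1, 10, size=200)
        acc_b = acc_a * rng.uniform(0.5, 2.0, size=200)
        bind_b = bind_a * (acc_b / acc_a)
        summary, r2 = integrate.delta_delta_correlation(
            bind_a, bind_b, acc_a, acc_b, pseudocount=0.0
        )
        assert summary.r == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_no_accessibility_change_is_error(self, rng):
        bind = rng.uniform(1, 10, size=50)
        acc = rng.uniform(1, 10, size=50)
        with pytest.raises(ValueError, match="zero variance"):
            integrate.delta_delta_correlation(bind, bind * 2, acc, acc)

    def test_planted_r2_recovered(self, rng):
        """dbind = dacc + noise tuned to a true r^2 of 0.25."""
        n = 5000
        estimates = []
        for _ in range(20):
            dacc = rng.normal(0, 1, size=n)
            noise = rng.normal(0, np.sqrt(3.0), size=n)  # var ratio 1:3 -> r2 0.25
            bind_a = np.exp2(rng.normal(4, 1, size=n))
            bind_b = bind_a * np.exp2(dacc + noise)
            acc_a = np.exp2(rng.normal(3, 1, size=n))
            acc_b = acc_a * np.exp2(dacc)
            _, r2 = integrate.delta_delta_correlation(
                bind_a, bind_b, acc_a, acc_b, pseudocount=0.0
            )
            estimates.append(r2)
        assert np.all(np.abs(np.array(estimates) - 0.25) < 0.04)


class TestBindingExpression:
    def test_identical_rows_correlate_perfectly(self, rng):
        values = rng.uniform(1, 10, size=(3, 6))
        m = matrix(values)
        expr = pd.DataFrame(
            values, index=[f"g{i}" for i in range(3)], columns=m.sample_ids
        )
        mapping = {f"pk{i}": f"g{i}" for i in range(3)}
        out = integrate.binding_expression_association(m, expr, mapping)
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-12)

    def test_too_few_shared_samples(self, rng):
        m = matrix(rng.uniform(1, 5, size=(2, 4)))
        expr = pd.DataFrame(
            rng.uniform(1, 5, size=(2, 2)), index=["g0", "g1"], columns=["s0", "s1"]
        )
        with pytest.raises(ValueError, match="shared"):
            integrate.binding_expression_association(
                m, expr, {"pk0": "g0", "pk1": "g1"}
            )

    def test_group_test_identity(self, rng):
        r = rng.uniform(-0.5, 0.5, size=40)
        t, df, p = integrate.group_correlation_test(r, r)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_group_test_separates_correlated_from_null(self, rng):
        """r's of a correlated model vs a null model: strong separation."""
        n_samples, n_per_group = 12, 200
        for _ in range(5):
            shared = rng.normal(size=(n_per_group, n_samples))
            corr_r = [
                two_pass_pearson(s, s + rng.normal(0, 0.8, size=n_samples))
                for s in shared
            ]
            null_r = [
                two_pass_pearson(rng.normal(size=n_samples), rng.normal(size=n_samples))
                for _ in range(n_per_group)
            ]
            _, _, p = integrate.group_correlation_test(corr_r, null_r)
            assert p < 1e-6


class TestHypergeometric:
    def test_worked_example(self):
        res = integrate.hypergeometric_enrichment(
            query=set("abcdefghij"),
            terms={"t": set("abcde")},
            universe=set("abcdefghijklmnopqrst"),
        )
        # all 5 term genes hit: p = C(15,5)/C(20,10) = 3003/184756
        assert res.loc["t", "p"] == pytest.approx(3003 / 184756, abs=1e-12)

    def test_zero_hits_p_one(self):
        res = integrate.hypergeometric_enrichment(
            query={"x", "y"},
            terms={"t": {"a", "b"}},
            universe={"x", "y", "a", "b", "c"},
        )
        assert res.loc["t", "k"] == 0
        assert res.loc["t", "p"] == pytest.approx(1.0)

    def test_single_term_correction_is_identity(self):
        for correction in ("BH", "bonferroni"):
            res = integrate.hypergeometric_enrichment(
                query={"a", "b"},
                terms={"t": {"a", "c"}},
                universe={"a", "b", "c", "d"},
                correction=correction,
            )
            assert res.loc["t", "p_adj"] == pytest.approx(res.loc["t", "p"])

    def test_matches_enumeration_small_universes(self):
        universe = [f"g{i}" for i in range(12)]
        for N in range(2, 13):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    res = integrate.hypergeometric_enrichment(
                        query=set(universe[:n]),
                        terms={"t": set(universe[:K])},
                        universe=set(universe[:N]),
                    )
                    k = len(set(universe[:n]) & set(universe[:K]))
                    want = brute_hypergeom_upper(N, K, n, k)
                    assert res.loc["t", "p"] == pytest.approx(want, abs=1e-12)

    def test_bh_monotone_and_bounded(self, rng):
        universe = {f"g{i}" for i in range(50)}
        query = set(rng.choice(sorted(universe), size=15, replace=False))
        terms = {
            f"t{j}": set(rng.choice(sorted(universe), size=10, replace=False))
            for j in range(20)
        }
        res = integrate.hypergeometric_enrichment(query, terms, universe)
        assert (res["p_adj"] <= 1.0 + 1e-12).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["p_adj"].is_monotonic_increasing  # sorted by p

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            integrate.hypergeometric_enrichment(set(), {"t": {"a"}}, {"a"})
        with pytest.raises(ValueError):
            integrate.hypergeometric_enrichment({"a"}, {"t": {"a"}}, set())


class TestBinSummary:
    def test_identity_relation_monotone_medians(self, rng):
        x = rng.normal(size=200)
        res = integrate.bin_summary(x, x, n_bins=5)
        meds = res["median"].to_numpy()
        assert (np.diff(meds) > 0).all()

    def test_one_point_per_bin(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 30.0])
        res = integrate.bin_summary(x, y, n_bins=3)
        np.testing.assert_allclose(res["median"], y)
        assert (res["count"] == 1).all()

    def test_independent_y_flat_medians(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        res = integrate.bin_summary(x, y, n_bins=5)
        rho = stats.spearmanr(res.index.to_numpy(), res["median"]).statistic
        assert abs(res["median"]).max() < 0.2
        assert np.isfinite(rho)

    def test_tied_bins_merge_with_warning(self, caplog):
        import logging

        x = np.array([1.0] * 10 + [2.0] * 2)
        y = np.arange(12.0)
        with caplog.at_level(logging.WARNING):
            res = integrate.bin_summary(x, y, n_bins=5)
        assert len(res) < 5
        assert "ties" in caplog.text
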