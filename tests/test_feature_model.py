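import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from songprov.errors import StatisticsError
from songprov.feature_model import (
    RESPONSE,
    SvmParams,
    default_lambda_grid,
    lambda_max,
    lasso_fit,
    lasso_objective,
    lasso_path,
    loo_predict,
    select_features,
    spearman,
    standardize,
    svm_regress,
)


def orthonormal_design(n, p, rng):
    """Mean-zero columns with X'X = n I, so OLS_j = x_j'y / n."""
    a = rng.standard_normal((n, p))
    a -= a.mean(axis=0)  # QR of centred columns keeps them mean-zero
    q, _ = np.linalg.qr(a)
    return q * math.sqrt(n)


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_closed_form_sample_sd(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out, rec = standardize(df)
        # sample SD (ddof=1) of {2,4,6} is 2
        assert list(out["x"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert rec.scale["x"] == pytest.approx(2.0)

    def test_population_sd_option(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out, _ = standardize(df, ddof=0)
        assert list(out["x"]) == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_idempotent_within_tolerance(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        once, _ = standardize(df)
        twice, _ = standardize(once)
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_year_reference_coding(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "year": [2010, 2011, 2012, 2010]}
        )
        out, rec = standardize(df)
        assert set(rec.dummy_columns) == {"year_2011", "year_2012"}
        assert "year" not in out.columns

    def test_zero_variance_named(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(StatisticsError, match="flat"):
            standardize(df)

    def test_scaling_record_roundtrip(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 30), "b": rng.normal(-2, 0.5, 30)})
        out, rec = standardize(df)
        fresh = rec.transform(df)
        assert np.allclose(fresh, out)


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------

class TestLasso:
    def test_lambda_max_gives_all_zero(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30) + X[:, 0]
        lmax = lambda_max(X, y)
        for lam in (lmax, 2 * lmax, 10 * lmax):
            beta, _, _ = lasso_fit(X, y, lam)
            assert np.all(beta == 0.0)

    def test_just_below_lambda_max_nonzero(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30) + 2 * X[:, 0]
        beta, _, _ = lasso_fit(X, y, 0.99 * lambda_max(X, y))
        assert np.any(beta != 0.0)

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        n, p = 64, 6
        X = orthonormal_design(n, p, rng)
        y = rng.standard_normal(n) + X @ np.array([2.0, -1.5, 0.8, 0.0, 0.0, 0.3])
        yc = y - y.mean()
        ols = X.T @ yc / n  # orthonormal-in-n sense
        for lam in (0.05, 0.2, 0.5, 1.0):
            beta, _, _ = lasso_fit(X, y, lam)
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            assert np.allclose(beta, expected, atol=1e-6)

    def test_lambda_zero_equals_ols(self, rng):
        n, p = 40, 5
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        beta, intercept, _ = lasso_fit(X, y, 0.0)
        A = np.column_stack([np.ones(n), X])
        coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(beta, coefs[1:], atol=1e-6)
        assert intercept == pytest.approx(coefs[0], abs=1e-6)

    def test_objective_beats_random_perturbations(self, rng):
        n, p = 20, 11
        X = rng.standard_normal((n, p))
        y = X[:, :3].sum(axis=1) + rng.standard_normal(n)
        for lam in (0.05, 0.3, 1.0):
            beta, intercept, _ = lasso_fit(X, y, lam)
            obj = lasso_objective(X, y, beta, intercept, lam)
            for _ in range(300):
                noise = rng.standard_normal(p) * rng.choice([1e-3, 1e-2, 1e-1])
                perturbed = lasso_objective(X, y, beta + noise, intercept, lam)
                assert perturbed >= obj - 1e-12

    def test_path_sparsity_monotone_orthonormal(self, rng):
        # exact monotonicity holds in the orthonormal case
        X = orthonormal_design(64, 6, rng)
        y = X @ np.array([2.0, -1.5, 0.8, 0.4, 0.2, 0.1]) + rng.standard_normal(64)
        fits = lasso_path(X, y, n_lambdas=50)
        sizes = [len(f.selected) for f in fits]  # lambdas decreasing
        assert sizes == sorted(sizes)

    def test_warm_start_path_matches_cold_fits(self, rng):
        X = rng.standard_normal((25, 7))
        y = X[:, 0] - X[:, 3] + 0.5 * rng.standard_normal(25)
        grid = default_lambda_grid(X, y, n_lambdas=20)
        fits = lasso_path(X, y, lambdas=grid)
        for fit in fits[::5]:
            cold, _, _ = lasso_fit(X, y, fit.lam)
            warm = np.array([fit.coef[k] for k in sorted(fit.coef)])
            cold_named = dict(zip([f"x{j}" for j in range(7)], cold))
            cold_sorted = np.array([cold_named[k] for k in sorted(cold_named)])
            assert np.allclose(warm, cold_sorted, atol=1e-5)

    def test_exact_zeros_not_thresholded(self, rng):
        X = rng.standard_normal((30, 6))
        y = 3 * X[:, 0] + 0.1 * rng.standard_normal(30)
        beta, _, _ = lasso_fit(X, y, 0.5 * lambda_max(X, y))
        assert set(np.unique(beta[beta == 0.0])) <= {0.0}
        assert np.sum(beta == 0.0) >= 1


# ---------------------------------------------------------------------------
# select_features
# ---------------------------------------------------------------------------

class TestSelectFeatures:
    def test_single_exact_predictor(self, rng):
        X = rng.standard_normal((50, 5))
        y = 2.0 * X[:, 2]
        sel = select_features(X, y, seed=0)
        assert sel.selected[0] == "x2"
        assert sel.coef["x2"] == pytest.approx(2.0, abs=0.15)

    def test_planted_recovery_small(self, rng):
        hits = 0
        for _ in range(20):
            X = rng.standard_normal((200, 11))
            y = X[:, :4] @ np.ones(4) + rng.standard_normal(200)
            sel = select_features(X, y, seed=rng)
            if all(f"x{j}" in sel.selected for j in range(4)):
                hits += 1
        assert hits >= 18

    def test_pure_noise_selects_little(self, rng):
        import warnings

        sizes = []
        for _ in range(20):
            X = rng.standard_normal((200, 11))
            y = rng.standard_normal(200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty selection is expected
                sel = select_features(X, y, seed=rng)
            sizes.append(len(sel.selected))
        assert np.median(sizes) <= 1

    def test_ordering_by_magnitude(self, rng):
        X = rng.standard_normal((100, 5))
        y = 3 * X[:, 1] + 1 * X[:, 4] + 0.2 * rng.standard_normal(100)
        sel = select_features(X, y, seed=0)
        coefs = [abs(sel.coef[k]) for k in sel.selected]
        assert coefs == sorted(coefs, reverse=True)
        assert sel.selected[0] == "x1"

    def test_1se_rule_sparser_or_equal(self, rng):
        X = rng.standard_normal((60, 8))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(60)
        s_min = select_features(X, y, rule="min", seed=1)
        s_1se = select_features(X, y, rule="1se", seed=1)
        assert len(s_1se.selected) <= len(s_min.selected)
        assert s_1se.lam >= s_min.lam


# ---------------------------------------------------------------------------
# svm_regress
# ---------------------------------------------------------------------------

class TestSvmRegress:
    def test_constant_response(self, rng):
        X = rng.standard_normal((15, 3))
        y = np.full(15, 4.2)
        pred = svm_regress(X, y, rng.standard_normal((5, 3)))
        assert np.allclose(pred, 4.2, atol=1e-9)

    def test_linear_noiseless_within_epsilon(self, rng):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = 2.0 * X[:, 0]
        params = SvmParams(kernel="linear", C=1000.0, epsilon=0.1)
        pred = svm_regress(X, y, X, params=params)
        assert np.all(np.abs(pred - y) <= 0.1 + 1e-6)

    def test_duplicate_training_point_interpolated(self, rng):
        X = rng.standard_normal((25, 2))
        y = X[:, 0] + 0.3 * X[:, 1]
        params = SvmParams(C=1000.0, epsilon=0.05)
        pred = svm_regress(X, y, X[7], params=params)
        assert abs(pred[0] - y[7]) <= 0.05 + 1e-6


# ---------------------------------------------------------------------------
# loo_predict
# ---------------------------------------------------------------------------

def toy_table(rng, n=8):
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = 10 + 2 * x1 - x2 + 0.1 * rng.standard_normal(n)
    return pd.DataFrame({"x1": x1, "x2": x2, RESPONSE: y})


class TestLooPredict:
    def test_round_count_and_shape(self, rng):
        table = toy_table(rng)
        loo = loo_predict(table, ["x1", "x2"])
        assert len(loo.table) == len(table)
        assert list(loo.table.columns) == ["observed", "predicted"]

    def test_leakage_probe(self, rng):
        table = toy_table(rng, n=6)
        loo = loo_predict(table, ["x1", "x2"])
        for i in range(len(table)):
            poked = table.copy()
            poked.iloc[i, poked.columns.get_loc(RESPONSE)] += 100.0
            loo2 = loo_predict(poked, ["x1", "x2"])
            assert loo2.table["predicted"].iloc[i] == pytest.approx(
                loo.table["predicted"].iloc[i], abs=1e-12
            )

    def test_needs_three_rows(self, rng):
        with pytest.raises(StatisticsError):
            loo_predict(toy_table(rng, n=2), ["x1"])

    def test_selector_mode_reselects_per_round(self, rng):
        table = toy_table(rng, n=10)
        calls = []

        def selector(train):
            calls.append(len(train))
            return ["x1", "x2"]

        loo = loo_predict(table, [], selector=selector)
        assert loo.mode == "refit"
        assert calls == [9] * 10

    def test_strong_signal_positive_rho(self, rng):
        table = toy_table(rng, n=20)
        loo = loo_predict(table, ["x1", "x2"])
        ev = spearman(loo.predicted, loo.observed)
        assert ev.spearman_rho > 0.5


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

class TestPlantedSignRecovery:
    def test_selected_planted_measures_positive(self):
        """Coefficients of the planted-effect measures keep their sign.

        The generator plants positive effects of orderliness (shortest
        path) and the three category repertoire sizes on feeding rate;
        whenever one of those four measures is selected its coefficient is
        positive in >= 90% of replicates.  (Emergent measures like
        transitivity may legitimately enter with a negative sign: a more
        cyclic walk has fewer triangles.)
        """
        import warnings

        from songprov.synthetic_data import SimulationConfig, simulate_study

        from conftest import study_feature_table

        planted = (
            "average_shortest_path",
            "whistle_repertoire",
            "trill_repertoire",
            "buzz_repertoire",
        )
        ok = 0
        n_rep = 30
        for rep in range(n_rep):
            study = simulate_study(SimulationConfig(seed=7_000 + rep))
            table = study_feature_table(study)
            std, _ = standardize(
                table[
                    list(planted)
                    + [
                        "repertoire_size", "whistle_occurrence",
                        "trill_occurrence", "buzz_occurrence", "transitivity",
                        "n_hatchlings", "year",
                    ]
                ]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_features(
                    std.to_numpy(float),
                    table[RESPONSE].to_numpy(float),
                    feature_names=list(std.columns),
                    seed=rep,
                )
            if all(sel.coef[k] >= 0 for k in sel.selected if k in planted):
                ok += 1
        assert ok >= 0.9 * n_rep


class TestSpearman:
    def test_identical_vectors(self):
        ev = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert ev.spearman_rho == 1.0
        assert ev.p_value == 0.0

    def test_reversed_ranks(self):
        ev = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert ev.spearman_rho == -1.0

    def test_tie_corrected_against_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]

        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        )
        ev = spearman(x, y)
        assert ev.spearman_rho == pytest.approx(num / den, rel=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        ev = spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert ev.spearman_rho == pytest.approx(rho, rel=1e-12)
        assert ev.p_value == pytest.approx(p, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatisticsError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        ev_t = spearman(x, y, method="t")
        ev_e = spearman(x, y, method="exact")
        assert ev_e.spearman_rho == ev_t.spearman_rho
        assert 0.0 < ev_e.p_value <= 1.0

    def test_exact_rejects_large_n(self):
        with pytest.raises(StatisticsError):
            spearman(list(range(12)), list(range(12)), method="exact")
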