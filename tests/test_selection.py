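import numpy as np
import pandas as pd
import pytest

from petfusion import phantom
from petfusion.selection import (FusedFeatureSpec, SelectionConfig, cross_cohort_refine,
                                 elastic_net_fit, elastic_net_path, prune_redundant,
                                 select_features, stability_filter)


def _soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


class TestElasticNet:
    def test_orthonormal_design_soft_threshold(self):
        # X^T X = n I  =>  lasso solution is soft(X_j . y / n, lam) elementwise
        rng = np.random.default_rng(0)
        n, p = 64, 6
        q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = q * np.sqrt(n)
        beta = np.array([2.0, -1.0, 0.5, 0.0, 0.0, 0.1])
        y = X @ beta
        for lam in (0.05, 0.3, 1.0):
            got = elastic_net_fit(X, y, lam, alpha=1.0)
            want = _soft(X.T @ y / n, lam)
            assert np.allclose(got, want, atol=1e-8), lam

    def test_elastic_net_mixed_penalty_closed_form(self):
        # orthonormal design, alpha in (0,1): b_j = soft(z_j, lam*alpha)/(1 + lam*(1-alpha))
        rng = np.random.default_rng(1)
        n, p = 50, 4
        q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = q * np.sqrt(n)
        y = X @ np.array([1.5, -0.7, 0.0, 0.2]) + 0.01 * rng.standard_normal(n)
        lam, alpha = 0.4, 0.5
        got = elastic_net_fit(X, y, lam, alpha)
        want = _soft(X.T @ y / n, lam * alpha) / (1 + lam * (1 - alpha))
        assert np.allclose(got, want, atol=1e-8)

    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        got = elastic_net_fit(X, y, 0.0, 0.5)
        want = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(got, want, atol=1e-10)

    def test_path_retains_informative_columns(self):
        rng = np.random.default_rng(3)
        n = 90
        y = np.repeat(["a", "b", "c"], n // 3)
        X = pd.DataFrame(rng.standard_normal((n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        X["f0"] += 2.0 * (y == "a")
        X["f1"] -= 2.0 * (y == "c")
        X = (X - X.mean()) / X.std(ddof=0)
        res = elastic_net_path(X, y, alpha=0.5, folds=5, seed=0)
        assert {"f0", "f1"} <= set(res.retained)
        assert res.lambda_star in res.lambda_path
        assert res.weights.shape == (8, 3)

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)))
        with pytest.raises(ValueError):
            elastic_net_path(X, ["a"] * 10, alpha=0.5, folds=2)


class TestStages:
    def test_stability_filter_rules(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame({"ok": rng.standard_normal(200),
                          "flat": np.zeros(200),
                          "shifted": rng.standard_normal(200)})
        b = pd.DataFrame({"ok": rng.standard_normal(200),
                          "flat": np.zeros(200),
                          "shifted": rng.standard_normal(200) + 3.0})
        kept, audit = stability_filter(a, b)
        assert kept == ["ok"]
        assert audit["flat"] == "variance"
        assert audit["shifted"] == "distribution"
        with pytest.raises(ValueError):
            stability_filter(a, b[["flat", "ok", "shifted"]])

    def test_cross_cohort_refine_profile_correlation(self):
        idx = ["x", "y", "z"]
        wa = pd.DataFrame([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [0.5, 0.2, -0.7]],
                          index=idx, columns=list("abc"))
        wb = wa.copy()
        wb.loc["y"] = [-1.0, 0.0, 1.0]       # anticorrelated profile
        ra = _result(idx, wa)
        rb = _result(idx, wb)
        kept, audit = cross_cohort_refine(ra, rb, r_threshold=0.6)
        assert kept == ["x", "z"]
        assert audit["y"].startswith("intercohort_r=")

    def test_prune_redundant_greedy_by_weight(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(100)
        table = pd.DataFrame({"big": base, "dup": base + 1e-3 * rng.standard_normal(100),
                              "other": rng.standard_normal(100)})
        weights = pd.Series({"big": 2.0, "dup": 1.0, "other": 0.5})
        kept, audit = prune_redundant(table, weights, r_threshold=0.5)
        assert kept == ["big", "other"]
        assert audit["dup"] == "collinear_with=big"


def _result(idx, weights):
    from petfusion.selection import SelectionResult

    return SelectionResult(retained=list(idx), weights=weights, lambda_star=0.1,
                           lambda_path=np.array([0.1]), cv_mse=np.array([0.0]), alpha=1.0)


class TestCascade:
    def test_planted_tables_recovery_single_draw(self):
        ta, tb, ya, yb, informative = phantom.planted_tables(seed=11)
        spec = select_features({"A": ta, "B": tb}, {"A": ya, "B": yb},
                               config=SelectionConfig(seed=11))
        recall = len(set(spec.radiomics) & set(informative)) / len(informative)
        assert recall >= 0.6        # single draw; the >=0.8 criterion is Monte-Carlo
        counts = spec.audit["counts"]
        assert counts["input"] >= counts["stage1"] >= counts["stage2b"] >= counts["stage3"]

    def test_latent_ranking_and_spec_order(self):
        rng = np.random.default_rng(6)
        ta, tb, ya, yb, _ = phantom.planted_tables(seed=2)
        loc = pd.DataFrame(rng.standard_normal((90, 8)),
                           columns=[f"Local_latent_{i}" for i in range(8)])
        for i in range(5):
            loc[f"Local_latent_{i}"] += 1.5 * (ya == i % 3)
        glo = pd.DataFrame(rng.standard_normal((90, 8)),
                           columns=[f"Global_latent_{i}" for i in range(8)])
        for i in range(5):
            glo[f"Global_latent_{i}"] += 1.5 * (ya == (i + 1) % 3)
        spec = select_features({"A": ta, "B": tb}, {"A": ya, "B": yb},
                               local_latents=loc, global_latents=glo, latent_labels=ya,
                               config=SelectionConfig(seed=3))
        assert len(spec.local) == 5 and len(spec.global_) == 5
        assert all(c.startswith("Local_") for c in spec.local)
        assert spec.columns == spec.radiomics + spec.local + spec.global_
        assert spec.width == len(spec.columns)

    def test_single_cohort_mode_skips_cross_rules(self):
        ta, _, ya, _, _ = phantom.planted_tables(seed=4)
        spec = select_features({"A": ta}, {"A": ya}, config=SelectionConfig(seed=4))
        assert spec.audit["stage1_removed"]["__distribution_rule__"].startswith("skipped")
        assert spec.audit["stage2b_removed"]["__intercohort_rule__"].startswith("skipped")
        assert len(spec.radiomics) > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(intercohort_r=1.5)
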