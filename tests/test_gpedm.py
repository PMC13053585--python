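"""GP-EDM: embedding construction, kernel algebra, posterior, LOO, suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from trophiclink import gpedm, synthgrid
from trophiclink.errors import EmbeddingError, FitError
from trophiclink.gpedm import (
    DelayMatrix,
    EmbeddingSpec,
    GPConfig,
    GPHyperparams,
    build_embedding,
    fit,
    gram_matrix,
    kernel,
    log_posterior,
)

from conftest import random_paired_panel


def complete_panel(years=11, n_cells=1, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cells):
        for t in range(years):
            rows.append((100_000, c, 0, 2000 + t, rng.normal(), rng.normal(),
                         rng.normal(9, 1), rng.normal(900, 30),
                         rng.normal(8, 1), rng.normal(180, 20),
                         rng.normal(15, 1), rng.normal(190, 20),
                         rng.normal(3, 1), rng.normal(260, 20), c, 0))
    return pd.DataFrame(rows, columns=[
        "scale_m", "ix", "iy", "year", "insectivore_value", "insect_value",
        "temp_annual", "precip_annual", "temp_spring", "precip_spring",
        "temp_summer", "precip_summer", "temp_winter", "precip_winter",
        "region_ix", "region_iy"])


class TestBuildEmbedding:
    def test_defaults(self):
        spec = EmbeddingSpec()
        assert spec.tau == 1 and spec.E == 3

    def test_row_count_for_complete_run(self):
        # years 2000-2010 complete, E=3 -> targets 2003..2010 = 8 rows
        dm = build_embedding(complete_panel(11), EmbeddingSpec())
        assert len(dm.y) == 8
        assert dm.years.tolist() == list(range(2003, 2011))

    def test_missing_variable_raises(self):
        panel = complete_panel(11).drop(columns=["temp_spring"])
        with pytest.raises(EmbeddingError):
            build_embedding(panel, EmbeddingSpec(weather_set="spring"))

    def test_all_nan_weather_column_raises(self):
        panel = complete_panel(11)
        panel["temp_spring"] = np.nan
        with pytest.raises(EmbeddingError):
            build_embedding(panel, EmbeddingSpec(weather_set="spring"))

    def test_gap_restricts_to_longest_run(self):
        panel = complete_panel(15)
        panel = panel[panel["year"] != 2004]  # split: 2000-2003 and 2005-2014
        dm = build_embedding(panel, EmbeddingSpec())
        assert dm.years.min() == 2008 and dm.years.max() == 2014

    def test_columns_standardized(self):
        dm = build_embedding(complete_panel(20), EmbeddingSpec(include_insect=True))
        assert np.allclose(dm.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(dm.X.std(axis=0, ddof=1), 1, atol=1e-12)
        assert len(dm.columns) == 6


class TestKernel:
    def test_same_point_same_cell(self):
        h = GPHyperparams(phi=np.array([0.5, 0.5]), ve=0.3, rho=0.7)
        assert kernel([1, 2], [1, 2], 0, 0, h) == pytest.approx(0.7)

    def test_zero_rho_across_cells(self):
        h = GPHyperparams(phi=np.array([0.5]), ve=0.3, rho=0.0)
        assert kernel([1.0], [0.5], 0, 1, h) == 0.0

    def test_zero_phi_constant_function(self):
        h = GPHyperparams(phi=np.zeros(3), ve=0.2, rho=1.0)
        assert kernel([9, 9, 9], [-4, 0, 2], 0, 0, h) == pytest.approx(0.8)

    def test_dimension_mismatch(self):
        h = GPHyperparams(phi=np.array([0.5]), ve=0.3, rho=0.5)
        with pytest.raises(FitError, match="dimension"):
            kernel([1, 2], [1, 2], 0, 0, h)

    def test_gram_psd_over_random_hyperparams(self, rng):
        X = rng.normal(size=(25, 3))
        cells = rng.integers(0, 4, 25)
        dm = DelayMatrix(X, rng.normal(size=25), cells, np.arange(25),
                         ["a", "b", "c"], [], 0.0, 1.0)
        for _ in range(25):
            h = GPHyperparams(phi=rng.uniform(0, 3, 3), ve=rng.uniform(0.01, 0.99),
                              rho=rng.uniform(0, 1))
            w = np.linalg.eigvalsh(gram_matrix(dm, h, noise=False))
            assert w.min() > -1e-8


def toy_dm(n=20, p=3, n_cells=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    return DelayMatrix(X, rng.normal(size=n), rng.integers(0, n_cells, n),
                       np.arange(n), [f"x{i}" for i in range(p)], [], 0.0, 1.0)


class TestLogPosterior:
    def test_single_row_closed_form(self):
        dm = DelayMatrix(np.zeros((1, 1)), np.zeros(1), np.zeros(1, int),
                         np.zeros(1, int), ["x"], [], 0.0, 1.0)
        h = GPHyperparams(phi=np.array([0.4]), ve=0.3, rho=0.5)
        c11 = (1 - h.ve) + h.ve
        expected = -0.5 * np.log(2 * np.pi) - 0.5 * np.log(c11) \
            - 0.5 * h.phi[0] ** 2  # half-normal prior term at scale 1
        assert log_posterior(dm, h) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_dense_inverse(self, rng):
        dm = toy_dm(20)
        h = GPHyperparams(phi=rng.uniform(0.1, 1.5, 3), ve=0.25, rho=0.6)
        C = gram_matrix(dm, h, noise=True)
        naive = (-0.5 * dm.y @ np.linalg.inv(C) @ dm.y
                 - 0.5 * np.log(np.linalg.det(C))
                 - 0.5 * len(dm.y) * np.log(2 * np.pi)
                 - 0.5 * np.sum(h.phi ** 2))
        assert log_posterior(dm, h) == pytest.approx(naive, abs=1e-8)

    def test_prior_monotone_in_scale(self):
        dm = toy_dm(10)
        h = GPHyperparams(phi=np.array([1.0, 1.0, 1.0]), ve=0.3, rho=0.5)
        assert log_posterior(dm, h, prior_scale=5.0) > log_posterior(dm, h, prior_scale=1.0)

    def test_analytic_gradient_matches_finite_difference(self, rng):
        dm = toy_dm(15)
        sq = gpedm._sq_diffs(dm.X)
        same = dm.cells[:, None] == dm.cells[None, :]
        theta = np.concatenate([np.log(rng.uniform(0.2, 1.0, 3)), [0.1], [-0.4]])
        _, g = gpedm._neg_logpost_grad(theta, sq, same, dm.y, 1.0)
        gn = approx_fprime(
            theta, lambda t: gpedm._neg_logpost_grad(t, sq, same, dm.y, 1.0)[0], 1e-6)
        assert np.abs(g - gn).max() < 1e-4


class TestFit:
    def test_closed_form_loo_equals_explicit_conditional(self, rng):
        dm = toy_dm(25, seed=4)
        f = fit(dm, GPConfig(n_starts=2, seed=0))
        h = f.hyperparams
        C = gram_matrix(dm, h, noise=True)
        for i in (0, 7, 24):
            idx = np.delete(np.arange(25), i)
            K_oi = C[i, idx]
            K_oo = C[np.ix_(idx, idx)]
            cond = K_oi @ np.linalg.solve(K_oo, dm.y[idx])
            assert f.loo_mean[i] == pytest.approx(cond, abs=1e-8)
            cond_var = C[i, i] - K_oi @ np.linalg.solve(K_oo, K_oi)
            assert f.loo_var[i] == pytest.approx(cond_var, abs=1e-8)

    def test_pure_noise_gives_low_r2(self):
        r2s = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 3))
            dm = DelayMatrix(X, rng.normal(size=200), rng.integers(0, 5, 200),
                             np.arange(200), ["a", "b", "c"], [], 0.0, 1.0)
            r2s.append(fit(dm, GPConfig(n_starts=2, seed=seed)).r2_oos)
        assert np.median(r2s) <= 0.1

    def test_single_row_flagged(self):
        dm = DelayMatrix(np.zeros((1, 2)), np.zeros(1), np.zeros(1, int),
                         np.zeros(1, int), ["a", "b"], [], 0.0, 1.0)
        f = fit(dm)
        assert f.loo_mean[0] == 0.0 and np.isnan(f.r2_oos)

    def test_rho_limits_pool_or_separate(self, rng):
        dm = toy_dm(12, n_cells=2, seed=1)
        base = GPHyperparams(phi=np.array([0.5, 0.5, 0.5]), ve=0.2, rho=1.0)
        pooled = gram_matrix(dm, base, noise=False)
        no_cells = DelayMatrix(dm.X, dm.y, np.zeros(12, int), dm.years,
                               dm.columns, [], 0.0, 1.0)
        assert np.allclose(pooled, gram_matrix(no_cells, base, noise=False))
        indep = gram_matrix(dm, GPHyperparams(base.phi, 0.2, 0.0), noise=False)
        across = dm.cells[:, None] != dm.cells[None, :]
        assert np.all(indep[across] == 0.0)

    def test_recovers_active_predictors_from_gp_draws(self):
        # predictors 0-1 active, predictor 2 irrelevant; phi rank must reflect it
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(150, 3))
            cells = rng.integers(0, 5, 150)
            truth = GPHyperparams(phi=np.array([1.0, 0.7, 0.0]), ve=0.2, rho=0.8)
            dm0 = DelayMatrix(X, np.zeros(150), cells, np.arange(150),
                              ["a", "b", "c"], [], 0.0, 1.0)
            C = gram_matrix(dm0, truth, noise=True)
            y = rng.multivariate_normal(np.zeros(150), C, method="cholesky")
            dm = DelayMatrix(X, y, cells, np.arange(150), ["a", "b", "c"], [], 0.0, 1.0)
            f = fit(dm, GPConfig(n_starts=3, seed=seed))
            if np.argmin(f.hyperparams.phi) == 2:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestComparisonSuite:
    def test_ten_models_fitted(self, bottom_up_panel):
        comp = gpedm.comparison_suite(
            bottom_up_panel, gp_config=GPConfig(n_starts=1, seed=0), E=2)
        assert len(comp.table) == 10
        assert comp.table["best_model"].sum() == 1
        assert comp.table["insect_model_better"].notna().sum() == 5

    def test_zero_variance_insect_column_arms_tie(self):
        panel = complete_panel(16)
        panel["insect_value"] = 1.0  # constant: no information
        cfg = GPConfig(n_starts=1, seed=0)
        dm_no = build_embedding(panel, EmbeddingSpec(include_insect=False))
        dm_yes = build_embedding(panel, EmbeddingSpec(include_insect=True))
        assert dm_yes.columns == dm_no.columns  # insect lags dropped
        r_no = fit(dm_no, cfg).r2_oos
        r_yes = fit(dm_yes, cfg).r2_oos
        assert r_yes == pytest.approx(r_no, abs=1e-10)


def test_destandardized_predictions_affine_invariant():
    """Affine rescaling of the raw inputs must not change de-standardized LOO."""
    panel = complete_panel(18, n_cells=2, seed=5)
    spec = EmbeddingSpec(E=2)
    cfg = GPConfig(n_starts=1, seed=0)
    dm1 = build_embedding(panel, spec)
    f1 = fit(dm1, cfg)
    scaled = panel.assign(insectivore_value=3.0 * panel["insectivore_value"] + 7.0)
    dm2 = build_embedding(scaled, spec)
    f2 = fit(dm2, cfg)
    pred1 = f1.loo_mean * dm1.y_sd + dm1.y_mean
    pred2 = f2.loo_mean * dm2.y_sd + dm2.y_mean
    assert np.allclose(pred2, 3.0 * pred1 + 7.0, atol=1e-6)
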