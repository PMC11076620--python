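"""Latent-variable multivariate regression: EM correctness (OLS reduction,
monotone likelihood, parameter recovery), AICc, forward selection, and
interaction screening."""

import numpy as np
import pandas as pd
import pytest

from grassmf.latent_model import (
    aicc,
    build_design_matrix,
    effect_table,
    fit_gllvm,
    forward_select,
    n_free_parameters,
    screen_interactions,
    significant_counts,
)


def _sim_gaussian(n, p, q, d, pair_sd, seed, beta_scale=0.3):
    """Data simulated directly from the fitted model family, with truth."""
    rng = np.random.default_rng(seed)
    npairs = max(n // 5, 1)
    pair = rng.integers(0, npairs, n)
    x = np.column_stack([np.ones(n), rng.binomial(1, 0.5, (n, q - 1))])
    beta = rng.normal(0, beta_scale, (q, p))
    lam = rng.normal(0, 0.3, (p, d)) if d else np.zeros((p, 0))
    psi = rng.uniform(0.05, 0.2, p)
    y = x @ beta + rng.normal(0, pair_sd, npairs)[pair][:, None]
    if d:
        y = y + rng.standard_normal((n, d)) @ lam.T
    y = y + rng.standard_normal((n, p)) * np.sqrt(psi)
    xd = pd.DataFrame(x, columns=["const"] + [f"x{i}" for i in range(1, q)])
    yd = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
    return yd, xd, pd.Series(pair), beta, lam, psi


class TestEmCore:
    def test_reduces_to_ols_without_latents_or_blocks(self):
        yd, xd, _, _, _, _ = _sim_gaussian(60, 5, 3, d=2, pair_sd=0.3, seed=0)
        fit = fit_gllvm(yd, xd, blocks=None, n_latent=0)
        ols = np.linalg.lstsq(xd.to_numpy(), yd.to_numpy(), rcond=None)[0]
        assert np.abs(fit.coefficients.to_numpy().T - ols).max() < 1e-8
        # fitted residual variances equal the ML (1/n) OLS residual variances
        resid = yd.to_numpy() - xd.to_numpy() @ ols
        assert np.allclose(fit.residual_variances, (resid**2).mean(axis=0), rtol=1e-6)

    @pytest.mark.parametrize("d,with_pair", [(0, False), (2, False), (0, True), (2, True)])
    def test_loglik_monotone_nondecreasing(self, d, with_pair):
        yd, xd, pair, *_ = _sim_gaussian(80, 6, 3, d=2, pair_sd=0.3, seed=d + with_pair)
        fit = fit_gllvm(yd, xd, blocks=pair if with_pair else None, n_latent=d, seed=1)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6 * (1 + np.abs(fit.loglik_trace[:-1]))).all()

    def test_parameter_recovery_within_reported_uncertainty(self):
        yd, xd, pair, beta, lam, psi = _sim_gaussian(400, 10, 4, d=2, pair_sd=0.3, seed=42)
        fit = fit_gllvm(yd, xd, blocks=pair, n_latent=2, seed=0)
        assert fit.converged
        err = np.abs(fit.coefficients.to_numpy().T - beta)
        assert err.mean() < 3 * fit.standard_errors.to_numpy().mean()
        # the rotation-invariant loading product is recovered
        lam_hat = fit.loadings.to_numpy()
        assert np.abs(lam_hat @ lam_hat.T - lam @ lam.T).max() < 0.25
        assert fit.pair_variance == pytest.approx(0.09, abs=0.06)

    def test_loadings_identification_convention(self):
        yd, xd, pair, *_ = _sim_gaussian(200, 8, 3, d=2, pair_sd=0.2, seed=3)
        fit = fit_gllvm(yd, xd, blocks=pair, n_latent=2, seed=5)
        lam = fit.loadings.to_numpy()
        assert lam[0, 1] == pytest.approx(0.0, abs=1e-10)  # lower triangular
        assert lam[0, 0] >= 0 and lam[1, 1] >= 0  # non-negative diagonal

    def test_rank_deficient_design_rejected(self):
        yd, xd, *_ = _sim_gaussian(50, 4, 3, d=0, pair_sd=0.0, seed=1)
        xd["dup"] = xd["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_gllvm(yd, xd, n_latent=0)

    def test_missing_cells_rejected(self):
        yd, xd, *_ = _sim_gaussian(50, 4, 3, d=0, pair_sd=0.0, seed=1)
        yd.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_gllvm(yd, xd, n_latent=0)

    def test_latents_improve_covariance_reconstruction(self):
        """On rank-2 data, the implied residual covariance error decreases
        as the number of latent variables grows 0 -> 1 -> 2."""
        yd, xd, _, _, lam, psi = _sim_gaussian(600, 8, 3, d=2, pair_sd=0.0, seed=8)
        true_cov = lam @ lam.T + np.diag(psi)
        errs = []
        for d in (0, 1, 2):
            fit = fit_gllvm(yd, xd, blocks=None, n_latent=d, seed=0)
            lam_hat = fit.loadings.to_numpy()
            implied = lam_hat @ lam_hat.T + np.diag(fit.residual_variances)
            errs.append(np.linalg.norm(implied - true_cov))
        assert errs[2] < errs[1] < errs[0]


class TestAicc:
    def test_formula_value(self):
        # AIC = 210, correction 2*5*6/44
        assert aicc(-100.0, 5, 50) == pytest.approx(210 + 60 / 44)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-5)

    def test_useless_parameter_increases_aicc(self):
        assert aicc(-100.0, 6, 50) > aicc(-100.0, 5, 50)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(-100.0, 49, 50)

    def test_free_parameter_count(self):
        # p=22 indicators, q=4 predictors, d=2 latents, pair variance
        assert n_free_parameters(22, 4, 2, True) == 88 + 43 + 22 + 1


class TestForwardSelection:
    def test_empty_candidate_list_returns_base(self):
        yd, xd, pair, *_ = _sim_gaussian(100, 6, 4, d=2, pair_sd=0.2, seed=2)
        sel = forward_select(yd, xd, None, blocks=pair, seed=0)
        assert sel.selected == []
        assert list(sel.fit.coefficients.columns) == list(xd.columns)

    def test_planted_covariate_selected_first(self):
        """A covariate with a strong true effect on many indicators is the
        first forward-selection pick in every replicate."""
        picks = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n, p = 150, 6
            x = np.column_stack([np.ones(n), rng.binomial(1, 0.5, (n, 2))])
            cands = pd.DataFrame(rng.standard_normal((n, 3)), columns=["e1", "e2", "e3"])
            y = x @ rng.normal(0, 0.2, (3, p)) + np.outer(cands["e2"], np.full(p, 0.6))
            y = y + rng.standard_normal((n, p)) * 0.3
            yd = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
            xd = pd.DataFrame(x, columns=["const", "a", "b"])
            sel = forward_select(yd, xd, cands, n_latent=0, seed=0)
            picks.append(sel.selected[0] if sel.selected else None)
        assert picks.count("e2") >= 9

    def test_pure_noise_candidates_usually_rejected(self):
        """With noise-only candidates the base model is selected most of
        the time (AICc penalises the useless additions)."""
        empty = 0
        reps = 12
        for rep in range(reps):
            yd, xd, _, *_ = _sim_gaussian(120, 5, 3, d=0, pair_sd=0.0, seed=200 + rep)
            rng = np.random.default_rng(300 + rep)
            cands = pd.DataFrame(rng.standard_normal((len(yd), 3)), columns=["e1", "e2", "e3"])
            sel = forward_select(yd, xd, cands, n_latent=0, seed=0)
            empty += sel.selected == []
        assert empty / reps > 0.5

    def test_history_is_monotone_in_aicc(self):
        yd, xd, _, *_ = _sim_gaussian(120, 5, 3, d=0, pair_sd=0.0, seed=7)
        rng = np.random.default_rng(7)
        cands = pd.DataFrame(rng.standard_normal((len(yd), 3)), columns=["e1", "e2", "e3"])
        cands["e1"] += yd.mean(axis=1) * 2  # make at least one informative
        sel = forward_select(yd, xd, cands, n_latent=0, seed=0)
        assert (np.diff(sel.history["aicc"]) < 0).all()


class TestInteractionScreen:
    @staticmethod
    def _aspect_design(n, rng):
        x = pd.DataFrame(
            {
                "const": np.ones(n),
                "production_system": rng.binomial(1, 0.5, n).astype(float),
                "eco_scheme": rng.binomial(1, 0.5, n).astype(float),
                "harvest_type": rng.binomial(1, 0.5, n).astype(float),
            }
        )
        return x

    def test_planted_interaction_detected(self):
        wins = 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(400 + rep)
            n, p = 200, 6
            x = self._aspect_design(n, rng)
            inter = (x["eco_scheme"] * x["harvest_type"]).to_numpy()
            y = x.to_numpy() @ rng.normal(0, 0.2, (4, p)) + np.outer(inter, np.full(p, 0.5))
            y = y + rng.standard_normal((n, p)) * 0.3
            yd = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
            screen = screen_interactions(yd, x, n_latent=0, seed=0, compute_se=False)
            wins += screen.winner == "interactions"
        assert wins / reps >= 0.8

    def test_no_interaction_data_prefers_main_effects(self):
        wins = 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            n, p = 200, 6
            x = self._aspect_design(n, rng)
            y = x.to_numpy() @ rng.normal(0, 0.3, (4, p)) + rng.standard_normal((n, p)) * 0.3
            yd = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
            screen = screen_interactions(yd, x, n_latent=0, seed=0, compute_se=False)
            wins += screen.winner == "main"
        assert wins / reps >= 0.8

    def test_empty_cell_interaction_dropped(self):
        # eco-scheme pastures never occur: the (1, 1) cell is empty, so the
        # eco:harvest interaction is undefined and must be dropped
        rng = np.random.default_rng(9)
        n, p = 120, 4
        x = self._aspect_design(n, rng)
        state = rng.choice(3, n, p=[0.4, 0.3, 0.3])
        x["eco_scheme"] = (state == 1).astype(float)
        x["harvest_type"] = (state == 2).astype(float)
        y = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"y{j}" for j in range(p)])
        with pytest.warns(RuntimeWarning, match="empty design cells"):
            screen = screen_interactions(y, x, n_latent=0, seed=0, compute_se=False)
        assert "eco_scheme:harvest_type" in screen.dropped_terms
        assert screen.winner in ("main", "interactions")


class TestEffectTable:
    def test_wald_interval_oracle(self):
        yd, xd, _, *_ = _sim_gaussian(50, 3, 2, d=0, pair_sd=0.0, seed=11)
        fit = fit_gllvm(yd, xd, n_latent=0)
        fit.coefficients.loc["y0", "x1"] = 0.2
        fit.standard_errors.loc["y0", "x1"] = 0.05
        tbl = effect_table(fit)
        row = tbl[(tbl["indicator"] == "y0") & (tbl["predictor"] == "x1")].iloc[0]
        assert row["ci_low"] == pytest.approx(0.2 - 1.959964 * 0.05, abs=1e-4)
        assert row["ci_high"] == pytest.approx(0.2 + 1.959964 * 0.05, abs=1e-4)
        assert row["significant"]

    def test_zero_coefficient_never_significant(self):
        yd, xd, _, *_ = _sim_gaussian(50, 3, 2, d=0, pair_sd=0.0, seed=12)
        fit = fit_gllvm(yd, xd, n_latent=0)
        fit.coefficients.loc[:, "x1"] = 0.0
        tbl = effect_table(fit)
        assert not tbl[tbl["predictor"] == "x1"]["significant"].any()

    def test_missing_se_rejected(self):
        yd, xd, _, *_ = _sim_gaussian(50, 3, 2, d=0, pair_sd=0.0, seed=13)
        fit = fit_gllvm(yd, xd, n_latent=0, compute_se=False)
        with pytest.raises(ValueError):
            effect_table(fit)

    def test_significant_tally_shape(self, study_dataset, service_map):
        from grassmf.preprocessing import preprocess_indicators

        design, _, indicators = study_dataset
        pre = preprocess_indicators(indicators, service_map).set_axis(design.index)
        x = build_design_matrix(design)
        fit = fit_gllvm(pre, x, blocks=design["pair_id"], n_latent=2, seed=0)
        counts = significant_counts(effect_table(fit))
        assert set(counts["predictor"]) == {"production_system", "eco_scheme", "harvest_type"}
        assert (counts["n_significant"] <= 22).all()
        assert (
            counts["n_significant"] == counts["n_positive"] + counts["n_negative"]
        ).all()


def test_factor_analysis_cross_check():
    """With no covariates and no blocking, the implied covariance from the
    EM fit agrees with scikit-learn's factor analysis on the same data."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(77)
    n, p, d = 800, 8, 2
    lam = rng.normal(0, 0.4, (p, d))
    psi = rng.uniform(0.1, 0.3, p)
    y = rng.standard_normal((n, d)) @ lam.T + rng.standard_normal((n, p)) * np.sqrt(psi)
    yd = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
    xd = pd.DataFrame({"const": np.ones(n)})
    fit = fit_gllvm(yd, xd, blocks=None, n_latent=d, seed=0, tol=1e-10, max_iter=5000)
    fa = sklearn.FactorAnalysis(n_components=d, tol=1e-6, max_iter=5000).fit(y)
    ours = fit.loadings.to_numpy() @ fit.loadings.to_numpy().T + np.diag(fit.residual_variances)
    theirs = fa.components_.T @ fa.components_ + np.diag(fa.noise_variance_)
    assert np.abs(ours - theirs).max() < 0.02
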