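"""Gaussian multivariate regression with latent variables and a blocked
random intercept, fitted by exact EM.

The model for plot i and indicator j is

    y_ij = x_i' beta_j + u_{pair(i)} + lambda_j' z_i + eps_ij,

with ordination scores z_i ~ N(0, I_d) shared across indicators within a
plot, a farm-pair random intercept u ~ N(0, sigma2_pair) shared across
indicators and plots of a pair, and eps_ij ~ N(0, psi_j).  The latent term
gives the residual covariance a rank-d (default 2) structure,
Lambda Lambda' + diag(psi), on top of the compound-symmetric pair
contribution.

Everything is jointly Gaussian, so the E-step is available in closed form
and the marginal likelihood is exact (no variational approximation).  The
EM log-likelihood trace is non-decreasing by construction and is recorded on
the fit for verification.  Loadings are reported in the lower-triangular,
non-negative-diagonal convention (the likelihood is invariant to orthogonal
rotation; the convention fixes the representative).

Standard errors of the regression coefficients are Wald SEs from the exact
Fisher information of the mean parameters at the converged variance
parameters.  Model comparison uses the small-sample corrected AICc; the
effective number of observations is the number of response cells
(plots x indicators) by default, configurable to the number of plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class LatentModelFit:
    """Converged (or flagged) fit of the latent-variable multivariate model."""

    coefficients: pd.DataFrame  # indicators x predictors
    standard_errors: pd.DataFrame | None
    loadings: pd.DataFrame  # indicators x n_latent, lower-triangular block
    pair_variance: float
    residual_variances: pd.Series
    log_likelihood: float
    aicc: float
    n_latent: int
    converged: bool
    n_iterations: int
    n_plots: int
    n_params: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_indicators(self) -> int:
        return self.coefficients.shape[0]


def n_free_parameters(p: int, q: int, d: int, with_pair: bool) -> int:
    """Free parameters: coefficients, identified loadings, variances."""
    return p * q + (p * d - d * (d - 1) // 2) + p + (1 if with_pair else 0)


def aicc(log_likelihood: float, k: int, n_observations: int) -> float:
    """Second-order Akaike Information Criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n_observations <= k + 1:
        raise ValueError(
            f"AICc undefined: n_observations={n_observations} must exceed k+1={k + 1}"
        )
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n_observations - k - 1)


def build_design_matrix(
    design: pd.DataFrame,
    env_covariates: tuple[str, ...] | list[str] = (),
    standardized_env: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intercept + 0/1 aspect dummies (+ optional standardized covariates).

    Aspect coding: organic = 1, eco-scheme yes = 1, pasture = 1.
    """
    from .preprocessing import standardize_env
    from .synthetic_data import ASPECTS, TREATED_LEVELS

    cols = {"const": np.ones(len(design))}
    for aspect in ASPECTS:
        cols[aspect] = (design[aspect] == TREATED_LEVELS[aspect]).to_numpy(dtype=float)
    x = pd.DataFrame(cols, index=design.index)
    if env_covariates:
        env = (
            standardized_env[list(env_covariates)]
            if standardized_env is not None
            else standardize_env(design[list(env_covariates)].astype(float))
        )
        x = pd.concat([x, env.set_axis(design.index)], axis=1)
    return x


def _lower_triangular_rotation(lam: np.ndarray) -> np.ndarray:
    """Rotate loadings so the top d x d block is lower triangular with a
    non-negative diagonal (likelihood-invariant identification)."""
    d = lam.shape[1]
    if d == 0 or lam.shape[0] < d:
        return lam
    a = lam[:d, :]
    q, _ = np.linalg.qr(a.T)
    out = lam @ q
    signs = np.sign(np.diag(out[:d, :]))
    signs[signs == 0] = 1.0
    return out * signs


class _EStepMoments:
    """Posterior moments of (u, z) accumulated over blocks for one E-step."""

    __slots__ = ("eu", "vu", "ez", "szz", "scz", "scuz", "suz", "pair_second", "loglik")

    def __init__(self, n, d):
        self.eu = np.zeros(n)
        self.vu = np.zeros(n)
        self.ez = np.zeros((n, d)) if d else np.zeros((n, 0))
        self.szz = np.zeros((d, d))
        self.scz = np.zeros((d, d))
        self.scuz = np.zeros(d)
        self.suz = np.zeros(d)
        self.pair_second = 0.0  # sum over pairs of E[u^2]
        self.loglik = 0.0


def _e_step(resid, groups, lam, psi, sigma2_pair, with_pair):
    """Closed-form E-step plus exact marginal log-likelihood.

    Within-plot residual covariance is Sigma_w = Lambda Lambda' + diag(psi);
    the pair intercept adds sigma2 * J across all cells of a pair and is
    handled by rank-one Woodbury updates.
    """
    n, p = resid.shape
    d = lam.shape[1]
    mom = _EStepMoments(n, d)

    psi_inv = 1.0 / psi
    sigma_w = lam @ lam.T + np.diag(psi)
    cw, low = linalg.cho_factor(sigma_w, lower=True)
    logdet_w = 2.0 * np.log(np.diag(cw)).sum()
    s_vec = linalg.cho_solve((cw, low), np.ones(p))  # Sigma_w^-1 1
    one_s = s_vec.sum()  # 1' Sigma_w^-1 1

    if d:
        g_lam = lam.T * psi_inv  # d x p, Lambda' Psi^-1
        w_mat = g_lam @ lam  # d x d
    a_scalar = psi_inv.sum()  # 1' Psi^-1 1

    ll = 0.0
    if not with_pair:
        # plots independent: loglik in one shot, shared posterior covariance
        t = linalg.cho_solve((cw, low), resid.T)  # p x n
        quad = np.einsum("ij,ji->i", resid, t).sum()
        ll = -0.5 * (n * p * np.log(2 * np.pi) + n * logdet_w + quad)
        if d:
            a_post = np.eye(d) + w_mat
            c_post = np.linalg.inv(a_post)
            mom.ez = resid @ g_lam.T @ c_post.T
            mom.scz = n * c_post
            mom.szz = mom.scz + mom.ez.T @ mom.ez
        mom.loglik = ll
        return mom

    for idx in groups:
        r = resid[idx]  # n_g x p
        n_g = len(idx)
        # marginal log-likelihood via Woodbury on the rank-one pair term
        t = linalg.cho_solve((cw, low), r.T)  # p x n_g
        quads = np.einsum("ij,ji->i", r, t)
        sr = r @ s_vec  # per-plot 1' Sigma_w^-1 r_i
        denom = 1.0 + sigma2_pair * n_g * one_s
        quad = quads.sum() - sigma2_pair * sr.sum() ** 2 / denom
        logdet = n_g * logdet_w + np.log(denom)
        ll += -0.5 * (n_g * p * np.log(2 * np.pi) + logdet + quad)

        # posterior of (u, z_1..z_ng)
        m = 1 + n_g * d
        a_mat = np.zeros((m, m))
        b = np.zeros(m)
        a_mat[0, 0] = (1.0 / sigma2_pair if sigma2_pair > 0 else np.inf) + n_g * a_scalar
        b[0] = (r * psi_inv).sum()
        if d:
            cross = psi_inv @ lam  # 1' Psi^-1 Lambda, d
            zz_block = np.eye(d) + w_mat
            gr = r @ g_lam.T  # n_g x d
            for i in range(n_g):
                sl = slice(1 + i * d, 1 + (i + 1) * d)
                a_mat[0, sl] = cross
                a_mat[sl, 0] = cross
                a_mat[sl, sl] = zz_block
                b[sl] = gr[i]
        if sigma2_pair > 0:
            c_post = np.linalg.inv(a_mat)
            mu = c_post @ b
        else:
            # u degenerate at 0: drop it
            c_post = np.zeros((m, m))
            mu = np.zeros(m)
            if d:
                sub = np.linalg.inv(a_mat[1:, 1:])
                c_post[1:, 1:] = sub
                mu[1:] = sub @ b[1:]
        mom.eu[idx] = mu[0]
        mom.vu[idx] = c_post[0, 0]
        mom.pair_second += mu[0] ** 2 + c_post[0, 0]
        if d:
            for i, row in enumerate(idx):
                sl = slice(1 + i * d, 1 + (i + 1) * d)
                ez_i = mu[sl]
                cz_i = c_post[sl, sl]
                cuz_i = c_post[0, sl]
                mom.ez[row] = ez_i
                mom.scz += cz_i
                mom.szz += cz_i + np.outer(ez_i, ez_i)
                mom.scuz += cuz_i
                mom.suz += cuz_i + mu[0] * ez_i
    mom.loglik = ll
    return mom


def fit_gllvm(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    blocks: pd.Series | None = None,
    n_latent: int = 2,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    compute_se: bool = True,
    aicc_observations: str = "cells",
) -> LatentModelFit:
    """Fit the latent-variable multivariate regression by exact EM.

    Parameters
    ----------
    Y:
        Preprocessed indicator matrix (plots x indicators), no missing cells.
    X:
        Design matrix including an intercept column (see
        :func:`build_design_matrix`); must be full column rank.
    blocks:
        Farm-pair identifier per plot; ``None`` fixes the pair variance at 0.
    n_latent:
        Number of latent variables (0 reduces the model to independent
        per-indicator regressions when ``blocks`` is also ``None``).
    seed:
        Controls the random jitter of the loading initialisation only.
    aicc_observations:
        "cells" (plots x indicators, default) or "plots"; the sample size
        entering the AICc small-sample correction.

    Raises ``ValueError`` on rank-deficient X or missing data;
    non-convergence is flagged on the returned fit, not raised.
    """
    yv = np.asarray(Y, dtype=float)
    xv = np.asarray(X, dtype=float)
    if np.isnan(yv).any() or np.isnan(xv).any():
        raise ValueError("missing cells in Y or X; drop or impute before fitting")
    n, p = yv.shape
    q = xv.shape[1]
    if np.linalg.matrix_rank(xv) < q:
        raise ValueError("design matrix X is rank deficient")
    d = int(n_latent)
    with_pair = blocks is not None
    if with_pair:
        codes, _ = pd.factorize(np.asarray(blocks))
        groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    else:
        groups = []

    rng = np.random.default_rng(seed)
    xtx = xv.T @ xv
    xtx_cho = linalg.cho_factor(xtx)
    beta = linalg.cho_solve(xtx_cho, xv.T @ yv)  # q x p
    resid0 = yv - xv @ beta
    psi = resid0.var(axis=0).clip(min=1e-8)
    if d:
        u_svd, s_svd, vt = np.linalg.svd(resid0, full_matrices=False)
        lam = (vt[:d].T * (s_svd[:d] / np.sqrt(n))) * 0.7
        lam += rng.normal(0.0, 0.01, size=lam.shape)
    else:
        lam = np.zeros((p, 0))
    sigma2 = 0.1 * psi.mean() if with_pair else 0.0

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = yv - xv @ beta
        mom = _e_step(resid, groups, lam, psi, sigma2, with_pair)
        trace.append(mom.loglik)
        if len(trace) > 1:
            if trace[-1] < trace[-2] - 1e-6 * (1.0 + abs(trace[-2])):
                warnings.warn(
                    f"EM log-likelihood decreased at iteration {it}", RuntimeWarning
                )
            if abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-2])):
                converged = True
                break

        # --- M-step: joint (beta, Lambda) per indicator, then variances ---
        ez = mom.ez
        m2 = np.zeros((q + d, q + d))
        m2[:q, :q] = xtx
        if d:
            m2[:q, q:] = xv.T @ ez
            m2[q:, :q] = m2[:q, q:].T
            m2[q:, q:] = mom.szz
        rhs = np.zeros((q + d, p))
        rhs[:q] = xv.T @ yv - np.outer(xv.T @ mom.eu, np.ones(p))
        if d:
            rhs[q:] = ez.T @ yv - np.outer(mom.suz, np.ones(p))
        theta = np.linalg.solve(m2, rhs)
        beta = theta[:q]
        if d:
            lam = theta[q:].T  # p x d

        point = yv - xv @ beta - mom.eu[:, None]
        if d:
            point = point - ez @ lam.T
        psi = (point**2).sum(axis=0) / n
        if d:
            psi = psi + np.einsum("jk,kl,jl->j", lam, mom.scz, lam) / n
            psi = psi + 2.0 * (lam @ mom.scuz) / n
        psi = psi + mom.vu.sum() / n
        psi = np.clip(psi, 1e-10, None)
        if with_pair:
            sigma2 = max(mom.pair_second / len(groups), 0.0)
            # a variance component decaying to the boundary is truncated at
            # exactly zero (avoids an asymptotic EM crawl; cf. random terms
            # estimated as zero and dropped in blocked designs)
            if sigma2 < 1e-8 * psi.mean():
                sigma2 = 0.0

    # final E-step so the reported log-likelihood matches the parameters
    resid = yv - xv @ beta
    mom = _e_step(resid, groups, lam, psi, sigma2, with_pair)
    loglik = mom.loglik
    if trace and loglik < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
        warnings.warn("final EM log-likelihood below trace maximum", RuntimeWarning)
    trace.append(loglik)

    lam = _lower_triangular_rotation(lam)

    k = n_free_parameters(p, q, d, with_pair)
    n_obs = n * p if aicc_observations == "cells" else n
    try:
        aicc_value = aicc(loglik, k, n_obs)
    except ValueError:
        aicc_value = np.nan

    se = None
    if compute_se:
        se = _coefficient_se(xv, groups, lam, psi, sigma2, with_pair, n, p, q)

    ind = list(Y.columns)
    pred = list(X.columns)
    return LatentModelFit(
        coefficients=pd.DataFrame(beta.T, index=ind, columns=pred),
        standard_errors=(
            pd.DataFrame(se, index=ind, columns=pred) if se is not None else None
        ),
        loadings=pd.DataFrame(lam, index=ind, columns=[f"LV{k+1}" for k in range(d)]),
        pair_variance=float(sigma2),
        residual_variances=pd.Series(psi, index=ind),
        log_likelihood=float(loglik),
        aicc=float(aicc_value),
        n_latent=d,
        converged=converged,
        n_iterations=it,
        n_plots=n,
        n_params=k,
        loglik_trace=np.asarray(trace),
    )


def _coefficient_se(xv, groups, lam, psi, sigma2, with_pair, n, p, q):
    """Exact Fisher information of the mean parameters at the converged
    variance parameters; SEs are sqrt(diag(K^-1)).

    Per pair g, the information contribution has the closed form
    (Xg'Xg) kron Sigma_w^-1 - (sigma2/c) (t t') kron (s s') with
    s = Sigma_w^-1 1, t = sum of the pair's covariate rows, and
    c = 1 + sigma2 * n_g * 1's.
    """
    sigma_w = lam @ lam.T + np.diag(psi)
    w_inv = np.linalg.inv(sigma_w)
    s_vec = w_inv @ np.ones(p)
    one_s = s_vec.sum()
    if not with_pair or sigma2 == 0:
        info = np.kron(xv.T @ xv, w_inv)
    else:
        info = np.zeros((q * p, q * p))
        ss = np.outer(s_vec, s_vec)
        for idx in groups:
            xg = xv[idx]
            n_g = len(idx)
            c = 1.0 + sigma2 * n_g * one_s
            t = xg.sum(axis=0)
            info += np.kron(xg.T @ xg, w_inv) - (sigma2 / c) * np.kron(np.outer(t, t), ss)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov)).reshape(q, p)  # (predictor, indicator)
    return se.T  # indicators x predictors


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class ForwardSelection:
    selected: list[str]
    fit: LatentModelFit
    history: pd.DataFrame


def forward_select(
    Y: pd.DataFrame,
    X_base: pd.DataFrame,
    candidates: pd.DataFrame | None,
    blocks: pd.Series | None = None,
    **fit_kwargs,
) -> ForwardSelection:
    """Greedy forward selection of candidate covariates under AICc.

    Starting from the base model, repeatedly adds the candidate giving the
    largest AICc improvement until no candidate improves it.  Deterministic
    given the data.  Fits during the search skip SE computation; the final
    model is refitted with SEs.
    """
    fit_kwargs.setdefault("n_latent", 2)
    search_kwargs = dict(fit_kwargs, compute_se=False)
    current_x = X_base.copy()
    current = fit_gllvm(Y, current_x, blocks=blocks, **search_kwargs)
    remaining = list(candidates.columns) if candidates is not None else []
    selected: list[str] = []
    rows = [{"step": 0, "added": "<base>", "aicc": current.aicc}]
    step = 0
    while remaining:
        trials = {}
        for name in remaining:
            x_try = pd.concat([current_x, candidates[[name]].set_axis(current_x.index)], axis=1)
            trials[name] = fit_gllvm(Y, x_try, blocks=blocks, **search_kwargs)
        best = min(trials, key=lambda nm: trials[nm].aicc)
        if trials[best].aicc < current.aicc:
            step += 1
            selected.append(best)
            current_x = pd.concat(
                [current_x, candidates[[best]].set_axis(current_x.index)], axis=1
            )
            current = trials[best]
            remaining.remove(best)
            rows.append({"step": step, "added": best, "aicc": current.aicc})
        else:
            break
    final = fit_gllvm(Y, current_x, blocks=blocks, **fit_kwargs)
    return ForwardSelection(selected=selected, fit=final, history=pd.DataFrame(rows))


@dataclass
class InteractionScreen:
    main_fit: LatentModelFit
    interaction_fit: LatentModelFit | None
    aicc_main: float
    aicc_interactions: float | None
    winner: str  # "main" or "interactions"
    dropped_terms: list[str]
    table: pd.DataFrame


def screen_interactions(
    Y: pd.DataFrame,
    X_selected: pd.DataFrame,
    aspect_columns: tuple[str, ...] = ("production_system", "eco_scheme", "harvest_type"),
    blocks: pd.Series | None = None,
    **fit_kwargs,
) -> InteractionScreen:
    """Compare the selected main-effects model against the model with all
    pairwise interactions between the management aspects added.

    Interactions whose 2x2 cross-table has an empty cell in the data are
    dropped with a warning.  Ties in AICc retain the main-effects model
    (parsimony tie-break).
    """
    fit_kwargs.setdefault("n_latent", 2)
    main_fit = fit_gllvm(Y, X_selected, blocks=blocks, **fit_kwargs)
    inter = {}
    dropped = []
    for i, a in enumerate(aspect_columns):
        for b in aspect_columns[i + 1 :]:
            col = X_selected[a] * X_selected[b]
            cells = set(zip(X_selected[a], X_selected[b]))
            if len(cells) < 4:
                warnings.warn(
                    f"interaction {a}:{b} has empty design cells; term dropped",
                    RuntimeWarning,
                )
                dropped.append(f"{a}:{b}")
                continue
            inter[f"{a}:{b}"] = col
    if inter:
        x_int = X_selected.assign(**inter)
        int_fit = fit_gllvm(Y, x_int, blocks=blocks, **fit_kwargs)
        winner = "interactions" if int_fit.aicc < main_fit.aicc else "main"
        aicc_int = int_fit.aicc
    else:
        int_fit, winner, aicc_int = None, "main", None
    table = pd.DataFrame(
        {
            "model": ["main_effects", "with_interactions"],
            "aicc": [main_fit.aicc, aicc_int],
        }
    )
    return InteractionScreen(
        main_fit=main_fit,
        interaction_fit=int_fit,
        aicc_main=main_fit.aicc,
        aicc_interactions=aicc_int,
        winner=winner,
        dropped_terms=dropped,
        table=table,
    )


def effect_table(
    fit: LatentModelFit,
    level: float = 0.95,
    predictors: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Per-indicator coefficient table with Wald CIs and significance flags.

    A coefficient is flagged significant when its CI excludes zero
    (two-sided, alpha = 1 - level).
    """
    if fit.standard_errors is None:
        raise ValueError("fit has no standard errors; refit with compute_se=True")
    z = stats.norm.ppf(0.5 + level / 2.0)
    preds = [p for p in fit.coefficients.columns if p != "const"]
    if predictors is not None:
        preds = [p for p in preds if p in predictors]
    rows = []
    for pred in preds:
        est = fit.coefficients[pred]
        se = fit.standard_errors[pred]
        lo, hi = est - z * se, est + z * se
        for ind in fit.coefficients.index:
            rows.append(
                {
                    "indicator": ind,
                    "predictor": pred,
                    "estimate": est[ind],
                    "se": se[ind],
                    "ci_low": lo[ind],
                    "ci_high": hi[ind],
                    "significant": bool(lo[ind] > 0 or hi[ind] < 0),
                }
            )
    return pd.DataFrame(rows)


def significant_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Tally of significant indicators per predictor, split by sign."""
    rows = []
    for pred, grp in table.groupby("predictor"):
        sig = grp[grp["significant"]]
        rows.append(
            {
                "predictor": pred,
                "n_significant": len(sig),
                "n_positive": int((sig["estimate"] > 0).sum()),
                "n_negative": int((sig["estimate"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows)
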