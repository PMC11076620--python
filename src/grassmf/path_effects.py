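"""Recursive path analysis: direct and indirect management effects on an
ecosystem-service indicator.

The basic model mirrors the mediation structure of the study design:

* plot inclination (exogenous) -> eco-scheme uptake and harvest type;
  the production system receives no inclination path because the matched-
  pair sampling equalises topography between organic and non-organic farms;
* each management aspect -> each of the three land-use-intensity variables
  (fertilizer N, cuts per year, grazing LU-days);
* aspects and intensity variables -> the indicator.

All variables (binary aspects as 0/1) are standardized to unit variance, so
path coefficients are standardized effects.  The system is recursive, hence
equation-wise least squares is the maximum-likelihood solution; residual
covariances among the three intensity variables, between the two
topography-driven aspects, and between the production system and those
aspects are left free (estimated from residual cross-moments).

The indirect effect of an aspect via a mediator is the product of the two
standardized paths; the total effect is direct plus the sum of indirect
components.  For a linear recursive system this total equals the aspect's
coefficient in the reduced-form regression of the indicator on the aspects
alone -- an algebraic identity used as a correctness check.

Fit statistics follow covariance-structure convention: chi2 = (n-1) F_ML
comparing the model-implied and sample covariance, CFI against the
independence baseline, and SRMR as the root mean square standardized
residual covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

ASPECT_COLUMNS = ("production_system", "eco_scheme", "harvest_type")
MEDIATORS = ("fertilizer_N_available", "n_cuts", "grazing_intensity")

_BINARY_POSITIVE = {
    "production_system": "organic",
    "eco_scheme": "yes",
    "harvest_type": "pasture",
}


@dataclass(frozen=True)
class PathModel:
    """A recursive path model: topologically ordered variables, parent sets,
    and the residual/exogenous covariances left free."""

    order: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    free_covariances: tuple[tuple[str, str], ...]

    def validate(self) -> None:
        pos = {v: i for i, v in enumerate(self.order)}
        for child, pars in self.parents.items():
            for par in pars:
                if pos[par] >= pos[child]:
                    raise ValueError(f"path {par} -> {child} violates recursive ordering")

    @property
    def n_free_parameters(self) -> int:
        n_paths = sum(len(p) for p in self.parents.values())
        return n_paths + len(self.order) + len(self.free_covariances)


def basic_model(indicator: str = "indicator") -> PathModel:
    """The per-indicator mediation model described in the module docstring."""
    order = ("inclination", "production_system", "eco_scheme", "harvest_type") + MEDIATORS + (
        indicator,
    )
    parents = {
        "eco_scheme": ("inclination",),
        "harvest_type": ("inclination",),
        **{m: ASPECT_COLUMNS for m in MEDIATORS},
        indicator: ASPECT_COLUMNS + MEDIATORS,
    }
    free_cov = (
        ("inclination", "production_system"),
        ("production_system", "eco_scheme"),
        ("production_system", "harvest_type"),
        ("eco_scheme", "harvest_type"),
        ("fertilizer_N_available", "n_cuts"),
        ("fertilizer_N_available", "grazing_intensity"),
        ("n_cuts", "grazing_intensity"),
    )
    model = PathModel(order=order, parents=parents, free_covariances=free_cov)
    model.validate()
    return model


def saturated_model(order: tuple[str, ...]) -> PathModel:
    """Fully saturated recursive model: every variable regressed on all its
    predecessors (zero degrees of freedom; reproduces the sample covariance
    exactly)."""
    parents = {v: tuple(order[:i]) for i, v in enumerate(order) if i > 0}
    return PathModel(order=order, parents=parents, free_covariances=())


@dataclass
class PathFit:
    model: PathModel
    indicator_name: str
    paths: pd.DataFrame  # child, parent, estimate, se, p_value
    b_matrix: pd.DataFrame  # k x k path coefficients (child row, parent col)
    psi: pd.DataFrame  # residual / exogenous covariance matrix (free entries)
    sample_cov: pd.DataFrame
    n: int
    data: pd.DataFrame = field(repr=False, default=None)  # standardized
    chi2: float = np.nan
    df: int = 0
    cfi: float = np.nan
    srmr: float = np.nan

    def path(self, parent: str, child: str) -> float:
        return float(self.b_matrix.loc[child, parent])

    def path_p(self, parent: str, child: str) -> float:
        row = self.paths[(self.paths["child"] == child) & (self.paths["parent"] == parent)]
        return float(row["p_value"].iloc[0])


def standardize_for_paths(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Binary aspects -> 0/1 dummies, then z-score every model column."""
    out = pd.DataFrame(index=data.index)
    for col in columns:
        v = data[col]
        if col in _BINARY_POSITIVE:
            v = (v == _BINARY_POSITIVE[col]).astype(float) if v.dtype == object else v.astype(float)
        v = v.astype(float)
        sd = v.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"variable {col!r} has zero variance")
        out[col] = (v - v.mean()) / sd
    return out


def fit_path_model(
    data: pd.DataFrame,
    indicator: str,
    model: PathModel | None = None,
) -> PathFit:
    """Fit a recursive path model by equation-wise least squares on
    standardized data and compute covariance-structure fit statistics.

    ``data`` must contain every model variable (aspects may be categorical).
    Perfectly collinear parents raise rather than being dropped silently.
    """
    model = model or basic_model(indicator)
    model.validate()
    cols = list(model.order)
    z = standardize_for_paths(data, cols)
    n = len(z)

    k = len(cols)
    b = pd.DataFrame(0.0, index=cols, columns=cols)
    residuals = pd.DataFrame(index=z.index, columns=cols, dtype=float)
    rows = []
    for var in cols:
        pars = model.parents.get(var, ())
        if not pars:
            residuals[var] = z[var]
            continue
        xmat = z[list(pars)].to_numpy()
        if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
            raise ValueError(f"collinear parents in equation for {var!r}: {pars}")
        res = sm.OLS(z[var].to_numpy(), sm.add_constant(xmat)).fit()
        coefs = res.params[1:]
        pvals = res.pvalues[1:]
        ses = res.bse[1:]
        for j, par in enumerate(pars):
            b.loc[var, par] = coefs[j]
            rows.append(
                {
                    "child": var,
                    "parent": par,
                    "estimate": coefs[j],
                    "se": ses[j],
                    "p_value": pvals[j],
                }
            )
        residuals[var] = z[var].to_numpy() - xmat @ coefs - res.params[0]

    s = z.cov()  # ddof=1
    rcov = residuals.cov()
    psi = pd.DataFrame(0.0, index=cols, columns=cols)
    for var in cols:
        psi.loc[var, var] = rcov.loc[var, var]
    exog = [v for v in cols if not model.parents.get(v)]
    for a in exog:
        for bb in exog:
            if a != bb:
                psi.loc[a, bb] = rcov.loc[a, bb]
    for a, bb in model.free_covariances:
        psi.loc[a, bb] = rcov.loc[a, bb]
        psi.loc[bb, a] = rcov.loc[a, bb]

    fit = PathFit(
        model=model,
        indicator_name=indicator,
        paths=pd.DataFrame(rows),
        b_matrix=b,
        psi=psi,
        sample_cov=s,
        n=n,
        data=z,
    )
    fit.chi2, fit.df, fit.cfi, fit.srmr = fit_statistics(fit)
    return fit


def implied_covariance(fit: PathFit) -> pd.DataFrame:
    """Model-implied covariance (I - B)^-1 Psi (I - B)^-T."""
    cols = list(fit.model.order)
    b = fit.b_matrix.loc[cols, cols].to_numpy()
    psi = fit.psi.loc[cols, cols].to_numpy()
    inv = np.linalg.inv(np.eye(len(cols)) - b)
    return pd.DataFrame(inv @ psi @ inv.T, index=cols, columns=cols)


def fit_statistics(fit: PathFit) -> tuple[float, int, float, float]:
    """(chi2, df, CFI, SRMR) of the fitted covariance structure."""
    cols = list(fit.model.order)
    s = fit.sample_cov.loc[cols, cols].to_numpy()
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise ValueError("sample covariance is not positive definite")
    sigma = implied_covariance(fit).to_numpy()
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0:
        raise ValueError("implied covariance is not positive definite")
    k = len(cols)
    f_ml = logdet_m - logdet_s + np.trace(s @ np.linalg.inv(sigma)) - k
    f_ml = max(f_ml, 0.0)
    chi2 = (fit.n - 1) * f_ml
    df = k * (k + 1) // 2 - fit.model.n_free_parameters

    # independence baseline: F_base = sum log s_ii - log|S| (tr term equals k)
    chi2_base = (fit.n - 1) * (np.log(np.diag(s)).sum() - logdet_s)
    df_base = k * (k - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0

    d_s = np.sqrt(np.diag(s))
    resid = s / np.outer(d_s, d_s) - sigma / np.outer(np.sqrt(np.diag(sigma)), np.sqrt(np.diag(sigma)))
    iu = np.triu_indices(k)
    srmr = float(np.sqrt((resid[iu] ** 2).mean()))
    return float(chi2), int(df), float(cfi), srmr


@dataclass
class EffectDecomposition:
    aspect: str
    indicator: str
    direct: float
    direct_significant: bool
    indirect: dict[str, float]
    indirect_significant: dict[str, bool]
    total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "indicator": self.indicator,
                "aspect": self.aspect,
                "component": "direct",
                "estimate": self.direct,
                "significant": self.direct_significant,
            }
        ]
        for med, est in self.indirect.items():
            rows.append(
                {
                    "indicator": self.indicator,
                    "aspect": self.aspect,
                    "component": f"via_{med}",
                    "estimate": est,
                    "significant": self.indirect_significant[med],
                }
            )
        rows.append(
            {
                "indicator": self.indicator,
                "aspect": self.aspect,
                "component": "total",
                "estimate": self.total,
                "significant": bool(
                    self.direct_significant or any(self.indirect_significant.values())
                ),
            }
        )
        return pd.DataFrame(rows)


def decompose_effects(fit: PathFit, aspect: str, alpha: float = 0.05) -> EffectDecomposition:
    """Direct / indirect / total standardized effect of ``aspect`` on the
    fitted indicator.

    Indirect via mediator M = path(aspect -> M) * path(M -> indicator);
    an indirect component is flagged significant only when both constituent
    paths are (joint-significance rule, matching the usual binary rendering
    of mediated paths).
    """
    if aspect not in ASPECT_COLUMNS:
        raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECT_COLUMNS}")
    ind = fit.indicator_name
    direct = fit.path(aspect, ind)
    direct_sig = fit.path_p(aspect, ind) < alpha
    indirect = {}
    indirect_sig = {}
    for med in MEDIATORS:
        a_path = fit.path(aspect, med)
        b_path = fit.path(med, ind)
        indirect[med] = a_path * b_path
        indirect_sig[med] = bool(
            fit.path_p(aspect, med) < alpha and fit.path_p(med, ind) < alpha
        )
    total = direct + sum(indirect.values())
    return EffectDecomposition(
        aspect=aspect,
        indicator=ind,
        direct=direct,
        direct_significant=bool(direct_sig),
        indirect=indirect,
        indirect_significant=indirect_sig,
        total=total,
    )


def select_sem_targets(effect_table: pd.DataFrame) -> list[str]:
    """Indicators with at least one significant aspect effect, in stable
    (first-appearance) order."""
    mask = effect_table["predictor"].isin(ASPECT_COLUMNS) & effect_table["significant"]
    seen: list[str] = []
    for ind in effect_table.loc[mask, "indicator"]:
        if ind not in seen:
            seen.append(ind)
    order = list(dict.fromkeys(effect_table["indicator"]))
    return [ind for ind in order if ind in seen]


def simulate_recursive(
    model: PathModel,
    coefficients: dict[tuple[str, str], float],
    n: int,
    noise_sd: dict[str, float] | float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate data from a linear recursive system (standard-normal
    exogenous variables; ``coefficients`` maps (parent, child) to the path
    value, missing paths are zero).  Used for parameter-recovery and
    identity checks."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(index=range(n))
    for var in model.order:
        pars = model.parents.get(var, ())
        sd = noise_sd.get(var, 1.0) if isinstance(noise_sd, dict) else float(noise_sd)
        value = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
        for par in pars:
            value = value + coefficients.get((par, var), 0.0) * data[par].to_numpy()
        data[var] = value
    return data
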