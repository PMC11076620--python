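"""Log-response-ratio multifunctionality: per-indicator LRRs aggregated
through the service hierarchy, with stratified bootstrap confidence
intervals.

For a management contrast (e.g. eco-scheme yes vs. no) the log response
ratio of indicator j is

    LRR_j = ln( mean(y_j | treated) / mean(y_j | reference) ),

multiplied by -1 for disservices so that positive always means "the service
improved".  Indicator LRRs are averaged within each ecosystem service, the
mean over services is the MLRR (overall, or restricted to one of the three
categories), and (e^MLRR - 1) x 100 is the percent effect on the linear
scale.  Because a common positive scaling of an indicator cancels in the
ratio, the MLRR is identical on raw and max-scaled data.

Group means are arithmetic means of the raw indicator values over all plots
at each contrast level, marginal over the other aspects.  Confidence
intervals come from a nonparametric percentile bootstrap.  The default
resampling unit is the farm pair (block bootstrap over the design's
exchangeable sampling units, which propagates the within-pair correlation
induced by the blocked design); resampling plots with replacement within
each contrast group (stratified) is available via ``unit="plot"`` and is
appropriate when plots are independent.

Two comparison metrics are provided: the per-plot averaging index (row mean
of the preprocessed matrix) and a model-estimate index built from the
multivariate-regression coefficients aggregated through the same service
weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .services import (
    CATEGORIES,
    category_of_service,
    service_weight_matrix,
    validate_service_map,
)
from .synthetic_data import ASPECTS, REFERENCE_LEVELS, TREATED_LEVELS

log = logging.getLogger(__name__)


def contrast_levels(aspect: str) -> tuple[str, str]:
    """(treated, reference) level of a management aspect."""
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
    return TREATED_LEVELS[aspect], REFERENCE_LEVELS[aspect]


def _zero_guard_offsets(values: np.ndarray) -> np.ndarray:
    """Per-indicator offset: half the smallest positive value for columns
    containing zeros (0 otherwise).  Raw indicators are positive in
    principle, but zero counts occur."""
    offsets = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        if (col <= 0).any():
            positive = col[col > 0]
            if positive.size == 0:
                continue  # caught later as a non-positive mean
            offsets[j] = 0.5 * positive.min()
            log.info("lrr zero-guard: offset %.6g applied to column %d", offsets[j], j)
    return offsets


def lrr(
    treated_values: np.ndarray | pd.Series,
    reference_values: np.ndarray | pd.Series,
    disservice: bool = False,
    zero_guard: bool = True,
) -> float:
    """Signed log response ratio of one indicator for one contrast."""
    t = np.asarray(treated_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both contrast groups must be non-empty")
    off = 0.0
    if zero_guard and ((t <= 0).any() or (r <= 0).any()):
        both = np.concatenate([t, r])
        positive = both[both > 0]
        if positive.size:
            off = 0.5 * positive.min()
    mt, mr = t.mean() + off, r.mean() + off
    if mt <= 0 or mr <= 0:
        raise ValueError("non-positive group mean after zero-guard")
    value = np.log(mt / mr)
    return -value if disservice else value


def indicator_lrrs(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    aspect: str,
    service_map: pd.DataFrame,
    zero_guard: bool = True,
) -> pd.Series:
    """Signed LRR per indicator for the marginal contrast on ``aspect``."""
    validate_service_map(service_map)
    treated_level, ref_level = contrast_levels(aspect)
    groups = design.set_index("plot_id")[aspect].reindex(matrix.index)
    t_mask = (groups == treated_level).to_numpy()
    r_mask = (groups == ref_level).to_numpy()
    if t_mask.sum() == 0 or r_mask.sum() == 0:
        raise ValueError(f"empty contrast group for aspect {aspect!r}")
    flags = service_map.set_index("indicator")["disservice_flag"]
    out = {}
    for col in matrix.columns:
        out[col] = lrr(
            matrix.loc[t_mask, col],
            matrix.loc[r_mask, col],
            disservice=bool(flags[col]),
            zero_guard=zero_guard,
        )
    return pd.Series(out, name=aspect)


def aggregate_services(indicator_lrr: pd.Series, service_map: pd.DataFrame) -> pd.Series:
    """Unweighted mean of member-indicator LRRs per ecosystem service."""
    unmapped = set(indicator_lrr.index) - set(service_map["indicator"])
    if unmapped:
        raise ValueError(f"indicators not mapped to a service: {sorted(unmapped)}")
    a = service_weight_matrix(service_map)
    return a @ indicator_lrr.reindex(a.columns)


def mlrr(service_lrr: pd.Series, services: list[str] | None = None) -> float:
    """Mean of (selected) service-level LRRs; all services when unfiltered."""
    selected = service_lrr if services is None else service_lrr.loc[list(services)]
    if len(selected) == 0:
        raise ValueError("empty service selection for MLRR")
    return float(selected.mean())


def category_mlrrs(service_lrr: pd.Series, service_map: pd.DataFrame) -> pd.Series:
    cat = category_of_service(service_map)
    out = {
        c: mlrr(service_lrr, services=list(cat.index[cat == c]))
        for c in CATEGORIES
        if (cat == c).any()
    }
    return pd.Series(out)


def percent_effect(mlrr_value: float) -> float:
    """Effect on the linear scale, in percent: (e^m - 1) x 100."""
    return float((np.exp(mlrr_value) - 1.0) * 100.0)


@dataclass
class MultifunReport:
    """MLRR results for one management contrast."""

    aspect: str
    treated_level: str
    reference_level: str
    indicator_lrr: pd.Series
    service_lrr: pd.Series
    category_mlrr: pd.Series
    overall_mlrr: float
    category_ci: dict[str, tuple[float, float]]
    overall_ci: tuple[float, float]
    percent_effects: pd.Series  # categories + overall
    n_bootstrap: int
    level: float
    seed: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for svc, val in self.service_lrr.items():
            rows.append({"aspect": self.aspect, "scope": "service", "name": svc,
                         "estimate": val, "ci_low": np.nan, "ci_high": np.nan,
                         "percent": np.nan})
        for c, val in self.category_mlrr.items():
            lo, hi = self.category_ci.get(c, (np.nan, np.nan))
            rows.append({"aspect": self.aspect, "scope": "category", "name": c,
                         "estimate": val, "ci_low": lo, "ci_high": hi,
                         "percent": self.percent_effects[c]})
        lo, hi = self.overall_ci
        rows.append({"aspect": self.aspect, "scope": "overall", "name": "overall",
                     "estimate": self.overall_mlrr, "ci_low": lo, "ci_high": hi,
                     "percent": self.percent_effects["overall"]})
        return pd.DataFrame(rows)


def _group_arrays(matrix, design, aspect):
    treated_level, ref_level = contrast_levels(aspect)
    groups = design.set_index("plot_id")[aspect].reindex(matrix.index)
    y = matrix.to_numpy(dtype=float)
    t_idx = np.flatnonzero((groups == treated_level).to_numpy())
    r_idx = np.flatnonzero((groups == ref_level).to_numpy())
    if t_idx.size == 0 or r_idx.size == 0:
        raise ValueError(f"empty contrast group for aspect {aspect!r}")
    return y, t_idx, r_idx


def bootstrap_ci(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    aspect: str,
    service_map: pd.DataFrame,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    unit: str = "pair",
) -> tuple[dict[str, tuple[float, float]], tuple[float, float], int]:
    """Percentile bootstrap CIs for the category and overall MLRRs.

    ``unit="plot"`` resamples plots with replacement within each contrast
    group (stratified); ``unit="pair"`` resamples whole farm pairs with
    replacement (block bootstrap).  Replicates producing a non-positive
    group mean are redrawn and counted.  Deterministic given ``seed``.

    Returns ``(category_cis, overall_ci, n_redrawn)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    validate_service_map(service_map)
    rng = np.random.default_rng(seed)
    y, t_idx, r_idx = _group_arrays(matrix, design, aspect)
    flags = service_map.set_index("indicator")["disservice_flag"].reindex(matrix.columns)
    signs = np.where(flags.to_numpy(dtype=bool), -1.0, 1.0)
    a = service_weight_matrix(service_map)[list(matrix.columns)]
    a_mat = a.to_numpy()
    cat = category_of_service(service_map).reindex(a.index)

    offsets = _zero_guard_offsets(y[np.concatenate([t_idx, r_idx])])

    def group_means(idx_pool: np.ndarray, b: int) -> np.ndarray:
        if unit == "plot":
            counts = rng.multinomial(idx_pool.size, np.full(idx_pool.size, 1.0 / idx_pool.size), size=b)
            return (counts @ y[idx_pool]) / idx_pool.size
        raise AssertionError

    n_redrawn = 0
    if unit == "plot":
        mt = group_means(t_idx, B) + offsets
        mr = group_means(r_idx, B) + offsets
        for _ in range(100):  # redraw replicates with non-positive means
            bad = ((mt <= 0) | (mr <= 0)).any(axis=1)
            if not bad.any():
                break
            n_redrawn += int(bad.sum())
            nb = int(bad.sum())
            mt[bad] = group_means(t_idx, nb) + offsets
            mr[bad] = group_means(r_idx, nb) + offsets
        else:
            raise ValueError("bootstrap kept producing non-positive group means")
    elif unit == "pair":
        pair_of = design.set_index("plot_id")["pair_id"].reindex(matrix.index).to_numpy()
        pairs, pair_codes = np.unique(pair_of, return_inverse=True)
        n_pairs = pairs.size
        # plot-membership matrix per pair restricted to each contrast group
        memb_t = np.zeros((n_pairs, t_idx.size))
        memb_r = np.zeros((n_pairs, r_idx.size))
        memb_t[pair_codes[t_idx], np.arange(t_idx.size)] = 1.0
        memb_r[pair_codes[r_idx], np.arange(r_idx.size)] = 1.0
        mt = np.empty((B, y.shape[1]))
        mr = np.empty((B, y.shape[1]))
        b = 0
        attempts = 0
        while b < B:
            attempts += 1
            if attempts > 100 * B + 100:
                raise ValueError("pair bootstrap kept producing invalid replicates")
            # multiplicity of each pair in this replicate
            counts = rng.multinomial(n_pairs, np.full(n_pairs, 1.0 / n_pairs))
            w_t = counts @ memb_t  # per-plot multiplicities within each group
            w_r = counts @ memb_r
            if w_t.sum() == 0 or w_r.sum() == 0:
                n_redrawn += 1
                continue
            cand_t = (w_t @ y[t_idx]) / w_t.sum() + offsets
            cand_r = (w_r @ y[r_idx]) / w_r.sum() + offsets
            if (cand_t <= 0).any() or (cand_r <= 0).any():
                n_redrawn += 1
                continue
            mt[b], mr[b] = cand_t, cand_r
            b += 1
    else:
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    lrr_mat = np.log(mt / mr) * signs  # B x p
    svc_mat = lrr_mat @ a_mat.T  # B x services
    alpha = 1.0 - level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]

    overall = svc_mat.mean(axis=1)
    overall_ci = tuple(np.percentile(overall, qs))
    category_cis = {}
    for c in CATEGORIES:
        mask = (cat == c).to_numpy()
        if mask.any():
            vals = svc_mat[:, mask].mean(axis=1)
            category_cis[c] = tuple(np.percentile(vals, qs))
    return category_cis, overall_ci, n_redrawn


def multifunctionality_report(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    aspect: str,
    service_map: pd.DataFrame,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    unit: str = "pair",
) -> MultifunReport:
    """Full MLRR analysis of one contrast: point estimates at every level of
    the hierarchy, bootstrap CIs, and percent effects."""
    ind = indicator_lrrs(matrix, design, aspect, service_map)
    svc = aggregate_services(ind, service_map)
    cats = category_mlrrs(svc, service_map)
    overall = mlrr(svc)
    cat_ci, overall_ci, n_redrawn = bootstrap_ci(
        matrix, design, aspect, service_map, B=B, level=level, seed=seed, unit=unit
    )
    percents = pd.Series(
        {**{c: percent_effect(v) for c, v in cats.items()}, "overall": percent_effect(overall)}
    )
    treated_level, ref_level = contrast_levels(aspect)
    return MultifunReport(
        aspect=aspect,
        treated_level=treated_level,
        reference_level=ref_level,
        indicator_lrr=ind,
        service_lrr=svc,
        category_mlrr=cats,
        overall_mlrr=overall,
        category_ci=cat_ci,
        overall_ci=overall_ci,
        percent_effects=percents,
        n_bootstrap=B,
        level=level,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def averaging_index(preprocessed_matrix: pd.DataFrame) -> pd.Series:
    """Per-plot averaging multifunctionality: row mean of the preprocessed
    (scaled, reversed) matrix.  Loses information: opposite deviations of
    two indicators cancel."""
    if preprocessed_matrix.isna().any().any():
        raise ValueError("missing cells in preprocessed matrix")
    return preprocessed_matrix.mean(axis=1)


def estimate_index(effect_table: pd.DataFrame, service_map: pd.DataFrame) -> pd.Series:
    """Model-estimate multifunctionality comparator: per aspect, the mean of
    the multivariate-regression coefficients aggregated through the same
    1/(indicators per service) weighting as the MLRR.  Coefficients are
    sign-consistent because disservices are reversed in preprocessing."""
    a = service_weight_matrix(service_map)
    out = {}
    for pred, grp in effect_table.groupby("predictor"):
        est = grp.set_index("indicator")["estimate"].reindex(a.columns)
        out[pred] = float((a @ est).mean())
    return pd.Series(out)


def dominance_flags(report: MultifunReport, service_map: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Flag categories where a single service contributes more than
    ``threshold`` of the summed absolute service LRRs (single-service
    dominance, e.g. livestock presence driving the cultural category)."""
    cat = category_of_service(service_map).reindex(report.service_lrr.index)
    flags = {}
    for c in CATEGORIES:
        vals = report.service_lrr[cat == c].abs()
        total = vals.sum()
        flags[c] = bool(total > 0 and (vals / total > threshold).any())
    return pd.Series(flags)
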