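"""Scaling and transformation of indicators and environmental covariates.

The multivariate model expects approximately Gaussian responses on a common
scale.  The chain applied to the raw indicator matrix is, in order:

1. ``log_transform`` -- natural log of the indicators flagged for it (an
   offset of half the smallest positive observed value is added when a
   flagged column contains zeros);
2. ``max_scale`` -- divide every column by its maximum, so column maxima
   are 1 and effect estimates are comparable across indicators;
3. ``reverse_disservices`` -- map disservice columns (smaller = better) to
   ``max - value`` so that larger is always better.

The reversal keeps values non-negative and equal effect magnitudes with
flipped sign relative to reflecting values below zero.  Note it is not an
involution in general: applying it twice yields ``value - min`` and restores
the column only when the column minimum is zero.

The whole chain is a deterministic pure function of the matrix, the
indicator metadata, and the configuration (transform order is exposed for
sensitivity checks).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_ORDER = ("log", "max_scale", "reverse")


def max_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its maximum (must be positive)."""
    maxima = matrix.max(axis=0)
    bad = maxima[maxima <= 0]
    if len(bad):
        raise ValueError(f"columns with non-positive maximum cannot be max-scaled: {list(bad.index)}")
    return matrix / maxima


def log_transform(
    matrix: pd.DataFrame,
    log_flags: pd.Series,
    offset: float | None = None,
) -> pd.DataFrame:
    """Natural-log transform the flagged columns.

    ``offset`` is added inside the log.  With ``offset=None`` each flagged
    column containing zeros gets half its smallest positive value (logged);
    columns without zeros use no offset.  Non-positive values that an offset
    does not lift above zero raise.
    """
    out = matrix.copy()
    flags = log_flags.reindex(matrix.columns).fillna(False).astype(bool)
    for col in matrix.columns[flags]:
        v = matrix[col].to_numpy(dtype=float)
        off = offset
        if off is None:
            if (v <= 0).any():
                positive = v[v > 0]
                if positive.size == 0:
                    raise ValueError(f"column {col!r} has no positive values to log-transform")
                off = 0.5 * positive.min()
                log.info("log_transform: column %r contains zeros; offset %.6g applied", col, off)
            else:
                off = 0.0
        if ((v + off) <= 0).any():
            raise ValueError(f"column {col!r} has non-positive values with offset {off}")
        out[col] = np.log(v + off)
    return out


def reverse_disservices(matrix: pd.DataFrame, disservice_flags: pd.Series) -> pd.DataFrame:
    """Reverse flagged columns as ``column max - value`` (larger = better)."""
    out = matrix.copy()
    flags = disservice_flags.reindex(matrix.columns).fillna(False).astype(bool)
    for col in matrix.columns[flags]:
        out[col] = matrix[col].max() - matrix[col]
    return out


def standardize_env(covariates: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Bring environmental covariates to standard-deviation scale.

    Each column is divided by its sample SD (ddof=1); centring on by default.
    Zero-variance covariates raise.
    """
    sds = covariates.std(axis=0, ddof=1)
    bad = sds[~(sds > 0)]
    if len(bad):
        raise ValueError(f"zero-variance covariates cannot be standardized: {list(bad.index)}")
    out = covariates - covariates.mean(axis=0) if center else covariates.copy()
    return out / sds


def preprocess_indicators(
    matrix: pd.DataFrame,
    service_map: pd.DataFrame,
    order: tuple[str, ...] = DEFAULT_ORDER,
    log_offset: float | None = None,
) -> pd.DataFrame:
    """Apply the full transformation chain in the configured order."""
    sm = service_map.set_index("indicator")
    missing = set(matrix.columns) - set(sm.index)
    if missing:
        raise ValueError(f"indicators missing from service map: {sorted(missing)}")
    out = matrix
    for step in order:
        if step == "log":
            out = log_transform(out, sm["log_flag"], offset=log_offset)
        elif step == "max_scale":
            out = max_scale(out)
        elif step == "reverse":
            out = reverse_disservices(out, sm["disservice_flag"])
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return out
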