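"""Sample filtering and variable transforms that precede the regression.

The analysis scale is log2(x + 1) for expression and
log2(psi/(1 - psi) + 1) for exon inclusion, with PSI first clamped away
from the boundaries {0, 1} so the ratio stays finite.  Outlying samples
are removed per gene on the raw expression scale using a mean +/- k*std
border before any transform is applied.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import ExpressionMatrix, PsiMatrix, TripletVectors
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_ArrayLike = Union[float, np.ndarray]


def clamp_psi(v: _ArrayLike, low: float = 0.01, high: float = 0.99) -> _ArrayLike:
    """Clamp inclusion fractions into [low, high].

    Values of exactly 0 map to ``low`` and exactly 1 to ``high``; interior
    values pass through unchanged.  Idempotent.  Raises ValidationError
    for finite values outside [0, 1].
    """
    arr = np.asarray(v, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        bad = arr[finite][(arr[finite] < 0) | (arr[finite] > 1)][0]
        raise ValidationError(f"PSI value {bad} outside [0, 1]")
    out = np.clip(arr, low, high)
    out = np.where(finite, out, arr)
    return float(out) if np.isscalar(v) else out


def transform_expression(v: _ArrayLike) -> _ArrayLike:
    """log2(x + 1) transform of a non-negative expression value."""
    arr = np.asarray(v, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] < 0):
        raise ValidationError(
            f"negative expression value {arr[finite][arr[finite] < 0][0]}"
        )
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(v) else out


def transform_psi(v: _ArrayLike, low: float = 0.01, high: float = 0.99) -> _ArrayLike:
    """log2(psi/(1 - psi) + 1) transform of a clamped inclusion fraction.

    Strictly increasing on [low, high]; the input must already be clamped.
    """
    arr = np.asarray(v, dtype=float)
    finite = np.isfinite(arr)
    eps = 1e-12
    if np.any((arr[finite] < low - eps) | (arr[finite] > high + eps)):
        bad = arr[finite][(arr[finite] < low - eps) | (arr[finite] > high + eps)][0]
        raise ValidationError(f"PSI value {bad} outside clamp range [{low}, {high}]")
    out = np.log2(arr / (1.0 - arr) + 1.0)
    return float(out) if np.isscalar(v) else out


def outlier_mask(values, n_sd: float = 3.0) -> np.ndarray:
    """Keep-mask for one gene's raw expression vector.

    True where |v - mean| <= n_sd * std over the finite entries; the std is
    the sample estimate (ddof=1).  Missing entries are False (they cannot
    be kept).  A constant vector keeps everything (std = 0 and all
    deviations are 0).  Raises on an all-missing vector.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValidationError("cannot compute outlier border of all-missing vector")
    vals = arr[finite]
    mean = vals.mean()
    std = vals.std(ddof=1) if vals.size > 1 else 0.0
    keep = np.zeros(arr.shape, dtype=bool)
    keep[finite] = np.abs(arr[finite] - mean) <= n_sd * std
    return keep


def gene_outlier_masks(expr: ExpressionMatrix, n_sd: float = 3.0) -> pd.DataFrame:
    """Keep-masks for every gene at once (genes x samples boolean frame)."""
    vals = expr.data.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    counts = finite.sum(axis=1)
    if np.any(counts == 0):
        # all-missing genes keep nothing; they are filtered out upstream
        logger.warning("%d gene(s) have no finite expression values",
                       int((counts == 0).sum()))
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(finite, vals, np.nan), axis=1)
        sq = np.nansum(np.where(finite, (vals - mean[:, None]) ** 2, 0.0), axis=1)
        dof = np.maximum(counts - 1, 1)
        std = np.sqrt(sq / dof)
        keep = finite & (np.abs(vals - mean[:, None]) <= n_sd * std[:, None])
    return pd.DataFrame(keep, index=expr.data.index, columns=expr.data.columns)


def assemble_triplet(
    expr: ExpressionMatrix,
    psi: PsiMatrix,
    target: str,
    tf: str,
    event: str,
    config: Optional[AnalysisConfig] = None,
    masks: Optional[pd.DataFrame] = None,
) -> TripletVectors:
    """Build the transformed, fully-observed vectors for one triplet.

    Samples are retained when all three measurements are present and
    neither the TF nor the target value is an outlier for its gene
    (outlier borders computed once per gene over the gene's full finite
    vector).  If fewer than ``config.min_samples_triplet`` samples remain
    the result is returned with status "skipped" rather than raising.

    Raises KeyError when an identifier is absent from its matrix.
    """
    cfg = config or AnalysisConfig()
    if target not in expr.data.index:
        raise KeyError(f"target {target!r} not in expression matrix")
    if tf not in expr.data.index:
        raise KeyError(f"tf {tf!r} not in expression matrix")
    if event not in psi.data.index:
        raise KeyError(f"event {event!r} not in PSI matrix")

    common = expr.data.columns.intersection(psi.data.columns)
    e_t = expr.data.loc[target, common].to_numpy(dtype=float)
    e_f = expr.data.loc[tf, common].to_numpy(dtype=float)
    p = psi.data.loc[event, common].to_numpy(dtype=float)

    if masks is not None:
        keep_t = masks.loc[target, common].to_numpy(dtype=bool)
        keep_f = masks.loc[tf, common].to_numpy(dtype=bool)
    else:
        keep_t = outlier_mask(expr.data.loc[target].to_numpy(dtype=float),
                              cfg.outlier_sd)[expr.data.columns.get_indexer(common)]
        keep_f = outlier_mask(expr.data.loc[tf].to_numpy(dtype=float),
                              cfg.outlier_sd)[expr.data.columns.get_indexer(common)]

    keep = keep_t & keep_f & np.isfinite(p)
    n = int(keep.sum())
    sample_ids = list(common[keep])
    psi_raw = p[keep]
    tv = TripletVectors(
        sample_ids=sample_ids,
        x_tf=transform_expression(e_f[keep]),
        y_target=transform_expression(e_t[keep]),
        x_m=transform_psi(
            clamp_psi(psi_raw, cfg.psi_clamp_low, cfg.psi_clamp_high),
            cfg.psi_clamp_low, cfg.psi_clamp_high),
        psi_raw=psi_raw,
        n=n,
    )
    if n < cfg.min_samples_triplet:
        tv.status = "skipped"
        tv.reason = f"n={n} below min_samples_triplet={cfg.min_samples_triplet}"
    return tv
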