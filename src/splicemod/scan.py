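"""Interaction-term regression scan over (target, TF, splicing event) triplets.

For each triplet the model

    y_target' = b0 + b1 * x_tf' + b2 * x_m' + b3 * x_tf' * x_m' + e

is fit by ordinary least squares on the transformed vectors, and the
interaction coefficient b3 is tested against zero with a two-sided t test
on n - 4 degrees of freedom.  A non-zero b3 means the exon's inclusion
level changes the slope of the TF-target relationship, i.e. the event
modulates the TF's regulatory effect.  Benjamini-Hochberg correction is
applied once across the whole scan.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import (
    ExpressionMatrix,
    PsiMatrix,
    TFTargetMap,
    TripletResult,
    TripletVectors,
)
from .preprocess import assemble_triplet, gene_outlier_masks

logger = logging.getLogger(__name__)

# singular values below this (relative to the largest) count as rank loss
_RCOND = 1e-10


def fit_triplet(tv: TripletVectors, target_id: str = "", tf_id: str = "",
                event_id: str = "") -> TripletResult:
    """OLS fit of the interaction model for one triplet.

    Returns a TripletResult without q3/significant (those belong to the
    scan-level correction).  A rank-deficient design (e.g. constant PSI
    after transform) or too few residual degrees of freedom yields
    status "unfit" with a reason instead of raising.
    """
    res = TripletResult(target_id=target_id, tf_id=tf_id, event_id=event_id,
                        n=tv.n)
    if tv.status != "ok":
        res.status = "skipped"
        res.reason = tv.reason
        return res
    if tv.n < 5:
        res.status = "unfit"
        res.reason = f"n={tv.n} leaves no residual degrees of freedom"
        return res

    X = np.column_stack([np.ones(tv.n), tv.x_tf, tv.x_m, tv.x_tf * tv.x_m])
    beta, _, rank, _ = np.linalg.lstsq(X, tv.y_target, rcond=_RCOND)
    if rank < 4:
        res.status = "unfit"
        res.reason = "rank-deficient design (constant or collinear regressor)"
        return res

    resid = tv.y_target - X @ beta
    dof = tv.n - 4
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se3 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    if se3 == 0.0:
        # perfect fit: the t statistic is undefined; report p = 0 only if
        # the coefficient itself is non-zero
        t3 = np.inf if beta[3] != 0 else 0.0
        p3 = 0.0 if beta[3] != 0 else 1.0
    else:
        t3 = float(beta[3] / se3)
        p3 = float(2.0 * stats.t.sf(abs(t3), dof))

    res.beta = tuple(float(b) for b in beta)
    res.se3 = se3
    res.t3 = t3
    res.p3 = p3
    res.sign = "positive" if beta[3] > 0 else "negative"
    return res


def scan_all(
    expr: ExpressionMatrix,
    psi: PsiMatrix,
    pairs: TFTargetMap,
    events: Optional[Sequence[str]] = None,
    config: Optional[AnalysisConfig] = None,
) -> List[TripletResult]:
    """Fit every (pair x event) triplet; deterministic (tf, target, event) order.

    Pairs whose TF or target is absent from the expression matrix, or has
    fewer than ``min_samples_gene`` non-missing samples, produce skip
    records rather than fits, so the output always has one row per
    attempted triplet.
    """
    cfg = config or AnalysisConfig()
    event_list = sorted(events) if events is not None else sorted(psi.event_ids)
    pair_list = pairs.sorted_pairs()
    if cfg.exclude_self_pairs:
        pair_list = [(a, b) for a, b in pair_list if a != b]
    if not pair_list:
        logger.warning("empty TF-target pair list: nothing to scan")
        return []
    missing_events = [e for e in event_list if e not in psi.data.index]
    if missing_events:
        raise KeyError(f"event(s) not in PSI matrix: {missing_events[:5]}")

    n_per_gene = expr.samples_per_gene()
    masks = gene_outlier_masks(expr, cfg.outlier_sd)

    def gene_status(g: str) -> Optional[str]:
        if g not in expr.data.index:
            return "absent from expression matrix"
        if int(n_per_gene[g]) < cfg.min_samples_gene:
            return (f"only {int(n_per_gene[g])} expression samples "
                    f"(min_samples_gene={cfg.min_samples_gene})")
        return None

    results: List[TripletResult] = []
    for tf, target in pair_list:
        tf_bad = gene_status(tf)
        target_bad = gene_status(target)
        for event in event_list:
            if cfg.exclude_self_modulation:
                host = psi.event_gene.get(event, "")
                if host and host in (tf, target):
                    results.append(TripletResult(
                        target_id=target, tf_id=tf, event_id=event,
                        status="skipped", reason="self-modulation excluded"))
                    continue
            if tf_bad or target_bad:
                which = f"tf {tf}: {tf_bad}" if tf_bad else f"target {target}: {target_bad}"
                results.append(TripletResult(
                    target_id=target, tf_id=tf, event_id=event,
                    status="skipped", reason=which))
                continue
            tv = assemble_triplet(expr, psi, target, tf, event,
                                  config=cfg, masks=masks)
            results.append(fit_triplet(tv, target, tf, event))

    n_fit = sum(r.is_fit for r in results)
    logger.info("scan: %d triplets attempted, %d fit, %d skipped/unfit",
                len(results), n_fit, len(results) - n_fit)
    return results


def correct_fdr(
    results: Iterable[TripletResult],
    alpha: float = 0.05,
    mode: str = "fdr",
    pvalue_threshold: float = 0.01,
    per_tf: bool = False,
) -> List[TripletResult]:
    """Benjamini-Hochberg step-up over all fit triplets; sets q3/significant.

    mode "fdr" (default): significant iff q3 < alpha.
    mode "pvalue": significant iff raw p3 < pvalue_threshold (q3 still
    computed and reported).  With ``per_tf`` the BH correction is applied
    within each TF's triplets separately.
    """
    results = list(results)
    fit = [r for r in results if r.is_fit]
    if not fit:
        return results

    groups = {}
    for r in fit:
        groups.setdefault(r.tf_id if per_tf else None, []).append(r)
    for grp in groups.values():
        pvals = np.array([r.p3 for r in grp])
        q = multipletests(pvals, method="fdr_bh")[1]
        for r, qi in zip(grp, q):
            r.q3 = float(qi)
    for r in fit:
        if mode == "fdr":
            r.significant = bool(r.q3 < alpha)
        elif mode == "pvalue":
            r.significant = bool(r.p3 < pvalue_threshold)
        else:
            raise ValueError(f"unknown significance mode {mode!r}")
    n_sig = sum(r.significant for r in fit)
    logger.info("correction (%s): %d of %d fit triplets significant",
                mode, n_sig, len(fit))
    return results
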