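"""Mode-of-action classification of significant triplets.

Samples are split into low- and high-inclusion strata (bottom and top 30%
of raw PSI by default) and the TF-target Pearson correlation is called
'+', '-' or 'ns' within each stratum.  The transition of that state from
low to high PSI defines the mode of action:

    Active   — correlation appears or disappears (exactly one side 'ns')
    Repress  — same signed correlation on both sides (annotated "reduced"
               when its magnitude shrinks at high inclusion)
    Inverts  — the correlation flips sign
    Uncalled — 'ns' on both sides, or a stratum too small to test

The direction of modulation (positive/negative) is carried over from the
sign of the fitted interaction coefficient b3.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import (
    CorrelationState,
    ExpressionMatrix,
    ModeOfActionCall,
    PsiMatrix,
    TripletResult,
    TripletVectors,
)
from .exceptions import ValidationError
from .preprocess import assemble_triplet, gene_outlier_masks

logger = logging.getLogger(__name__)

CATEGORIES = ("Active", "Repress", "Inverts")
STATES = ("+", "-", "ns")


def split_by_psi(psi: pd.Series, fraction: float = 0.30) -> Tuple[list, list]:
    """Bottom and top floor(fraction * n) samples by raw PSI.

    Ties are broken by sample-id lexicographic order so the split is
    deterministic.  Raises if the two groups would overlap.
    """
    s = psi.dropna()
    n = len(s)
    k = math.floor(fraction * n)
    if k < 1:
        raise ValidationError(
            f"cannot split {n} samples at fraction {fraction}: empty groups")
    if 2 * k > n:
        raise ValidationError(
            f"groups of {k} overlap with only {n} samples at fraction {fraction}")
    order = sorted(zip(s.to_numpy(), s.index.astype(str)))
    ids = [sid for _, sid in order]
    if order[0][0] == order[-1][0]:
        logger.warning("all PSI values equal; split decided by sample-id order")
    return ids[:k], ids[n - k:]


def correlation_state(x, y, group: str = "", alpha_corr: float = 0.05) -> CorrelationState:
    """Pearson correlation state of a TF-target pair within one stratum.

    '+' / '-' require the two-sided correlation test p-value below
    ``alpha_corr``.  A zero-variance vector yields 'ns' with r undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("correlation vectors differ in length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 samples for a correlation state, got {x.size}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationState(group=group, r=float("nan"), p=float("nan"),
                                state="ns", n=int(x.size))
    r, p = stats.pearsonr(x, y)
    if p < alpha_corr and r > 0:
        state = "+"
    elif p < alpha_corr and r < 0:
        state = "-"
    else:
        state = "ns"
    return CorrelationState(group=group, r=float(r), p=float(p), state=state,
                            n=int(x.size))


def _categorize(low: str, high: str) -> str:
    if low == "ns" and high == "ns":
        return "Uncalled"
    if {low, high} == {"+", "-"}:
        return "Inverts"
    if low == high:
        return "Repress"
    return "Active"


def classify_triplet(
    result: TripletResult,
    tv: TripletVectors,
    psi_raw: Optional[pd.Series] = None,
    fraction: float = 0.30,
    alpha_corr: float = 0.05,
) -> ModeOfActionCall:
    """Assign one triplet a mode-of-action category.

    ``psi_raw`` defaults to the raw PSI stored in ``tv``.  Both strata need
    at least 3 samples; otherwise the call is Uncalled with a reason.
    """
    if psi_raw is None:
        psi_raw = pd.Series(tv.psi_raw, index=tv.sample_ids)
    psi_raw = psi_raw.reindex(tv.sample_ids)
    sign = result.sign
    base = dict(target_id=result.target_id, tf_id=result.tf_id,
                event_id=result.event_id, sign=sign)
    try:
        low_ids, high_ids = split_by_psi(psi_raw, fraction)
    except ValidationError as exc:
        return ModeOfActionCall(**base, low=None, high=None, transition=None,
                                category="Uncalled", reason=str(exc))
    if len(low_ids) < 3:
        return ModeOfActionCall(**base, low=None, high=None, transition=None,
                                category="Uncalled",
                                reason=f"stratum of {len(low_ids)} samples < 3")
    pos = {sid: i for i, sid in enumerate(tv.sample_ids)}
    li = [pos[s] for s in low_ids]
    hi = [pos[s] for s in high_ids]
    low = correlation_state(tv.x_tf[li], tv.y_target[li], "low", alpha_corr)
    high = correlation_state(tv.x_tf[hi], tv.y_target[hi], "high", alpha_corr)
    transition = f"{low.state}->{high.state}"
    category = _categorize(low.state, high.state)
    reduced = None
    if category == "Repress":
        reduced = bool(abs(high.r) < abs(low.r))
    return ModeOfActionCall(**base, low=low, high=high, transition=transition,
                            category=category, reduced=reduced)


def classify_all(
    results: Sequence[TripletResult],
    expr: ExpressionMatrix,
    psi: PsiMatrix,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[List[ModeOfActionCall], pd.DataFrame]:
    """Classify every significant triplet and tabulate the calls.

    Returns the calls plus a summary frame: rows (positive, negative) by
    columns (Active, Repress, Inverts, Uncalled); each called triplet falls
    in exactly one cell.
    """
    cfg = config or AnalysisConfig()
    masks = gene_outlier_masks(expr, cfg.outlier_sd)
    calls: List[ModeOfActionCall] = []
    for r in results:
        if not (r.is_fit and r.significant):
            continue
        tv = assemble_triplet(expr, psi, r.target_id, r.tf_id, r.event_id,
                              config=cfg, masks=masks)
        calls.append(classify_triplet(r, tv, fraction=cfg.psi_fraction,
                                      alpha_corr=cfg.alpha_corr))
    return calls, summarize_calls(calls)


def summarize_calls(calls: Sequence[ModeOfActionCall]) -> pd.DataFrame:
    """2 x 4 contingency table of calls by (b3 sign x category)."""
    table = pd.DataFrame(
        0, index=["positive", "negative"],
        columns=list(CATEGORIES) + ["Uncalled"], dtype=int)
    for c in calls:
        sign = c.sign if c.sign in ("positive", "negative") else "positive"
        table.loc[sign, c.category] += 1
    return table


def write_calls(calls: Sequence[ModeOfActionCall], path) -> None:
    """Write mode-of-action calls as a TSV."""
    rows = []
    for c in calls:
        rows.append({
            "target": c.target_id, "tf": c.tf_id, "event": c.event_id,
            "sign": c.sign if c.sign else "NA",
            "r_low": c.low.r if c.low else float("nan"),
            "p_low": c.low.p if c.low else float("nan"),
            "state_low": c.low.state if c.low else "NA",
            "r_high": c.high.r if c.high else float("nan"),
            "p_high": c.high.p if c.high else float("nan"),
            "state_high": c.high.state if c.high else "NA",
            "transition": c.transition if c.transition else "NA",
            "category": c.category,
            "reduced": "NA" if c.reduced is None else str(c.reduced),
            "reason": c.reason if c.reason else "NA",
        })
    cols = ["target", "tf", "event", "sign", "r_low", "p_low", "state_low",
            "r_high", "p_high", "state_high", "transition", "category",
            "reduced", "reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            na_rep="NA")
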