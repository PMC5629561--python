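"""Core in-memory containers shared across modules.

All matrices are thin wrappers around :class:`pandas.DataFrame` with
validation at construction time.  Expression matrices are genes x samples
on the raw (non-negative) scale; PSI matrices are splicing events x samples
with inclusion fractions in [0, 1].  Missing values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ExpressionMatrix",
    "PsiMatrix",
    "TFTargetMap",
    "PpiEdgeList",
    "TripletVectors",
    "TripletResult",
    "CorrelationState",
    "ModeOfActionCall",
    "ModulatorEdge",
]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``data.index`` holds gene identifiers, ``data.columns`` sample
    identifiers; both must be unique.  NaN marks a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        neg = np.asarray((vals < 0) & np.isfinite(vals))
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative expression value {vals[i, j]!r} at gene "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def samples_per_gene(self) -> pd.Series:
        """Number of non-missing samples for each gene."""
        return self.data.notna().sum(axis=1)


@dataclass
class PsiMatrix:
    """Splicing events x samples matrix of inclusion fractions (PSI).

    Every finite value lies in [0, 1].  ``event_gene`` maps each event to
    its host gene (empty string when unannotated).
    """

    data: pd.DataFrame
    event_gene: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "event")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        bad = np.asarray(((vals < 0) | (vals > 1)) & np.isfinite(vals))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"PSI value {vals[i, j]!r} outside [0, 1] at event "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)
        self.event_gene = {e: self.event_gene.get(e, "") for e in self.data.index}

    @property
    def event_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class TFTargetMap:
    """Set of directed (tf, target) regulatory pairs."""

    pairs: set

    def __post_init__(self) -> None:
        self.pairs = {(str(a), str(b)) for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    @property
    def tfs(self) -> list:
        return sorted({a for a, _ in self.pairs})

    @property
    def targets(self) -> list:
        return sorted({b for _, b in self.pairs})

    def drop_self_pairs(self) -> "TFTargetMap":
        return TFTargetMap({(a, b) for a, b in self.pairs if a != b})

    def sorted_pairs(self) -> list:
        return sorted(self.pairs)


@dataclass
class PpiEdgeList:
    """Undirected protein-protein interaction edges (no self-loops).

    Edges are stored as frozensets so (a, b) and (b, a) are the same edge.
    """

    edges: set

    def __post_init__(self) -> None:
        norm = set()
        for e in self.edges:
            a, b = tuple(e)
            if a == b:
                raise ValidationError(f"PPI self-loop on {a!r}")
            norm.add(frozenset((str(a), str(b))))
        self.edges = norm

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return a != b and frozenset((a, b)) in self.edges


@dataclass
class TripletVectors:
    """Analysis-ready vectors for one (target, TF, event) triplet.

    All vectors are aligned to ``sample_ids``, contain no missing values,
    and are on the model's transformed scale: log2(x + 1) for expression,
    log2(psi/(1 - psi) + 1) for clamped PSI.  ``psi_raw`` keeps the
    untransformed inclusion fractions for PSI-based sample grouping.
    ``status`` is "ok" or "skipped" (with ``reason``) when fewer samples
    survive preprocessing than the configured minimum.
    """

    sample_ids: list
    x_tf: np.ndarray
    y_target: np.ndarray
    x_m: np.ndarray
    psi_raw: np.ndarray
    n: int
    status: str = "ok"
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        self.x_tf = np.asarray(self.x_tf, dtype=float)
        self.y_target = np.asarray(self.y_target, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.psi_raw = np.asarray(self.psi_raw, dtype=float)
        lens = {len(self.sample_ids), self.x_tf.size, self.y_target.size,
                self.x_m.size, self.psi_raw.size}
        if lens != {self.n}:
            raise ValidationError(
                f"triplet vectors have inconsistent lengths {sorted(lens)}; n={self.n}"
            )
        for name, v in (("x_tf", self.x_tf), ("y_target", self.y_target),
                        ("x_m", self.x_m)):
            if self.n and not np.isfinite(v).all():
                raise ValidationError(f"non-finite value in {name}")


@dataclass
class TripletResult:
    """Regression outcome for one (target, TF, event) triplet.

    ``beta`` holds (b0 intercept, b1 TF main effect, b2 modulator main
    effect, b3 interaction).  ``p3`` is the two-sided t-test p-value for
    H0: b3 = 0 on n - 4 degrees of freedom; ``q3`` the Benjamini-Hochberg
    adjusted value over the scan.  ``status`` is "ok", "skipped" or
    "unfit"; non-ok rows carry a ``reason`` and NaN statistics.
    """

    target_id: str
    tf_id: str
    event_id: str
    n: int = 0
    beta: tuple = (float("nan"),) * 4
    se3: float = float("nan")
    t3: float = float("nan")
    p3: float = float("nan")
    q3: float = float("nan")
    significant: bool = False
    sign: Optional[str] = None
    status: str = "ok"
    reason: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.target_id, self.tf_id, self.event_id)

    @property
    def is_fit(self) -> bool:
        return self.status == "ok"


@dataclass
class CorrelationState:
    """TF-target Pearson correlation within one PSI stratum.

    ``state`` is '+' when p < alpha and r > 0, '-' when p < alpha and
    r < 0, otherwise 'ns' (no significant correlation).
    """

    group: str
    r: float
    p: float
    state: str
    n: int


@dataclass
class ModeOfActionCall:
    """Mode-of-action classification for one significant triplet.

    ``transition`` is "<low-state>-><high-state>" with states in
    {'+', '-', 'ns'}.  ``category`` is Active (exactly one side 'ns'),
    Repress (same signed state both sides), Inverts (signed state flips),
    or Uncalled ('ns'->'ns', or groups too small).  ``reduced`` is set for
    Repress calls when |r_high| < |r_low|.
    """

    target_id: str
    tf_id: str
    event_id: str
    sign: Optional[str]
    low: Optional[CorrelationState]
    high: Optional[CorrelationState]
    transition: Optional[str]
    category: str
    reduced: Optional[bool] = None
    reason: Optional[str] = None


@dataclass
class ModulatorEdge:
    """Aggregated influence of one (TF, splicing event) pair.

    ``pct_influenced`` = 100 * n_influenced / n_targets_tested, the
    percentage of the TF's tested targets whose regulation is significantly
    modulated by the event's inclusion level.
    """

    tf_id: str
    event_id: str
    event_gene: str
    n_targets_tested: int
    n_influenced: int
    pct_influenced: float
    n_positive: int
    n_negative: int
    ppi_supported: Optional[bool] = None
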