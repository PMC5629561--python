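"""Readers and writers for the tab-separated inputs and outputs.

Matrix files are TSV with the first row holding sample identifiers and the
first column gene/event identifiers.  A PSI matrix may carry an optional
second column named ``gene`` giving each event's host gene.  Missing values
are written as ``NA``; on input both ``NA`` and the empty cell are accepted.
Identifiers are opaque, case-sensitive strings.

Floats are written with Python's shortest round-tripping repr, so a
write -> read cycle reproduces every finite value bit-exactly.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    ModulatorEdge,
    PpiEdgeList,
    PsiMatrix,
    TFTargetMap,
    TripletResult,
)
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

_NA_TOKENS = ["NA", "nan", "NaN", ""]

TRIPLET_COLUMNS = [
    "target", "tf", "event", "status", "reason", "n",
    "beta0", "beta1", "beta2", "beta3",
    "se3", "t3", "p3", "q3", "significant", "sign",
]

EDGE_COLUMNS = [
    "tf", "event", "gene", "n_targets_tested", "n_influenced",
    "pct_influenced", "n_positive", "n_negative", "ppi_supported",
]


def _read_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    if df.index.isna().any() or any(c == "" for c in df.columns):
        raise ParseError(f"{path}: malformed header or empty identifier")
    return df


def _to_float(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.replace(dict.fromkeys(_NA_TOKENS, np.nan))
    try:
        return out.astype(float)
    except ValueError:
        for col in out.columns:
            bad = pd.to_numeric(out[col], errors="coerce").isna() & out[col].notna()
            if bad.any():
                row = out.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"{path}: non-numeric cell {out.loc[row, col]!r} at row "
                    f"{row!r}, column {col!r}"
                ) from None
        raise


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    Raises :class:`ParseError` on malformed input and
    :class:`ValidationError` on negative values or duplicate identifiers.
    """
    df = _to_float(_read_matrix(path), path)
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_psi(path) -> PsiMatrix:
    """Read an events x samples PSI matrix.

    If the second column of the header is named ``gene`` it is taken as the
    per-event host-gene annotation rather than a sample.
    """
    df = _read_matrix(path)
    event_gene = {}
    if len(df.columns) and df.columns[0].lower() == "gene":
        event_gene = {e: g for e, g in zip(df.index, df.iloc[:, 0])}
        df = df.iloc[:, 1:]
    vals = _to_float(df, path)
    try:
        return PsiMatrix(vals, event_gene=event_gene)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_two_columns(path, header_names) -> List[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip() != ""]
            if lineno == 1 and [f.lower() for f in fields] == list(header_names):
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 identifier fields, got "
                    f"{len(fields)}: {line!r}"
                )
            rows.append((fields[0], fields[1]))
    return rows


def read_pairs(path) -> TFTargetMap:
    """Read a two-column (tf, target) pair list; duplicates collapse."""
    rows = _read_two_columns(path, ("tf", "target"))
    if not rows:
        logger.warning("%s: empty TF-target pair list", path)
    return TFTargetMap(set(rows))


def read_ppi(path) -> PpiEdgeList:
    """Read a two-column undirected protein-interaction edge list.

    Self-loop rows are dropped with a warning rather than rejected.
    """
    rows = _read_two_columns(path, ("protein_a", "protein_b"))
    loops = [(a, b) for a, b in rows if a == b]
    if loops:
        logger.warning("%s: dropped %d self-loop edge(s)", path, len(loops))
    return PpiEdgeList({frozenset(e) for e in rows if e[0] != e[1]})


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def write_psi(psi: PsiMatrix, path) -> None:
    df = psi.data.copy()
    if any(g != "" for g in psi.event_gene.values()):
        df.insert(0, "gene", [psi.event_gene.get(e, "") for e in df.index])
    df.to_csv(path, sep="\t", na_rep="NA", index_label="event_id")


def write_pairs(pairs: TFTargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\n")
        for a, b in pairs.sorted_pairs():
            fh.write(f"{a}\t{b}\n")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if isinstance(x, bool) or isinstance(x, np.bool_):
        return "True" if x else "False"
    return repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)


def write_triplets(results: Iterable[TripletResult], path) -> None:
    """Write triplet regression results as a TSV with a header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRIPLET_COLUMNS) + "\n")
        for r in results:
            b = list(r.beta) + [float("nan")] * (4 - len(r.beta))
            row = [r.target_id, r.tf_id, r.event_id, r.status,
                   r.reason if r.reason is not None else "NA",
                   str(int(r.n)),
                   _fmt(b[0]), _fmt(b[1]), _fmt(b[2]), _fmt(b[3]),
                   _fmt(r.se3), _fmt(r.t3), _fmt(r.p3), _fmt(r.q3),
                   _fmt(r.significant),
                   r.sign if r.sign is not None else "NA"]
            fh.write("\t".join(row) + "\n")


def read_triplets(path) -> List[TripletResult]:
    """Read back a triplet table written by :func:`write_triplets`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing triplet column(s) {missing}")

    def f(v):
        return float("nan") if v == "NA" else float(v)

    out = []
    for row in df.itertuples(index=False):
        out.append(TripletResult(
            target_id=row.target, tf_id=row.tf, event_id=row.event,
            status=row.status,
            reason=None if row.reason == "NA" else row.reason,
            n=int(row.n),
            beta=(f(row.beta0), f(row.beta1), f(row.beta2), f(row.beta3)),
            se3=f(row.se3), t3=f(row.t3), p3=f(row.p3), q3=f(row.q3),
            significant=(row.significant == "True"),
            sign=None if row.sign == "NA" else row.sign,
        ))
    return out


def write_edges(edges: Iterable[ModulatorEdge], path) -> None:
    """Write TF-modulator edges (with percent-influenced) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            row = [e.tf_id, e.event_id, e.event_gene,
                   str(e.n_targets_tested), str(e.n_influenced),
                   _fmt(float(e.pct_influenced)),
                   str(e.n_positive), str(e.n_negative),
                   "NA" if e.ppi_supported is None else _fmt(e.ppi_supported)]
            fh.write("\t".join(row) + "\n")


def read_edges(path) -> List[ModulatorEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing edge column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(ModulatorEdge(
            tf_id=row.tf, event_id=row.event, event_gene=row.gene,
            n_targets_tested=int(row.n_targets_tested),
            n_influenced=int(row.n_influenced),
            pct_influenced=float(row.pct_influenced),
            n_positive=int(row.n_positive),
            n_negative=int(row.n_negative),
            ppi_supported=None if row.ppi_supported == "NA"
            else row.ppi_supported == "True",
        ))
    return out
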