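"""TF-modulator influence aggregation and bipartite network construction.

Each (TF, splicing event) pair becomes a candidate network edge weighted
by the percentage of the TF's tested targets whose regulation the event
significantly modulates.  Edges can be thresholded (strictly) on that
percentage and optionally restricted to pairs with documented physical
interaction between the TF and the event's host protein.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .datatypes import ModulatorEdge, PpiEdgeList, TripletResult

logger = logging.getLogger(__name__)


def summarize_edges(
    results: Sequence[TripletResult],
    event_gene: Optional[Dict[str, str]] = None,
) -> List[ModulatorEdge]:
    """One ModulatorEdge per (tf, event) with at least one fit triplet.

    The denominator counts fit (tested) triplets only; skipped and unfit
    triplets do not enter the percentage.  Sorted by (tf, event).
    """
    event_gene = event_gene or {}
    tested: Dict[Tuple[str, str], List[TripletResult]] = {}
    for r in results:
        if r.is_fit:
            tested.setdefault((r.tf_id, r.event_id), []).append(r)
    edges = []
    for (tf, event) in sorted(tested):
        grp = tested[(tf, event)]
        sig = [r for r in grp if r.significant]
        n_pos = sum(1 for r in sig if r.sign == "positive")
        edges.append(ModulatorEdge(
            tf_id=tf, event_id=event,
            event_gene=event_gene.get(event, ""),
            n_targets_tested=len(grp),
            n_influenced=len(sig),
            pct_influenced=100.0 * len(sig) / len(grp),
            n_positive=n_pos,
            n_negative=len(sig) - n_pos,
        ))
    return edges


def threshold_network(
    edges: Sequence[ModulatorEdge], min_pct: float = 30.0
) -> List[ModulatorEdge]:
    """Edges whose percent-influenced strictly exceeds ``min_pct``."""
    kept = [e for e in edges if e.pct_influenced > min_pct]
    logger.info("threshold > %g%%: kept %d of %d edges (%d TFs, %d modulators)",
                min_pct, len(kept), len(edges),
                len({e.tf_id for e in kept}), len({e.event_id for e in kept}))
    return kept


def filter_ppi(
    edges: Sequence[ModulatorEdge],
    ppi: PpiEdgeList,
    require: bool = False,
) -> List[ModulatorEdge]:
    """Flag edges whose (TF, event host gene) pair has a documented
    physical interaction; with ``require`` unsupported edges are dropped.

    Membership is unordered: an interaction recorded as (B, A) supports
    the edge (A, B-event).  Events without a host-gene annotation are
    unsupported (with a warning).  Percentages are never altered.
    """
    out = []
    n_unannotated = 0
    for e in edges:
        e.ppi_supported = bool(e.event_gene) and ppi.has_edge(e.tf_id, e.event_gene)
        if not e.event_gene:
            n_unannotated += 1
        if e.ppi_supported or not require:
            out.append(e)
    if n_unannotated:
        logger.warning("%d edge(s) lack a host-gene annotation; marked unsupported",
                       n_unannotated)
    return out


def to_bipartite_graph(edges: Sequence[ModulatorEdge]) -> nx.Graph:
    """networkx bipartite graph: TFs (bipartite=0) vs modulator events (=1)."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.tf_id, bipartite=0, kind="tf")
        g.add_node(e.event_id, bipartite=1, kind="modulator",
                   gene=e.event_gene)
        g.add_edge(e.tf_id, e.event_id,
                   pct_influenced=e.pct_influenced,
                   n_influenced=e.n_influenced,
                   n_targets_tested=e.n_targets_tested,
                   ppi_supported=e.ppi_supported)
    return g
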