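"""Prior-knowledge-network (PKN) interaction tables.

The curated literature database behind the model is a flat table of pairwise
regulations. Each row records an activation (``->``) or inhibition (``-|``)
from one gene product (protein, complex, or miRNA) to another, the UniProt
accessions, the PubMed IDs supporting it, a curator confidence class and a
short evidence extract. Confidence classes:

- ``S`` (Sure): textbook/UniProt-annotated, usually many PMIDs;
- ``U`` (Unsure): shown once or unconfirmed;
- ``I`` (Inferred): from another cell type/organism or isoform inference;
- ``C`` (Contradictory): conflicting reports.

This module reads/writes the table (TSV, header row using the canonical
column names below, case-insensitive and order-free), computes summary
statistics, and derives the signed interaction digraph. It deliberately does
*not* synthesize Boolean rules from the table: turning curated edges into
logic is a manual refinement step, not a mechanical compilation.

Complex names such as ``Byr4p-Cdc16p`` are single node identifiers; the
action column, never tokenization of names, carries the edge semantics.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionRecord",
    "PknStats",
    "COLUMNS",
    "parse_interaction_table",
    "write_interaction_table",
    "pkn_statistics",
    "skeleton_from_pkn",
]

COLUMNS = (
    "Node 1",
    "Action",
    "Node 2",
    "Node 1 type",
    "Node 2 type",
    "UniProt ID 1",
    "UniProt ID 2",
    "PMID",
    "Class",
    "Evidence tag",
)

_ACTIONS = {"->": "activation", "-|": "inhibition"}
_ACTION_SYMBOLS = {v: k for k, v in _ACTIONS.items()}
_CONFIDENCE = frozenset("SUIC")
_NODE1_TYPES = frozenset({"protein", "complex", "miRNA"})
_NODE2_TYPES = frozenset({"protein", "miRNA"})


@dataclass(frozen=True)
class InteractionRecord:
    """One curated pairwise regulation: node1 --action--> node2."""

    node1: str
    action: str  # "activation" | "inhibition"
    node2: str
    node1_type: str = "protein"
    node2_type: str = "protein"
    uniprot1: str = ""
    uniprot2: str = ""
    pmids: tuple[str, ...] = ()
    confidence: str = "S"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.action not in _ACTION_SYMBOLS:
            raise ValueError(f"action must be activation/inhibition, got {self.action!r}")
        if self.confidence not in _CONFIDENCE:
            raise ValueError(f"confidence class must be one of S/U/I/C, got {self.confidence!r}")
        object.__setattr__(self, "pmids", tuple(self.pmids))

    @property
    def sign(self) -> str:
        return "+" if self.action == "activation" else "-"


@dataclass(frozen=True)
class PknStats:
    n_nodes: int
    n_edges: int
    n_pmids: int
    confidence_histogram: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_pmids": self.n_pmids,
            "confidence_histogram": dict(self.confidence_histogram),
        }


def _canon_column(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


_CANON_TO_FIELD = {_canon_column(c): c for c in COLUMNS}
_MANDATORY = {"node 1", "action", "node 2", "class"}


def _split_pmids(cell: str) -> tuple[str, ...]:
    # multi-PMID cells split on any non-digit run; order preserved, no dedup
    return tuple(m.group(0) for m in re.finditer(r"\d+", cell or ""))


def parse_interaction_table(tsv: str | io.TextIOBase) -> list[InteractionRecord]:
    """Parse a TSV interaction table into records.

    The header row must contain the mandatory columns (Node 1, Action,
    Node 2, Class); matching is case-insensitive and order-free. Unknown
    action symbols or confidence classes raise ``ValueError``.
    """
    if isinstance(tsv, str):
        tsv = io.StringIO(tsv)
    df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in df.columns:
        canon = _canon_column(col)
        if canon in _CANON_TO_FIELD:
            colmap[_CANON_TO_FIELD[canon]] = col
    missing = [_CANON_TO_FIELD[c] for c in _MANDATORY if _CANON_TO_FIELD[c] not in colmap]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    def get(row, field: str) -> str:
        col = colmap.get(field)
        return str(row[col]).strip() if col is not None else ""

    records: list[InteractionRecord] = []
    for i, row in df.iterrows():
        symbol = get(row, "Action")
        if symbol not in _ACTIONS:
            raise ValueError(f"row {i + 1}: unknown action symbol {symbol!r} (expected -> or -|)")
        conf = get(row, "Class").upper()
        if conf not in _CONFIDENCE:
            raise ValueError(f"row {i + 1}: unknown confidence class {conf!r}")
        records.append(
            InteractionRecord(
                node1=get(row, "Node 1"),
                action=_ACTIONS[symbol],
                node2=get(row, "Node 2"),
                node1_type=get(row, "Node 1 type") or "protein",
                node2_type=get(row, "Node 2 type") or "protein",
                uniprot1=get(row, "UniProt ID 1"),
                uniprot2=get(row, "UniProt ID 2"),
                pmids=_split_pmids(get(row, "PMID")),
                confidence=conf,
                evidence=get(row, "Evidence tag"),
            )
        )
    return records


def write_interaction_table(records: Iterable[InteractionRecord]) -> str:
    """Serialize records back to canonical TSV (inverse of parsing, field-wise)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Node 1": r.node1,
                "Action": _ACTION_SYMBOLS[r.action],
                "Node 2": r.node2,
                "Node 1 type": r.node1_type,
                "Node 2 type": r.node2_type,
                "UniProt ID 1": r.uniprot1,
                "UniProt ID 2": r.uniprot2,
                "PMID": ", ".join(r.pmids),
                "Class": r.confidence,
                "Evidence tag": r.evidence,
            }
        )
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return df.to_csv(sep="\t", index=False)


def pkn_statistics(records: Sequence[InteractionRecord]) -> PknStats:
    """Node, edge and distinct-PMID counts plus the confidence histogram.

    ``n_nodes`` counts distinct endpoint names, ``n_edges`` counts rows
    (parallel and opposite-sign regulations each count), ``n_pmids`` counts
    distinct PubMed IDs across all rows.
    """
    names = {r.node1 for r in records} | {r.node2 for r in records}
    pmids = {p for r in records for p in r.pmids}
    hist: dict[str, int] = {}
    for r in records:
        hist[r.confidence] = hist.get(r.confidence, 0) + 1
    return PknStats(len(names), len(records), len(pmids), hist)


def skeleton_from_pkn(records: Sequence[InteractionRecord]) -> nx.MultiDiGraph:
    """Signed interaction digraph: nodes = endpoint names, one edge per
    (source, target, sign), with same-signed parallel duplicates collapsed.
    Opposite-sign edges between the same pair are both retained. Node
    insertion order is lexicographic, so layouts and iterations are stable.
    """
    g = nx.MultiDiGraph()
    names = sorted({r.node1 for r in records} | {r.node2 for r in records})
    g.add_nodes_from(names)
    seen: set[tuple[str, str, str]] = set()
    for r in records:
        key = (r.node1, r.node2, r.sign)
        if key in seen:
            continue
        seen.add(key)
        g.add_edge(r.node1, r.node2, key=r.sign, sign=r.sign)
    return g
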