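"""Multi-layer meta-interactome data model and edge-table readers.

The meta-interactome merges four relation layers over three node kinds:

* protein--protein interactions (PPI; undirected, confidence-scored),
* miRNA -> target-gene regulation (directed),
* transcription-factor -> target-gene regulation (directed),
* metabolic-enzyme -- metabolite incidence (substrate/product roles).

Proteins and genes share one node per gene symbol: the network treats the
gene and its product as a single entity, so identifiers must be pre-mapped
to symbols before loading.  PPI edges are stored once with canonical
``source < target`` ordering; regulatory edges keep their direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN = "protein"
MIRNA = "mirna"
METABOLITE = "metabolite"
NODE_KINDS = (PROTEIN, MIRNA, METABOLITE)

PPI = "ppi"
MIRNA_TARGET = "mirna_target"
TF_TARGET = "tf_target"
ENZYME_METABOLITE = "enzyme_metabolite"
EDGE_KINDS = (PPI, MIRNA_TARGET, TF_TARGET, ENZYME_METABOLITE)

#: regulatory edge kinds are directed; PPI and enzyme-metabolite are not
DIRECTED_KINDS = frozenset({MIRNA_TARGET, TF_TARGET})


class FormatError(ValueError):
    """Raised when an input table violates its documented dialect."""


@dataclass(frozen=True)
class NodeRecord:
    """One node of the meta-interactome.

    ``kind`` is one of ``protein``, ``mirna``, ``metabolite``.  Boolean
    flags mark pathway membership (signaling / metabolic enzyme), TF
    status, participation in signaling crosstalk, and rate-limiting
    enzymes; metabolite nodes never carry protein-only flags.
    """

    id: str
    kind: str = PROTEIN
    is_tf: bool = False
    is_signaling: bool = False
    is_metabolic_enzyme: bool = False
    is_crosstalk: bool = False
    is_rate_limiting: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == METABOLITE and (
            self.is_tf or self.is_signaling or self.is_metabolic_enzyme
        ):
            raise ValueError(
                f"metabolite node {self.id!r} cannot carry protein flags"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """One edge; PPI edges are canonicalized so that source < target."""

    source: str
    target: str
    kind: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source!r}")
        if self.kind == PPI and self.source > self.target:
            lo, hi = self.target, self.source
            object.__setattr__(self, "source", lo)
            object.__setattr__(self, "target", hi)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.kind)


@dataclass
class Annotations:
    """Optional node-flag tables joined onto the merged network."""

    signaling: frozenset[str] = frozenset()
    metabolic_enzymes: frozenset[str] = frozenset()
    crosstalk: frozenset[str] = frozenset()
    rate_limiting: frozenset[str] = frozenset()


class MetaInteractome:
    """Merged multi-layer network with per-kind adjacency lookup.

    Neighbor queries are dictionary lookups: ``neighbors(v, kind)``
    returns the undirected neighbor set restricted to one edge kind,
    ``successors``/``predecessors`` respect direction for regulatory
    kinds.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, NodeRecord] = {}
        self.edges: dict[tuple[str, str, str], EdgeRecord] = {}
        # node -> kind -> neighbor ids (undirected view)
        self._adj: dict[str, dict[str, set[str]]] = {}
        # node -> kind -> targets / sources (directed kinds only)
        self._out: dict[str, dict[str, set[str]]] = {}
        self._in: dict[str, dict[str, set[str]]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, record: NodeRecord) -> None:
        existing = self.nodes.get(record.id)
        if existing is None:
            self.nodes[record.id] = record
            self._adj.setdefault(record.id, {})
            return
        if existing.kind != record.kind:
            raise FormatError(
                f"node {record.id!r} declared both {existing.kind} "
                f"and {record.kind}"
            )
        # merge flags (logical OR)
        self.nodes[record.id] = NodeRecord(
            id=record.id,
            kind=record.kind,
            is_tf=existing.is_tf or record.is_tf,
            is_signaling=existing.is_signaling or record.is_signaling,
            is_metabolic_enzyme=existing.is_metabolic_enzyme
            or record.is_metabolic_enzyme,
            is_crosstalk=existing.is_crosstalk or record.is_crosstalk,
            is_rate_limiting=existing.is_rate_limiting
            or record.is_rate_limiting,
        )

    def add_edge(self, edge: EdgeRecord) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                kind = PROTEIN
                if edge.kind == MIRNA_TARGET and endpoint == edge.source:
                    kind = MIRNA
                self.add_node(NodeRecord(id=endpoint, kind=kind))
        if edge.key in self.edges:
            return
        self.edges[edge.key] = edge
        self._adj.setdefault(edge.source, {}).setdefault(edge.kind, set()).add(
            edge.target
        )
        self._adj.setdefault(edge.target, {}).setdefault(edge.kind, set()).add(
            edge.source
        )
        if edge.kind in DIRECTED_KINDS:
            self._out.setdefault(edge.source, {}).setdefault(
                edge.kind, set()
            ).add(edge.target)
            self._in.setdefault(edge.target, {}).setdefault(
                edge.kind, set()
            ).add(edge.source)

    # -- queries ------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def neighbors(self, node_id: str, kind: str | None = None) -> set[str]:
        """Undirected neighbor set, optionally restricted to one kind."""
        by_kind = self._adj.get(node_id, {})
        if kind is not None:
            return set(by_kind.get(kind, ()))
        out: set[str] = set()
        for members in by_kind.values():
            out |= members
        return out

    def successors(self, node_id: str, kind: str) -> set[str]:
        return set(self._out.get(node_id, {}).get(kind, ()))

    def predecessors(self, node_id: str, kind: str) -> set[str]:
        return set(self._in.get(node_id, {}).get(kind, ()))

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, r in self.nodes.items() if r.kind == kind}

    def to_networkx(self, kinds: Iterable[str] = (PPI,)) -> nx.Graph:
        """Undirected simple-graph projection over the given edge kinds."""
        wanted = set(kinds)
        graph = nx.Graph()
        for node_id, record in self.nodes.items():
            graph.add_node(node_id, kind=record.kind)
        for edge in self.edges.values():
            if edge.kind in wanted:
                graph.add_edge(edge.source, edge.target, kind=edge.kind)
        return graph

    def subgraph(self, node_ids: Iterable[str]) -> "MetaInteractome":
        """Induced subgraph: kept nodes and every edge between them."""
        keep = set(node_ids)
        sub = MetaInteractome()
        for node_id in sorted(keep):
            if node_id in self.nodes:
                sub.add_node(self.nodes[node_id])
        for edge in self.edges.values():
            if edge.source in keep and edge.target in keep:
                sub.add_edge(edge)
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaInteractome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        """Deterministic JSON graph export (nodes[], edges[], flags)."""
        payload = {
            "nodes": [
                {
                    "id": r.id,
                    "kind": r.kind,
                    "is_tf": r.is_tf,
                    "is_signaling": r.is_signaling,
                    "is_metabolic_enzyme": r.is_metabolic_enzyme,
                    "is_crosstalk": r.is_crosstalk,
                    "is_rate_limiting": r.is_rate_limiting,
                }
                for r in sorted(self.nodes.values(), key=lambda r: r.id)
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind,
                    "score": e.score,
                }
                for e in sorted(self.edges.values(), key=lambda e: e.key)
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetaInteractome":
        payload = json.loads(text)
        net = cls()
        for n in payload["nodes"]:
            net.add_node(NodeRecord(**n))
        for e in payload["edges"]:
            net.add_edge(EdgeRecord(**e))
        return net


# ---------------------------------------------------------------------
# readers


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_string_edges(
    path: str | Path,
    min_experimental: int = 700,
    score_column: str = "experimental",
) -> set[EdgeRecord]:
    """Read a STRING-style protein-links table and keep confident edges.

    The file is whitespace- or tab-delimited with a header naming at
    least ``protein1``, ``protein2`` and the per-channel score column
    (``experimental`` by default; pass ``score_column="combined_score"``
    to filter on the combined channel instead).  Scores are integers on
    the 0--1000 STRING scale; only rows with
    ``score >= min_experimental`` are kept.  Self-edges are dropped and
    duplicate pairs (either orientation) collapse to one undirected
    edge.
    """
    if not 0 <= min_experimental <= 1000:
        raise ValueError("min_experimental must lie in [0, 1000]")
    frame = _read_table(path, sep=r"\s+")
    required = {"protein1", "protein2", score_column}
    missing = required - set(frame.columns)
    if missing and not frame.empty:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    edges: set[EdgeRecord] = set()
    if frame.empty:
        logger.warning("%s: empty links file", path)
        return edges
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        a, b = getattr(row, "protein1"), getattr(row, "protein2")
        raw = getattr(row, score_column)
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{line_no}: unreadable {score_column} score {raw!r}"
            ) from None
        if a == b or score < min_experimental:
            continue
        edges.add(EdgeRecord(source=a, target=b, kind=PPI, score=score))
    return edges


def read_regulatory_edges(path: str | Path, kind: str) -> set[EdgeRecord]:
    """Read a regulator/target TSV into directed regulatory edges.

    ``kind`` selects the layer: ``mirna_target`` creates miRNA source
    nodes, ``tf_target`` flags sources as transcription factors when the
    network is built.  Duplicate rows collapse silently.
    """
    if kind not in DIRECTED_KINDS:
        raise ValueError(f"kind must be one of {sorted(DIRECTED_KINDS)}")
    frame = _read_table(path, sep="\t")
    if frame.empty:
        logger.warning("%s: empty regulatory file", path)
        return set()
    missing = {"regulator", "target"} - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    edges: set[EdgeRecord] = set()
    for row in frame.itertuples(index=False):
        reg, tgt = getattr(row, "regulator"), getattr(row, "target")
        if reg == tgt:
            continue
        edges.add(EdgeRecord(source=reg, target=tgt, kind=kind))
    return edges


def read_metabolite_edges(path: str | Path) -> set[EdgeRecord]:
    """Read (enzyme, metabolite, role) incidence rows.

    ``role`` must be ``substrate`` or ``product``; a pair listed under
    both roles is still a single edge.
    """
    frame = _read_table(path, sep="\t")
    if frame.empty:
        return set()
    missing = {"enzyme", "metabolite", "role"} - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    edges: set[EdgeRecord] = set()
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        role = getattr(row, "role")
        if role not in ("substrate", "product"):
            raise FormatError(f"{path}:{line_no}: unknown role {role!r}")
        edges.add(
            EdgeRecord(
                source=getattr(row, "enzyme"),
                target=getattr(row, "metabolite"),
                kind=ENZYME_METABOLITE,
            )
        )
    return edges


def build_meta_interactome(
    edge_sets: Sequence[Iterable[EdgeRecord]],
    annotations: Annotations | None = None,
) -> MetaInteractome:
    """Union the edge layers into one validated meta-interactome.

    Node kinds and flags are inferred from edge kinds (miRNA-target
    sources become miRNA nodes, TF-target sources are flagged as TFs,
    enzyme-metabolite endpoints become enzyme and metabolite nodes) and
    the optional annotation tables add signaling / metabolic /
    crosstalk / rate-limiting flags.  Merging is order-independent; an
    identifier used with two incompatible kinds raises ``FormatError``.
    """
    net = MetaInteractome()
    # deterministic insertion regardless of input ordering
    all_edges = sorted(
        (e for edge_set in edge_sets for e in edge_set), key=lambda e: e.key
    )
    for edge in all_edges:
        if edge.kind == MIRNA_TARGET:
            net.add_node(NodeRecord(id=edge.source, kind=MIRNA))
            net.add_node(NodeRecord(id=edge.target, kind=PROTEIN))
        elif edge.kind == TF_TARGET:
            net.add_node(NodeRecord(id=edge.source, kind=PROTEIN, is_tf=True))
            net.add_node(NodeRecord(id=edge.target, kind=PROTEIN))
        elif edge.kind == ENZYME_METABOLITE:
            net.add_node(
                NodeRecord(
                    id=edge.source, kind=PROTEIN, is_metabolic_enzyme=True
                )
            )
            net.add_node(NodeRecord(id=edge.target, kind=METABOLITE))
        net.add_edge(edge)
    if annotations is not None:
        for node_id in sorted(
            annotations.signaling
            | annotations.metabolic_enzymes
            | annotations.crosstalk
            | annotations.rate_limiting
        ):
            record = net.nodes.get(node_id)
            if record is None or record.kind != PROTEIN:
                continue
            net.nodes[node_id] = replace(
                record,
                is_signaling=record.is_signaling
                or node_id in annotations.signaling,
                is_metabolic_enzyme=record.is_metabolic_enzyme
                or node_id in annotations.metabolic_enzymes,
                is_crosstalk=record.is_crosstalk
                or node_id in annotations.crosstalk,
                is_rate_limiting=record.is_rate_limiting
                or node_id in annotations.rate_limiting,
            )
    return net
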