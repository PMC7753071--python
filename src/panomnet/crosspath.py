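"""Cross-pathway path discovery and probabilistic scoring.

This module connects regulatory entry points X — signaling proteins, or
target genes of deregulated TFs / miRNAs — to metabolic enzymes M
through at most three protein--protein interactors P, giving four path
grammars: XM, XPM, XPPM, XPPPM.  Candidate paths are filtered on omics
status (both terminals deregulated, every interior node at least
expressed), then scored with a hidden-Markov-style log-likelihood:

    PS(path) = sum_edges log t(u -> v) + sum_nodes log e(v)

* transition ``t(u -> v)`` is the normalized interaction probability:
  the product of the endpoints' expression scores s(u)·s(v), divided by
  the same product summed over all of u's expressed-or-deregulated
  network neighbors (so outgoing probabilities from each node sum to 1
  over eligible neighbors).  The expression score is
  s(v) = 1 + |combined normalized logFC(v)|, i.e. 1 for merely
  expressed nodes and up to 1 + k for strongly deregulated ones.
* emission ``e(v)`` folds in node importance: a count of satisfied
  weight options (deregulated gene, crosstalk gene, rate-limiting
  enzyme, hub, central node, bottleneck; at most four selectable) and,
  optionally, the node's local network entropy rescaled by the network
  maximum:

      e(v) = (1 + w(v) + [entropy] * H(v)/H_max) / (2 + |options|).

Path scores are standardized to z-scores across the run's filtered
paths and paths with z >= 1 (inclusive) are reported as important
cross-pathway links.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import (
    MIRNA_TARGET,
    PPI,
    TF_TARGET,
    MetaInteractome,
)
from .omics import ABSENT, DOWN, EXPRESSED, UP, DeregulationTable

logger = logging.getLogger(__name__)

SIGNALING_TO_METABOLIC = "signaling_to_metabolic"
TF_TO_METABOLIC = "tf_to_metabolic"
MIRNA_TO_METABOLIC = "mirna_to_metabolic"
MODES = (SIGNALING_TO_METABOLIC, TF_TO_METABOLIC, MIRNA_TO_METABOLIC)

WEIGHT_OPTIONS = (
    "deregulated_gene",
    "crosstalk_gene",
    "rate_limiting_enzyme",
    "hub",
    "central_node",
    "bottleneck",
)
NETWORK_OPTIONS = frozenset({"hub", "central_node", "bottleneck"})

PATH_TYPES = {0: "XM", 1: "XPM", 2: "XPPM", 3: "XPPPM"}

#: statuses that make a node an eligible path member at all
_ELIGIBLE = frozenset({UP, DOWN, EXPRESSED})


@dataclass(frozen=True)
class WeightConfig:
    """Selected node-weight options (at most four of the six)."""

    options: frozenset[str] = frozenset({"deregulated_gene"})
    use_entropy: bool = False

    def __post_init__(self) -> None:
        unknown = self.options - set(WEIGHT_OPTIONS)
        if unknown:
            raise ValueError(f"unknown weight option(s) {sorted(unknown)}")
        if not self.options:
            raise ValueError("select at least one weight option")
        if len(self.options) > 4:
            raise ValueError("at most four weight options may be selected")


@dataclass(frozen=True)
class CandidatePath:
    """One X->M path, optionally prefixed by its TF/miRNA regulator."""

    mode: str
    nodes: tuple[str, ...]
    regulator: str | None = None
    node_weights: tuple[int, ...] = ()
    transition_probs: tuple[float, ...] = ()
    path_score: float = math.nan
    z: float = math.nan
    important: bool = False

    @property
    def path_type(self) -> str:
        return PATH_TYPES[len(self.nodes) - 2]

    @property
    def full_nodes(self) -> tuple[str, ...]:
        """Node sequence including the regulator prefix when present."""
        if self.regulator is None:
            return self.nodes
        return (self.regulator,) + self.nodes

    @property
    def terminals(self) -> tuple[str, str]:
        return (self.full_nodes[0], self.nodes[-1])

    @property
    def signature(self) -> tuple:
        return (self.regulator, self.nodes)


def _entry_points(
    meta: MetaInteractome,
    mode: str,
    table: DeregulationTable | None,
) -> dict[str, str | None]:
    """Map X node -> regulator (None in signaling mode)."""
    if mode == SIGNALING_TO_METABOLIC:
        xs = {
            n: None
            for n, r in meta.nodes.items()
            if r.kind == "protein" and r.is_signaling
        }
        if not xs:
            raise ValueError("network has no signaling proteins")
        return xs
    edge_kind = TF_TARGET if mode == TF_TO_METABOLIC else MIRNA_TARGET
    xs: dict[str, set[str]] = {}
    for (src, tgt, kind) in meta.edges:
        if kind != edge_kind:
            continue
        if table is not None and not table.is_deregulated(src):
            continue
        xs.setdefault(tgt, set()).add(src)
    if not xs:
        raise ValueError(
            "no deregulated regulators with targets for mode "
            f"{mode!r}"
        )
    return xs


def enumerate_paths(
    meta: MetaInteractome,
    mode: str,
    table: DeregulationTable | None = None,
    max_intermediates: int = 3,
) -> list[CandidatePath]:
    """All simple X->M paths through <= ``max_intermediates`` PPI hops.

    X nodes are signaling proteins (signaling mode) or targets of
    deregulated TFs / miRNAs (regulatory modes, the regulator is
    recorded as a prefix and one path is emitted per regulator).  The
    terminal M is any metabolic enzyme distinct from X.  Output is
    lexicographically ordered by (regulator, node sequence).
    """
    if mode not in MODES:
        raise ValueError(f"unknown connectivity mode {mode!r}")
    if not any(
        r.is_metabolic_enzyme for r in meta.nodes.values()
    ):
        raise ValueError("network has no metabolic enzymes")
    entry = _entry_points(meta, mode, table)
    max_edges = max_intermediates + 1
    paths: list[CandidatePath] = []
    for x in sorted(entry):
        # depth-first over PPI edges, tracking the simple-path stack
        stack: list[tuple[str, ...]] = [(x,)]
        found: list[tuple[str, ...]] = []
        while stack:
            current = stack.pop()
            tail = current[-1]
            if (
                len(current) >= 2
                and meta.nodes[tail].is_metabolic_enzyme
            ):
                found.append(current)
            if len(current) > max_edges:
                continue
            for nxt in sorted(meta.neighbors(tail, PPI), reverse=True):
                if nxt not in current:
                    stack.append(current + (nxt,))
        for nodes in found:
            regulators = entry[x]
            if regulators is None:
                paths.append(CandidatePath(mode=mode, nodes=nodes))
            else:
                for reg in sorted(regulators):
                    paths.append(
                        CandidatePath(mode=mode, nodes=nodes, regulator=reg)
                    )
    paths.sort(key=lambda p: (p.regulator or "", p.nodes))
    return paths


def filter_paths(
    paths: Sequence[CandidatePath], table: DeregulationTable
) -> list[CandidatePath]:
    """Keep paths with deregulated terminals and expressed interiors.

    Terminals are the first node of the full sequence (the regulator in
    TF/miRNA modes, the signaling protein otherwise) and the metabolic
    enzyme; every other node must carry primary-omics coverage (status
    up, down or expressed).
    """
    kept: list[CandidatePath] = []
    for path in paths:
        first, last = path.terminals
        if not (table.is_deregulated(first) and table.is_deregulated(last)):
            continue
        interior = [n for n in path.full_nodes if n not in (first, last)]
        if all(table.status(n) in _ELIGIBLE for n in interior):
            kept.append(path)
    if not kept:
        logger.info("no paths survive the deregulation filter")
    return kept


def expression_score(node: str, table: DeregulationTable) -> float:
    """s(v) = 1 + |combined normalized logFC|; expressed nodes score 1."""
    if table.status(node) == ABSENT:
        raise ValueError(f"node {node!r} absent from primary omics data")
    return 1.0 + abs(table.combined_score(node))


def _eligible_neighbors(
    meta: MetaInteractome, node: str, kind: str, table: DeregulationTable
) -> list[str]:
    if kind in (TF_TARGET, MIRNA_TARGET):
        pool = meta.successors(node, kind)
    else:
        pool = meta.neighbors(node, PPI)
    return sorted(u for u in pool if table.status(u) in _ELIGIBLE)


def transition_probabilities(
    path: CandidatePath,
    table: DeregulationTable,
    meta: MetaInteractome,
) -> tuple[float, ...]:
    """Per-step normalized interaction probabilities along the path.

    For a PPI step u->v the probability is s(u)s(v) normalized over u's
    eligible PPI neighbors; for the regulator->X step the normalization
    runs over the regulator's eligible targets.  Each node's outgoing
    probabilities therefore sum to 1 over its eligible neighbors.
    """
    full = path.full_nodes
    probs: list[float] = []
    for i, (u, v) in enumerate(zip(full[:-1], full[1:])):
        if path.regulator is not None and i == 0:
            kind = TF_TARGET if path.mode == TF_TO_METABOLIC else MIRNA_TARGET
        else:
            kind = PPI
        neighbors = _eligible_neighbors(meta, u, kind, table)
        denom = sum(
            expression_score(u, table) * expression_score(w, table)
            for w in neighbors
        )
        if denom <= 0 or v not in neighbors:
            raise ValueError(
                f"no eligible transition mass from {u!r} to {v!r}"
            )
        probs.append(
            expression_score(u, table) * expression_score(v, table) / denom
        )
    return tuple(probs)


def local_entropy(
    node: str, meta: MetaInteractome, table: DeregulationTable
) -> float:
    """Shannon entropy of the node's eligible-neighbor weight profile.

    Edge weights are products of endpoint expression scores; uniform
    weights over k neighbors give log k, a single neighbor gives 0.
    """
    neighbors = _eligible_neighbors(meta, node, PPI, table)
    if not neighbors:
        return 0.0
    weights = np.array(
        [
            expression_score(node, table) * expression_score(u, table)
            for u in neighbors
        ]
    )
    p = weights / weights.sum()
    return float(-(p * np.log(p)).sum())


def node_weight(
    node: str,
    config: WeightConfig,
    meta: MetaInteractome,
    table: DeregulationTable,
    report: pd.DataFrame | None = None,
) -> int:
    """Count of satisfied selected weight options for one node."""
    if config.options & NETWORK_OPTIONS and report is None:
        raise ValueError(
            "network weight options require a topology report"
        )
    record = meta.nodes[node]
    weight = 0
    for option in config.options:
        if option == "deregulated_gene":
            weight += table.is_deregulated(node)
        elif option == "crosstalk_gene":
            weight += record.is_crosstalk
        elif option == "rate_limiting_enzyme":
            weight += record.is_rate_limiting
        elif option == "hub":
            weight += node in report.index and bool(
                report.loc[node, "is_hub"]
            )
        elif option == "central_node":
            weight += node in report.index and bool(
                report.loc[node, "is_central"]
            )
        elif option == "bottleneck":
            weight += node in report.index and bool(
                report.loc[node, "is_bottleneck"]
            )
    return int(weight)


def _max_entropy(
    meta: MetaInteractome, table: DeregulationTable
) -> float:
    best = 0.0
    for node in meta.nodes:
        if table.status(node) in _ELIGIBLE:
            best = max(best, local_entropy(node, meta, table))
    return best


def path_score(
    path: CandidatePath,
    config: WeightConfig,
    meta: MetaInteractome,
    table: DeregulationTable,
    report: pd.DataFrame | None = None,
    h_max: float | None = None,
) -> CandidatePath:
    """Attach weights, transition probabilities and the HMM-style score.

    PS = sum of log transition probabilities + sum of log emissions,
    with emission e(v) = (1 + w(v) + entropy term) / (2 + |options|) so
    that 0 < e(v) <= 1 and the score is finite for every valid path.
    Higher scores mean more probable, more important paths.
    """
    probs = transition_probabilities(path, table, meta)
    if h_max is None and config.use_entropy:
        h_max = _max_entropy(meta, table)
    weights = []
    log_emission = 0.0
    denom = 2.0 + len(config.options)
    for node in path.full_nodes:
        w = node_weight(node, config, meta, table, report)
        weights.append(w)
        numer = 1.0 + w
        if config.use_entropy and h_max and h_max > 0:
            numer += local_entropy(node, meta, table) / h_max
        emission = numer / denom
        if emission <= 0:
            raise ValueError("zero emission probability")
        log_emission += math.log(emission)
    score = sum(math.log(p) for p in probs) + log_emission
    return replace(
        path,
        node_weights=tuple(weights),
        transition_probs=probs,
        path_score=score,
    )


def score_paths(
    paths: Sequence[CandidatePath],
    config: WeightConfig,
    meta: MetaInteractome,
    table: DeregulationTable,
    report: pd.DataFrame | None = None,
) -> list[CandidatePath]:
    """Score every filtered path, sharing the entropy normalizer."""
    h_max = _max_entropy(meta, table) if config.use_entropy else None
    return [
        path_score(p, config, meta, table, report, h_max=h_max)
        for p in paths
    ]


def select_important(
    paths: Sequence[CandidatePath], z_threshold: float = 1.0
) -> list[CandidatePath]:
    """Standardize path scores and flag z >= threshold (inclusive).

    Output is sorted by z descending (ties by node sequence); requires
    at least two distinct scores for the z-distribution to exist.
    """
    if len(paths) < 2:
        raise ValueError("need at least two scored paths for z-selection")
    scores = np.array([p.path_score for p in paths], dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate score distribution")
    zs = (scores - scores.mean()) / sd
    out = [
        replace(p, z=float(z), important=bool(z >= z_threshold))
        for p, z in zip(paths, zs)
    ]
    out.sort(key=lambda p: (-p.z, p.regulator or "", p.nodes))
    return out


def path_overlap(
    named_runs: Mapping[str, Sequence[CandidatePath]],
) -> dict[str, int]:
    """Venn region counts over path signatures across 2-3 runs."""
    modes = {
        p.mode for run in named_runs.values() for p in run
    }
    if len(modes) > 1:
        raise ValueError("cannot overlap runs of different modes")
    from .topology import overlap_report

    return overlap_report(
        {k: {p.signature for p in v} for k, v in named_runs.items()}
    )


def paths_frame(
    paths: Sequence[CandidatePath], meta: MetaInteractome | None = None
) -> pd.DataFrame:
    """Tabular view of scored paths (one row per path).

    When the meta-interactome is supplied the metabolites attached to
    each terminal enzyme are listed alongside.
    """
    rows = []
    for p in paths:
        row = {
            "type": p.path_type,
            "regulator": p.regulator or "",
            "nodes": "->".join(p.nodes),
            "path_score": p.path_score,
            "z": p.z,
            "important": p.important,
        }
        if meta is not None:
            row["metabolites"] = ";".join(
                sorted(meta.neighbors(p.nodes[-1], "enzyme_metabolite"))
            )
        rows.append(row)
    return pd.DataFrame(rows)
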