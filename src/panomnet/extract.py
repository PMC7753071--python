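"""Context-specific ("filtered") network extraction.

The filtered network is the induced subgraph of the meta-interactome on
the deregulated/altered seed nodes plus everything within one or two
hops of a seed.  Expansion crosses every edge layer and traverses
regulatory edges in both directions, so a deregulated target pulls in
its upstream TFs and miRNAs; this is configurable via ``undirected``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from .interactome import ENZYME_METABOLITE, METABOLITE, MetaInteractome
from .omics import DeregulationTable


@dataclass
class FilteredNetwork:
    """Induced subgraph around the omics-derived seed set."""

    network: MetaInteractome
    seeds: frozenset[str]
    level: int
    statuses: dict[str, str] = field(default_factory=dict)

    @property
    def node_ids(self) -> set[str]:
        return set(self.network.nodes)

    def to_json(self) -> str:
        """Viewer export: the graph JSON plus per-node status colors."""
        payload = json.loads(self.network.to_json())
        status_color = {
            "up": "#d62728",
            "down": "#1f77b4",
            "altered": "#9467bd",
            "expressed": "#7f7f7f",
            "absent": "#c7c7c7",
        }
        for node in payload["nodes"]:
            status = self.statuses.get(node["id"], "absent")
            node["status"] = status
            node["color"] = status_color[status]
            node["is_seed"] = node["id"] in self.seeds
        payload["level"] = self.level
        return json.dumps(payload, indent=1, sort_keys=True)


def _expand(
    meta: MetaInteractome, seeds: set[str], level: int
) -> set[str]:
    reached = set(seeds)
    frontier = set(seeds)
    for _ in range(level):
        nxt: set[str] = set()
        for node in frontier:
            nxt |= meta.neighbors(node)
        frontier = nxt - reached
        reached |= frontier
    return reached


def extract_filtered_network(
    meta: MetaInteractome,
    table: DeregulationTable,
    level: int = 1,
) -> FilteredNetwork:
    """Extract the subnetwork of deregulated/altered nodes + interactors.

    Seeds are the table's up/down/altered identifiers that map onto the
    meta-interactome; the result is the induced subgraph on seeds plus
    all nodes within ``level`` (1 or 2) hops across any edge layer.
    """
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    seeds = table.deregulated_or_altered() & set(meta.nodes)
    if not seeds:
        raise ValueError(
            "no deregulated/altered nodes map to the meta-interactome"
        )
    reached = _expand(meta, seeds, level)
    sub = meta.subgraph(reached)
    statuses = {n: table.status(n) for n in sub.nodes}
    return FilteredNetwork(
        network=sub, seeds=frozenset(seeds), level=level, statuses=statuses
    )


def metabolites_to_enzyme_network(
    meta: MetaInteractome,
    metabolite_ids: Iterable[str],
) -> FilteredNetwork:
    """Seed from metabolomics: enzymes touching any listed metabolite.

    Every enzyme incident to a listed metabolite becomes a seed; the
    seeds are expanded one protein hop, and the listed metabolites stay
    attached as leaves of the extracted network.
    """
    listed = set(metabolite_ids) & meta.nodes_of_kind(METABOLITE)
    enzymes: set[str] = set()
    for met in listed:
        enzymes |= meta.neighbors(met, ENZYME_METABOLITE)
    if not enzymes:
        raise ValueError("no listed metabolite maps to an enzyme")
    expanded = _expand(meta, enzymes, 1)
    # expansion is protein-level: unlisted metabolites are not pulled in
    reached = {
        n for n in expanded if meta.nodes[n].kind != METABOLITE
    } | listed
    sub = meta.subgraph(reached)
    statuses = {
        n: ("altered" if n in enzymes or n in listed else "expressed")
        for n in sub.nodes
    }
    return FilteredNetwork(
        network=sub, seeds=frozenset(enzymes), level=1, statuses=statuses
    )
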