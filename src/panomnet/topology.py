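"""Topology indices, z-scoring, and selection of important nodes.

Four classical node indices are computed on the undirected projection of
the filtered network: degree, betweenness, closeness and clustering
coefficient.  Each index x is rescaled by its network maximum,

    x_normalized(i) = x(i) / x_maximum,

and converted to a z-score over the candidate node set (sample standard
deviation, ddof=1).  Three families of topologically important nodes
(TINs) are selected by strict z-thresholds:

* hubs            -- z-scored degree,
* bottlenecks     -- z-scored betweenness,
* central nodes   -- z-scored cumulative centrality score (CCS), where
  CCS(i) is the node's combined score c(i) = normalized betweenness +
  normalized closeness + normalized clustering plus the sum of c over
  its first-layer interactors.

Nodes selected by at least two of the three families are important
interacting nodes (IINs).  Candidates are restricted to nodes covered
by the omics data (expressed or deregulated for transcriptomics /
proteomics runs; altered nodes for alteration-driven runs); metabolite
nodes are never candidates.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .extract import FilteredNetwork, extract_filtered_network
from .interactome import METABOLITE
from .omics import ALTERED, DOWN, EXPRESSED, UP, DeregulationTable

logger = logging.getLogger(__name__)


def candidate_nodes(
    network: FilteredNetwork,
    table: DeregulationTable,
    driven_by: str = "primary",
) -> set[str]:
    """Nodes eligible for TIN selection.

    ``driven_by="primary"`` (transcriptomics/proteomics/miRNA runs)
    admits nodes the omics data covers: status up, down or expressed.
    ``driven_by="alteration"`` admits altered nodes, and
    ``driven_by="metabolomics"`` the seeded enzymes.  Metabolite nodes
    are excluded always.
    """
    if driven_by == "primary":
        allowed = {UP, DOWN, EXPRESSED}
        pool = {n for n in network.node_ids if table.status(n) in allowed}
    elif driven_by == "alteration":
        pool = {n for n in network.node_ids if table.status(n) == ALTERED}
    elif driven_by == "metabolomics":
        pool = set(network.seeds) & network.node_ids
    else:
        raise ValueError(f"unknown run kind {driven_by!r}")
    pool = {
        n
        for n in pool
        if network.network.nodes[n].kind != METABOLITE
    }
    if not pool:
        raise ValueError("no candidate nodes for topology analysis")
    return pool


def compute_centralities(
    graph: nx.Graph,
) -> pd.DataFrame:
    """Degree, betweenness, closeness and clustering per node.

    Betweenness is normalized by (N-1)(N-2)/2; closeness uses the
    component-scaled (Wasserman--Faust) form so values are comparable
    across disconnected components; isolated nodes get closeness and
    clustering 0.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least two nodes")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    clustering = nx.clustering(graph)
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "degree": [float(degree[n]) for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def normalize_index(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Rescale an index by its maximum so the top node scores 1."""
    series = pd.Series(values, dtype=float)
    max_value = series.max()
    if max_value <= 0:
        raise ValueError("index maximum must be positive to normalize")
    return series / max_value


def _safe_normalize(series: pd.Series) -> pd.Series:
    """Max-rescale, mapping an all-zero index to zeros instead of failing."""
    max_value = series.max()
    if max_value <= 0:
        return series * 0.0
    return series / max_value


def to_zscores(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Standardize with sample SD (ddof=1); constant input is an error."""
    series = pd.Series(values, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least two values for z-scores")
    sd = series.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "degenerate distribution; threshold selection impossible"
        )
    return (series - series.mean()) / sd


def pdf_plot_data(
    z_values: Sequence[float] | pd.Series, bins: int = 20
) -> pd.DataFrame:
    """Density histogram of z-scores as (bin_center, density) rows.

    This table (and the optional matplotlib rendering in the CLI) is
    what a user inspects to choose the selection thresholds.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    arr = np.asarray(z_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to histogram")
    density, edges = np.histogram(arr, bins=bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"bin_center": centers, "density": density})


def save_pdf_plot(hist: pd.DataFrame, path) -> None:
    """Render a z-score density histogram table to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    width = (
        hist["bin_center"].iloc[1] - hist["bin_center"].iloc[0]
        if len(hist) > 1
        else 0.5
    )
    ax.bar(hist["bin_center"], hist["density"], width=width * 0.95)
    ax.set_xlabel("z-score")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def select_by_z(z: pd.Series, z_threshold: float) -> set[str]:
    """Strictly-greater selection on a z-scored index."""
    selected = set(z.index[z > z_threshold])
    if not selected:
        logger.info("no nodes exceed z > %s", z_threshold)
    return selected


def select_hubs(z_degree: pd.Series, z_threshold: float = 1.0) -> set[str]:
    return select_by_z(z_degree, z_threshold)


def select_bottlenecks(
    z_betweenness: pd.Series, z_threshold: float = 1.0
) -> set[str]:
    return select_by_z(z_betweenness, z_threshold)


def compute_ccs(
    graph: nx.Graph, centralities: pd.DataFrame
) -> pd.Series:
    """Cumulative centrality score: own combined score + neighbor sum.

    The combined score c(i) sums the max-rescaled betweenness,
    closeness and clustering of node i; CCS(i) = c(i) + sum of c(j)
    over i's neighbors, so a node is central when it and its immediate
    neighborhood carry centrality mass.  An index that is uniformly
    zero (e.g. clustering in a tree) contributes zeros.
    """
    combined = (
        _safe_normalize(centralities["betweenness"])
        + _safe_normalize(centralities["closeness"])
        + _safe_normalize(centralities["clustering"])
    )
    ccs = {}
    for node in centralities.index:
        ccs[node] = combined[node] + sum(
            combined[nb] for nb in graph.neighbors(node)
        )
    return pd.Series(ccs, name="ccs").loc[centralities.index]


def identify_iins(flags: pd.DataFrame) -> set[str]:
    """Nodes satisfying >= 2 of the hub / central / bottleneck flags."""
    count = (
        flags["is_hub"].astype(int)
        + flags["is_central"].astype(int)
        + flags["is_bottleneck"].astype(int)
    )
    return set(flags.index[count >= 2])


def analyze_topology(
    network: FilteredNetwork,
    table: DeregulationTable,
    z_hub: float = 1.0,
    z_cn: float = 1.0,
    z_bn: float = 1.0,
    driven_by: str = "primary",
) -> pd.DataFrame:
    """Full topology report: indices, z-scores, and TIN/IIN flags.

    Centralities and CCS are computed on the whole undirected
    projection of the filtered network; z-scores and selections are
    restricted to the candidate nodes.  Returns one row per network
    node; z columns are NaN outside the candidate set.
    """
    graph = network.network.to_networkx(
        kinds=("ppi", "mirna_target", "tf_target", "enzyme_metabolite")
    )
    cents = compute_centralities(graph)
    ccs = compute_ccs(graph, cents)
    candidates = sorted(candidate_nodes(network, table, driven_by))

    report = cents.copy()
    report["ccs"] = ccs
    report["is_candidate"] = report.index.isin(candidates)

    for z_col, source in (
        ("z_degree", "degree"),
        ("z_ccs", "ccs"),
        ("z_betweenness", "betweenness"),
    ):
        sub = report.loc[candidates, source]
        normalized = _safe_normalize(sub)
        report[z_col] = to_zscores(normalized).reindex(report.index)

    hubs = select_hubs(report.loc[candidates, "z_degree"], z_hub)
    centrals = select_by_z(report.loc[candidates, "z_ccs"], z_cn)
    bottlenecks = select_bottlenecks(
        report.loc[candidates, "z_betweenness"], z_bn
    )
    report["is_hub"] = report.index.isin(hubs)
    report["is_central"] = report.index.isin(centrals)
    report["is_bottleneck"] = report.index.isin(bottlenecks)
    report["is_iin"] = report.index.isin(identify_iins(report))
    return report


def tin_subnetwork(
    network: FilteredNetwork,
    tins: Iterable[str],
    level: int = 1,
) -> FilteredNetwork:
    """Subnetwork of the TINs and their 1st/2nd-layer interactors."""
    seeds = set(tins) & network.node_ids
    if not seeds:
        raise ValueError("empty TIN seed set")
    pseudo = DeregulationTable(
        statuses={n: UP for n in seeds}
    )
    sub = extract_filtered_network(network.network, pseudo, level=level)
    sub.statuses = {n: network.statuses.get(n, "absent") for n in sub.node_ids}
    return sub


def overlap_report(
    named_sets: Mapping[str, Iterable[str]],
) -> dict[str, int]:
    """Venn region cardinalities for 2 or 3 labelled sets.

    Keys are '&'-joined sorted label combinations; each element of the
    union is counted in exactly one region.
    """
    labels = sorted(named_sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("overlap report supports 2 or 3 sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[k] for k in combo))
            outside = set.union(
                *(sets[k] for k in labels if k not in combo), set()
            )
            regions["&".join(combo)] = len(inside - outside)
    return regions
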