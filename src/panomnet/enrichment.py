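"""Pathway enrichment of important nodes and annotation joins.

Gene sets are read from GMT files whose description field carries a
class token (signaling / metabolic / cancer / other).  For a query list
of b genes against a pathway of c genes drawn from a universe of d
pathway genes, with a genes of the query inside the pathway, two
hypergeometric statistics are available:

* ``point`` -- the single-table probability

      p = C(b, a) * C(d, c) / C(b + d, a + c),

* ``tail`` (default) -- the standard one-sided over-representation
  (Fisher-exact) p-value P[overlap >= a] under the hypergeometric law
  with population d, successes c and draws b.

Pathways with p <= 0.05 are selected (raw p by default; an optional
Benjamini--Hochberg correction is available).  Selected pathways and
their member TINs form a bipartite network for export, and nodes can be
joined against a survival-derived prognostic-marker table, reporting
for each gene the cancer type with the smallest p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

PATHWAY_CLASSES = ("signaling", "metabolic", "cancer", "other")


@dataclass(frozen=True)
class Pathway:
    name: str
    pathway_class: str
    members: frozenset[str]


@dataclass
class PathwayDB:
    """Gene-set collection; the universe is the union of all members."""

    pathways: list[Pathway] = field(default_factory=list)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    pathway_class: str
    a: int  #: query genes inside the pathway
    b: int  #: query list size
    c: int  #: pathway size
    d: int  #: universe size
    p_point: float
    p_tail: float
    p_selected_on: float
    selected: bool


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT file; field 2 carries the pathway class token."""
    db = PathwayDB()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs >= 3 fields"
                )
            name, desc = fields[0], fields[1]
            cls = desc.strip().lower()
            if cls not in PATHWAY_CLASSES:
                cls = "other"
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{line_no}: empty member list")
            db.pathways.append(
                Pathway(name=name, pathway_class=cls, members=members)
            )
    return db


def _check_counts(a: int, b: int, c: int, d: int) -> None:
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not isinstance(v, (int,)) or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if a > b:
        raise ValueError("need a <= b")
    if c > d:
        raise ValueError("need c <= d")


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_point(a: int, b: int, c: int, d: int) -> float:
    """Single-table hypergeometric probability, in log space.

    Exactly C(b,a) * C(d,c) / C(b+d, a+c).
    """
    _check_counts(a, b, c, d)
    if a + c > b + d:
        raise ValueError("need a + c <= b + d")
    log_p = (
        _log_comb(b, a) + _log_comb(d, c) - _log_comb(b + d, a + c)
    )
    return float(math.exp(log_p))


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided over-representation p-value, P[overlap >= a].

    Orientation: the universe of d pathway genes is the population, the
    pathway's c genes are the successes, and the b query genes are the
    draws.  Requires b <= d and a <= c (draws from within the
    universe); queries containing out-of-universe genes should be
    intersected with the universe before calling.
    """
    _check_counts(a, b, c, d)
    if b > d:
        raise ValueError("tail statistic needs draws b <= population d")
    if a > c:
        raise ValueError("overlap a cannot exceed pathway size c")
    return float(hypergeom.sf(a - 1, d, c, b))


def enrich(
    query: Iterable[str],
    db: PathwayDB,
    statistic: str = "tail",
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Score every pathway overlapping the query; select at p <= alpha.

    ``statistic`` picks the selection p-value: ``tail`` (default
    Fisher-exact over-representation) or ``point`` (single-table
    probability).  Results are sorted by ascending selection p, ties by
    pathway name.  Selection uses raw p-values unless ``bh_correct``
    applies a Benjamini--Hochberg adjustment first.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene set")
    if statistic not in ("tail", "point"):
        raise ValueError("statistic must be 'tail' or 'point'")
    universe = db.universe
    d = len(universe)
    b = len(query_set)
    b_in = len(query_set & universe)
    results: list[EnrichmentResult] = []
    for pw in db.pathways:
        a = len(query_set & pw.members)
        if a == 0:
            continue
        c = len(pw.members)
        p_point = hypergeom_point(a, b, c, d)
        # the tail is computed within the universe (draws <= population)
        p_tail = hypergeom_tail(a, b_in, c, d)
        results.append(
            EnrichmentResult(
                pathway=pw.name,
                pathway_class=pw.pathway_class,
                a=a,
                b=b,
                c=c,
                d=d,
                p_point=p_point,
                p_tail=p_tail,
                p_selected_on=p_tail if statistic == "tail" else p_point,
                selected=False,
            )
        )
    results.sort(key=lambda r: (r.p_selected_on, r.pathway))
    p_for_selection = [r.p_selected_on for r in results]
    if bh_correct and results:
        m = len(results)
        adjusted = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p_for_selection[rank - 1] * m / rank)
            adjusted[rank - 1] = running
        p_for_selection = adjusted
    final: list[EnrichmentResult] = []
    for r, p_sel in zip(results, p_for_selection):
        final.append(
            EnrichmentResult(
                **{
                    **r.__dict__,
                    "selected": p_sel <= alpha,
                }
            )
        )
    return final


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def tin_pathway_network(
    tins: Iterable[str], results: Sequence[EnrichmentResult], db: PathwayDB
) -> dict:
    """Bipartite TIN <-> selected-pathway graph as a JSON-able dict."""
    members = {p.name: p.members for p in db.pathways}
    tin_set = set(tins)
    edges = []
    for r in results:
        if not r.selected:
            continue
        for gene in sorted(tin_set & members[r.pathway]):
            edges.append({"tin": gene, "pathway": r.pathway})
    used_tins = sorted({e["tin"] for e in edges})
    used_pathways = sorted(
        {r.pathway for r in results if r.selected}
    )
    return {
        "tins": used_tins,
        "pathways": [
            {
                "name": name,
                "class": next(
                    r.pathway_class for r in results if r.pathway == name
                ),
            }
            for name in used_pathways
        ],
        "edges": sorted(edges, key=lambda e: (e["tin"], e["pathway"])),
    }


def read_prognostic_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "cancer_type", "direction", "p"} - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    p = pd.to_numeric(frame["p"], errors="coerce")
    if p.isna().any():
        bad = int(p.isna().sum())
        raise ValueError(f"{path}: {bad} row(s) with malformed p-value")
    frame = frame.assign(p=p)
    if not frame["direction"].isin(["favorable", "unfavorable"]).all():
        raise ValueError(f"{path}: direction must be favorable|unfavorable")
    return frame


def annotate_prognostic(
    nodes: Iterable[str], marker_table: pd.DataFrame
) -> dict[str, dict]:
    """Best (minimum-p) prognostic annotation per node.

    The full per-gene row list is retained under ``all`` so secondary
    cancer types remain inspectable.
    """
    out: dict[str, dict] = {}
    grouped = marker_table.groupby("gene")
    for node in nodes:
        if node not in grouped.groups:
            continue
        rows = grouped.get_group(node).sort_values(
            ["p", "cancer_type"], kind="stable"
        )
        best = rows.iloc[0]
        out[node] = {
            "cancer_type": best["cancer_type"],
            "direction": best["direction"],
            "p": float(best["p"]),
            "all": rows[["cancer_type", "direction", "p"]].to_dict(
                "records"
            ),
        }
    return out


def cancer_pathway_fraction(
    results: Sequence[EnrichmentResult],
) -> float:
    """Fraction of the selected pathways carrying the cancer class."""
    selected = [r for r in results if r.selected]
    if not selected:
        logger.warning("no pathways selected; cancer fraction is 0")
        return 0.0
    n_cancer = sum(r.pathway_class == "cancer" for r in selected)
    return n_cancer / len(selected)
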