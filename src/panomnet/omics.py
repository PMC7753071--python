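"""Per-layer omics parsing and harmonization into deregulation calls.

Seven layers are supported.  The *primary* layers (mRNA transcriptomics,
miRNA transcriptomics, proteomics) are quantitative: each record carries
a log fold-change and an adjusted p-value, and these layers alone decide
whether a node is deregulated.  The *alteration* layers
(phosphoproteomics, genomics, epigenomics) are identifier lists of
phosphorylated / mutated / methylated entities, and metabolomics is a
list of detected metabolites.

Within each uploaded quantitative table the log fold-changes are
rescaled to [-1, +1] by dividing by the table's maximum absolute value,

    logFC_normalized(i) = logFC(i) / max_j |logFC(j)|,

so positive values mean up- and negative values down-regulation.  When
several primary layers cover the same node the normalized values of its
threshold-passing records are summed; a non-zero sum calls the node
deregulated (up or down by sign), a node covered by primary data but
never passing thresholds is merely *expressed*, and a node absent from
every primary layer is *absent* and excluded downstream regardless of
any alteration-layer evidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MRNA = "mrna"
MIRNA_LAYER = "mirna"
PROTEOMICS = "proteomics"
PHOSPHO = "phospho"
GENOMICS = "genomics"
EPIGENOMICS = "epigenomics"
METABOLOMICS = "metabolomics"

PRIMARY_LAYERS = (MRNA, MIRNA_LAYER, PROTEOMICS)
ALTERATION_LAYERS = (PHOSPHO, GENOMICS, EPIGENOMICS)
ALL_LAYERS = PRIMARY_LAYERS + ALTERATION_LAYERS + (METABOLOMICS,)

UP = "up"
DOWN = "down"
EXPRESSED = "expressed"
ALTERED = "altered"
ABSENT = "absent"

#: exact-cancellation tolerance for the non-zero-sum deregulation test
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class Thresholds:
    """Per-layer deregulation cut-offs (inclusive comparisons)."""

    logfc_up: float = 1.0
    logfc_down: float = -1.0
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not self.logfc_down < 0 < self.logfc_up:
            raise ValueError("need logfc_down < 0 < logfc_up")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")


@dataclass
class OmicsProfile:
    """One parsed omics table.

    Quantitative layers hold ``records`` as a DataFrame with columns
    (id, logFC, p); alteration and metabolomics layers hold ``ids``.
    """

    layer: str
    records: pd.DataFrame | None = None
    ids: tuple[str, ...] = ()
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def is_quantitative(self) -> bool:
        return self.layer in PRIMARY_LAYERS


@dataclass
class DeregulationTable:
    """Harmonized per-node status and combined normalized logFC.

    ``combined`` maps node id -> summed normalized logFC over primary
    layers (threshold-passing records only); ``statuses`` maps node id
    -> up/down/expressed/altered; identifiers not present anywhere are
    implicitly ``absent``.  ``alterations`` records which alteration
    layers flagged each node.
    """

    statuses: dict[str, str] = field(default_factory=dict)
    combined: dict[str, float] = field(default_factory=dict)
    alterations: dict[str, set[str]] = field(default_factory=dict)

    def status(self, node_id: str) -> str:
        return self.statuses.get(node_id, ABSENT)

    def combined_score(self, node_id: str) -> float:
        return self.combined.get(node_id, 0.0)

    def is_deregulated(self, node_id: str) -> bool:
        return self.status(node_id) in (UP, DOWN)

    def deregulated_or_altered(self) -> set[str]:
        return {
            n for n, s in self.statuses.items() if s in (UP, DOWN, ALTERED)
        }

    def present(self) -> set[str]:
        """Nodes covered by primary omics data (any status but absent)."""
        return set(self.statuses)


def load_thresholds(path: str | Path) -> dict[str, Thresholds]:
    """Read per-layer thresholds from a YAML config block.

    Expected shape::

        mrna: {logfc_up: 1.0, logfc_down: -1.0, p_max: 0.05}
        proteomics: {logfc_up: 0.58, logfc_down: -0.58, p_max: 0.01}

    Layers not mentioned fall back to the defaults.
    """
    import yaml

    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    out: dict[str, Thresholds] = {}
    for layer, block in raw.items():
        if layer not in ALL_LAYERS:
            raise ValueError(f"unknown omics layer {layer!r} in {path}")
        out[layer] = Thresholds(**(block or {}))
    return out


def parse_omics_table(
    path: str | Path,
    layer: str,
    thresholds: Thresholds | None = None,
) -> OmicsProfile:
    """Parse a processed omics TSV for one layer.

    Quantitative layers expect a header ``id<TAB>logFC<TAB>p``; rows
    failing numeric parsing are skipped with a logged count, duplicate
    identifiers keep the record with the smallest p-value, and a table
    with no valid row is a hard error.  Alteration / metabolomics layers
    expect one identifier per row (header ``id`` optional).
    """
    if layer not in ALL_LAYERS:
        raise ValueError(f"unknown omics layer {layer!r}")
    thresholds = thresholds or Thresholds()
    if layer not in PRIMARY_LAYERS:
        frame = pd.read_csv(path, sep="\t", dtype=str, header=None)
        ids = [
            v
            for v in frame.iloc[:, 0].dropna().tolist()
            if v.lower() != "id"
        ]
        seen: dict[str, None] = {}
        for v in ids:
            seen.setdefault(v)
        return OmicsProfile(
            layer=layer, ids=tuple(seen), thresholds=thresholds
        )
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "logFC", "p"} - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    logfc = pd.to_numeric(frame["logFC"], errors="coerce")
    pval = pd.to_numeric(frame["p"], errors="coerce")
    valid = (
        logfc.notna()
        & pval.notna()
        & logfc.apply(math.isfinite)
        & pval.between(0.0, 1.0)
        & frame["id"].notna()
    )
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%s: skipped %d unparseable row(s)", path, n_bad)
    clean = pd.DataFrame(
        {"id": frame["id"][valid], "logFC": logfc[valid], "p": pval[valid]}
    )
    if clean.empty:
        raise ValueError(f"{path}: no valid rows")
    n_before = len(clean)
    clean = (
        clean.sort_values(["p", "id"], kind="stable")
        .drop_duplicates("id", keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    if len(clean) < n_before:
        logger.info(
            "%s: collapsed %d duplicate id(s) keeping min p",
            path,
            n_before - len(clean),
        )
    return OmicsProfile(layer=layer, records=clean, thresholds=thresholds)


def normalize_logfc(profile: OmicsProfile) -> dict[str, float]:
    """Rescale one profile's logFC values to [-1, +1].

    Divides by the maximum |logFC| within the uploaded table, so the
    extreme record maps to +/-1 and signs are preserved.  All-zero
    tables are rejected (the scale is undefined).
    """
    if not profile.is_quantitative or profile.records is None:
        raise ValueError("normalization requires a quantitative layer")
    max_abs = profile.records["logFC"].abs().max()
    if max_abs == 0:
        raise ValueError("all logFC values are zero; cannot normalize")
    return {
        row.id: row.logFC / max_abs
        for row in profile.records.itertuples(index=False)
    }


def call_layer_deregulation(profile: OmicsProfile) -> dict[str, str]:
    """Call up/down/expressed per record from raw logFC and p.

    Both cut-offs are inclusive: ``logFC >= logfc_up`` (or
    ``<= logfc_down``) *and* ``p <= p_max``.
    """
    if not profile.is_quantitative or profile.records is None:
        raise ValueError("deregulation calls require a quantitative layer")
    th = profile.thresholds
    calls: dict[str, str] = {}
    for row in profile.records.itertuples(index=False):
        if row.p <= th.p_max and row.logFC >= th.logfc_up:
            calls[row.id] = UP
        elif row.p <= th.p_max and row.logFC <= th.logfc_down:
            calls[row.id] = DOWN
        else:
            calls[row.id] = EXPRESSED
    return calls


def combine_primary(
    profiles: Sequence[OmicsProfile],
) -> DeregulationTable:
    """Sum normalized logFC across primary layers into one status table.

    Only records passing their layer's deregulation call contribute to
    the sum; the sign of the sum gives up/down, an exact cancellation
    (|sum| <= 1e-12) or no passing record leaves the node expressed.
    """
    primary = [p for p in profiles if p.layer in PRIMARY_LAYERS]
    if not primary:
        raise ValueError("at least one primary omics profile is required")
    table = DeregulationTable()
    sums: dict[str, float] = {}
    for profile in primary:
        normalized = normalize_logfc(profile)
        calls = call_layer_deregulation(profile)
        for node_id, call in calls.items():
            table.statuses.setdefault(node_id, EXPRESSED)
            if call in (UP, DOWN):
                sums[node_id] = sums.get(node_id, 0.0) + normalized[node_id]
    for node_id, total in sums.items():
        table.combined[node_id] = total
        if total > ZERO_TOL:
            table.statuses[node_id] = UP
        elif total < -ZERO_TOL:
            table.statuses[node_id] = DOWN
        else:
            table.statuses[node_id] = EXPRESSED
    return table


def mark_alterations(
    table: DeregulationTable,
    alteration_profiles: Sequence[OmicsProfile],
    network_nodes: Iterable[str] | None = None,
) -> DeregulationTable:
    """Fold alteration layers (mutation/methylation/phosphorylation) in.

    An altered identifier keeps an existing up/down call (the alteration
    is recorded as a per-layer flag); otherwise its status becomes
    ``altered``.  When ``network_nodes`` is given, identifiers outside
    the network are ignored.  In a pure alteration run (no primary
    coverage of the node) the altered status is what seeds extraction.
    """
    known = set(network_nodes) if network_nodes is not None else None
    for profile in alteration_profiles:
        if profile.layer not in ALTERATION_LAYERS:
            raise ValueError(
                f"{profile.layer!r} is not an alteration layer"
            )
        for node_id in profile.ids:
            if known is not None and node_id not in known:
                continue
            table.alterations.setdefault(node_id, set()).add(profile.layer)
            if table.statuses.get(node_id) not in (UP, DOWN):
                table.statuses[node_id] = ALTERED
    return table
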