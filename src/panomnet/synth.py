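"""Seeded synthetic data: meta-interactome, omics tables, gene sets.

Every stage of the pipeline is exercisable offline from these
generators.  The PPI layer comes from a standard random-graph model
(Barabasi--Albert by default, for a scale-free-ish degree tail;
Erdos--Renyi optionally), miRNAs and TFs are wired to random target
subsets, metabolites attach to the metabolic-enzyme subset, and omics
tables plant a known fraction of deregulated nodes with
logFC ~ Normal(+-mu, sd) and significant p-values, writing the ground
truth alongside for recovery tests.  All sampling is driven by one
integer seed through numpy's Generator, so identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome import (
    Annotations,
    EdgeRecord,
    MetaInteractome,
    build_meta_interactome,
    read_metabolite_edges,
    read_regulatory_edges,
    read_string_edges,
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic fixture.

    Sizes default to a small multi-layer network (200 proteins, 20
    miRNAs, 10 TFs, 30 metabolites) on which the complete pipeline,
    including bounded path enumeration, runs in seconds.  The planted
    deregulation signal uses |logFC| ~ Normal(2.0, 0.3) against the
    conventional cut-offs |logFC| >= 1, p <= 0.05.
    """

    n_proteins: int = 200
    n_mirnas: int = 20
    n_tfs: int = 10
    n_metabolites: int = 30
    ppi_model: str = "barabasi_albert"
    ppi_param: float = 2  # m for BA; edge probability for ER
    targets_per_regulator: int = 8
    frac_signaling: float = 0.2
    frac_metabolic: float = 0.2
    frac_crosstalk: float = 0.1
    frac_rate_limiting: float = 0.3
    frac_deregulated: float = 0.2
    logfc_mu: float = 2.0
    logfc_sd: float = 0.3
    n_pathways: int = 12
    pathway_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_mirnas", "n_tfs", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_signaling",
            "frac_metabolic",
            "frac_deregulated",
        ):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ppi_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValueError(f"unknown ppi model {self.ppi_model!r}")


def _protein_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def generate_network(
    config: SynthConfig, outdir: str | Path
) -> MetaInteractome:
    """Write the four edge tables + annotation lists; return the merged net.

    Files written (module-reader dialects): ``ppi_links.txt`` (STRING
    style, real edges score 700-999 plus ~5% decoy sub-threshold
    rows), ``mirna_targets.tsv``, ``tf_targets.tsv``,
    ``enzyme_metabolites.tsv``, ``signaling.txt``, ``crosstalk.txt``,
    ``rate_limiting.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    proteins = _protein_names(config.n_proteins)

    if config.ppi_model == "barabasi_albert":
        graph = nx.barabasi_albert_graph(
            config.n_proteins,
            int(config.ppi_param),
            seed=int(rng.integers(2**31)),
        )
    else:
        graph = nx.erdos_renyi_graph(
            config.n_proteins,
            float(config.ppi_param),
            seed=int(rng.integers(2**31)),
        )
    ppi_rows = []
    for u, v in sorted(graph.edges()):
        score = int(rng.integers(700, 1000))
        ppi_rows.append([proteins[u], proteins[v], score])
    # decoy rows below the confidence threshold exercise the filter
    n_decoy = max(1, len(ppi_rows) // 20)
    non_edges = []
    while len(non_edges) < n_decoy:
        u, v = rng.integers(0, config.n_proteins, size=2)
        if u != v and not graph.has_edge(int(u), int(v)):
            non_edges.append((int(u), int(v)))
    for u, v in non_edges:
        ppi_rows.append(
            [proteins[u], proteins[v], int(rng.integers(100, 700))]
        )
    _write_tsv(
        outdir / "ppi_links.txt",
        ["protein1", "protein2", "experimental"],
        ppi_rows,
    )

    mirnas = [f"hsa-miR-{i + 1}" for i in range(config.n_mirnas)]
    mirna_rows = []
    for m in mirnas:
        k = max(1, int(rng.integers(1, config.targets_per_regulator + 1)))
        targets = rng.choice(config.n_proteins, size=k, replace=False)
        for t in sorted(targets):
            mirna_rows.append([m, proteins[t]])
    _write_tsv(
        outdir / "mirna_targets.tsv", ["regulator", "target"], mirna_rows
    )

    tf_ids = rng.choice(config.n_proteins, size=config.n_tfs, replace=False)
    tf_rows = []
    for tf in sorted(tf_ids):
        k = max(1, int(rng.integers(1, config.targets_per_regulator + 1)))
        targets = rng.choice(config.n_proteins, size=k, replace=False)
        for t in sorted(targets):
            if t != tf:
                tf_rows.append([proteins[tf], proteins[t]])
    _write_tsv(outdir / "tf_targets.tsv", ["regulator", "target"], tf_rows)

    n_enzymes = max(2, int(config.frac_metabolic * config.n_proteins))
    enzyme_ids = sorted(
        rng.choice(config.n_proteins, size=n_enzymes, replace=False)
    )
    metabolites = [f"MET{i:03d}" for i in range(config.n_metabolites)]
    met_rows = []
    for met in metabolites:
        k = int(rng.integers(1, 4))
        enzymes = rng.choice(enzyme_ids, size=min(k, len(enzyme_ids)),
                             replace=False)
        for idx, e in enumerate(sorted(enzymes)):
            role = "substrate" if idx % 2 == 0 else "product"
            met_rows.append([proteins[e], met, role])
    _write_tsv(
        outdir / "enzyme_metabolites.tsv",
        ["enzyme", "metabolite", "role"],
        met_rows,
    )

    n_signaling = max(2, int(config.frac_signaling * config.n_proteins))
    signaling = sorted(
        rng.choice(config.n_proteins, size=n_signaling, replace=False)
    )
    crosstalk = sorted(
        rng.choice(
            config.n_proteins,
            size=max(1, int(config.frac_crosstalk * config.n_proteins)),
            replace=False,
        )
    )
    rate_limiting = sorted(
        rng.choice(
            enzyme_ids,
            size=max(1, int(config.frac_rate_limiting * len(enzyme_ids))),
            replace=False,
        )
    )
    for fname, ids in (
        ("signaling.txt", signaling),
        ("crosstalk.txt", crosstalk),
        ("rate_limiting.txt", rate_limiting),
    ):
        with open(outdir / fname, "w") as handle:
            for i in ids:
                handle.write(proteins[i] + "\n")

    return load_network(outdir)


def load_network(outdir: str | Path) -> MetaInteractome:
    """Rebuild the meta-interactome from a generated directory."""
    outdir = Path(outdir)

    def _read_list(name: str) -> frozenset[str]:
        path = outdir / name
        if not path.exists():
            return frozenset()
        return frozenset(
            line.strip() for line in path.read_text().splitlines()
            if line.strip()
        )

    edge_sets = [
        read_string_edges(outdir / "ppi_links.txt", min_experimental=700),
        read_regulatory_edges(outdir / "mirna_targets.tsv", "mirna_target"),
        read_regulatory_edges(outdir / "tf_targets.tsv", "tf_target"),
        read_metabolite_edges(outdir / "enzyme_metabolites.tsv"),
    ]
    annotations = Annotations(
        signaling=_read_list("signaling.txt"),
        crosstalk=_read_list("crosstalk.txt"),
        rate_limiting=_read_list("rate_limiting.txt"),
    )
    return build_meta_interactome(edge_sets, annotations)


def generate_omics(
    config: SynthConfig,
    meta: MetaInteractome,
    outdir: str | Path,
) -> dict:
    """Write per-layer omics TSVs with a planted deregulation signal.

    A fraction of protein nodes (and miRNAs) is drawn deregulated:
    logFC ~ Normal(+-logfc_mu, logfc_sd), p ~ Uniform(0, 0.049); the
    remainder is expressed with sub-threshold logFC and p ~ Uniform.
    Alteration layers sample random node subsets and metabolomics a
    metabolite subset.  Returns the ground-truth dict (also written to
    ``ground_truth.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    proteins = sorted(
        n for n, r in meta.nodes.items() if r.kind == "protein"
    )
    mirnas = sorted(n for n, r in meta.nodes.items() if r.kind == "mirna")
    metabolites = sorted(
        n for n, r in meta.nodes.items() if r.kind == "metabolite"
    )

    def _quant_layer(ids: list[str], fname: str) -> dict:
        n_dereg = max(1, int(round(config.frac_deregulated * len(ids))))
        dereg_idx = rng.choice(len(ids), size=n_dereg, replace=False)
        dereg = {ids[i] for i in dereg_idx}
        up, down = set(), set()
        rows = []
        for node in ids:
            if node in dereg:
                sign = 1 if rng.random() < 0.5 else -1
                logfc = sign * rng.normal(config.logfc_mu, config.logfc_sd)
                p = rng.uniform(0, 0.049)
                (up if sign > 0 else down).add(node)
            else:
                logfc = rng.uniform(-0.5, 0.5)
                p = rng.uniform(0, 1)
            rows.append([node, f"{logfc:.6f}", f"{p:.6f}"])
        _write_tsv(outdir / fname, ["id", "logFC", "p"], rows)
        return {"up": sorted(up), "down": sorted(down)}

    truth = {
        "mrna": _quant_layer(proteins, "mrna.tsv"),
        "mirna": _quant_layer(mirnas, "mirna.tsv"),
    }
    for layer, ids in (
        ("genomics", proteins),
        ("epigenomics", proteins),
        ("phospho", proteins),
    ):
        k = max(1, int(0.05 * len(ids)))
        chosen = sorted(
            ids[i] for i in rng.choice(len(ids), size=k, replace=False)
        )
        with open(outdir / f"{layer}.tsv", "w") as handle:
            handle.write("\n".join(chosen) + "\n")
        truth[layer] = chosen
    k = max(1, len(metabolites) // 3)
    chosen = sorted(
        metabolites[i]
        for i in rng.choice(len(metabolites), size=k, replace=False)
    )
    with open(outdir / "metabolomics.tsv", "w") as handle:
        handle.write("\n".join(chosen) + "\n")
    truth["metabolomics"] = chosen
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True)
    )
    return truth


def generate_pathways(
    config: SynthConfig,
    meta: MetaInteractome,
    truth: dict,
    outdir: str | Path,
) -> str:
    """Write a GMT gene-set file and the prognostic-marker table.

    Pathways are random protein groups labelled with the four classes;
    one planted pathway (``PLANTED_CANCER``) draws a disproportionate
    share of its members from the planted deregulated genes, so a
    correct enrichment engine should rank it first on the tail p-value.
    Returns the planted pathway name.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed + 2)
    proteins = sorted(
        n for n, r in meta.nodes.items() if r.kind == "protein"
    )
    planted_dereg = sorted(
        set(truth["mrna"]["up"]) | set(truth["mrna"]["down"])
    )
    classes = ["signaling", "metabolic", "cancer", "other"]
    lines = []
    for i in range(config.n_pathways):
        cls = classes[i % len(classes)]
        size = min(config.pathway_size, len(proteins))
        members = sorted(
            proteins[j]
            for j in rng.choice(len(proteins), size=size, replace=False)
        )
        lines.append(
            "\t".join([f"PATHWAY_{i:02d}", cls] + members)
        )
    # planted pathway: most members from the deregulated set
    n_sig = min(len(planted_dereg), int(0.7 * config.pathway_size))
    sig_members = sorted(
        planted_dereg[j]
        for j in rng.choice(len(planted_dereg), size=n_sig, replace=False)
    )
    background = [p for p in proteins if p not in set(sig_members)]
    n_bg = config.pathway_size - n_sig
    bg_members = sorted(
        background[j]
        for j in rng.choice(len(background), size=n_bg, replace=False)
    )
    planted_name = "PLANTED_CANCER"
    lines.append(
        "\t".join([planted_name, "cancer"] + sorted(sig_members + bg_members))
    )
    (outdir / "pathways.gmt").write_text("\n".join(lines) + "\n")

    cancer_types = ["renal", "liver", "lung", "breast", "cervical"]
    rows = []
    k = max(1, len(proteins) // 4)
    marker_idx = rng.choice(len(proteins), size=k, replace=False)
    for i in sorted(marker_idx):
        n_rows = int(rng.integers(1, 3))
        for _ in range(n_rows):
            rows.append(
                [
                    proteins[i],
                    cancer_types[int(rng.integers(len(cancer_types)))],
                    "favorable" if rng.random() < 0.5 else "unfavorable",
                    f"{rng.uniform(1e-5, 0.1):.6f}",
                ]
            )
    _write_tsv(
        outdir / "prognostic_markers.tsv",
        ["gene", "cancer_type", "direction", "p"],
        rows,
    )
    return planted_name


def generate_all(config: SynthConfig, outdir: str | Path) -> dict:
    """Full fixture: network + omics + pathways; returns a manifest."""
    outdir = Path(outdir)
    meta = generate_network(config, outdir)
    truth = generate_omics(config, meta, outdir)
    planted = generate_pathways(config, meta, truth, outdir)
    manifest = {
        "config": asdict(config),
        "planted_pathway": planted,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
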