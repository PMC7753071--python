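"""Shared fixtures: hand-built mini-networks and a seeded synthetic bundle."""

import pytest

from panomnet.interactome import (
    Annotations,
    EdgeRecord,
    MetaInteractome,
    NodeRecord,
    build_meta_interactome,
)
from panomnet.omics import DeregulationTable
from panomnet.synth import SynthConfig, generate_all, load_network


def make_ppi_network(
    edges,
    signaling=(),
    metabolic=(),
    crosstalk=(),
    rate_limiting=(),
) -> MetaInteractome:
    """Build a PPI-only meta-interactome from endpoint pairs."""
    records = [
        EdgeRecord(source=a, target=b, kind="ppi") for a, b in edges
    ]
    return build_meta_interactome(
        [records],
        Annotations(
            signaling=frozenset(signaling),
            metabolic_enzymes=frozenset(metabolic),
            crosstalk=frozenset(crosstalk),
            rate_limiting=frozenset(rate_limiting),
        ),
    )


def make_table(up=(), down=(), expressed=(), altered=(), scores=None):
    """Hand-built deregulation table; scores default to +-1 by status."""
    table = DeregulationTable()
    for n in up:
        table.statuses[n] = "up"
        table.combined[n] = (scores or {}).get(n, 1.0)
    for n in down:
        table.statuses[n] = "down"
        table.combined[n] = (scores or {}).get(n, -1.0)
    for n in expressed:
        table.statuses[n] = "expressed"
    for n in altered:
        table.statuses[n] = "altered"
    return table


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle (seed 7) shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SynthConfig(seed=7)
    manifest = generate_all(config, outdir)
    return {"dir": outdir, "config": config, "manifest": manifest}


@pytest.fixture(scope="session")
def bundle_network(bundle):
    return load_network(bundle["dir"])
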