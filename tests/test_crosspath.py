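"""Cross-pathway path enumeration, filtering, and HMM-style scoring."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from panomnet.crosspath import (
    MIRNA_TO_METABOLIC,
    SIGNALING_TO_METABOLIC,
    TF_TO_METABOLIC,
    CandidatePath,
    WeightConfig,
    enumerate_paths,
    expression_score,
    filter_paths,
    local_entropy,
    node_weight,
    path_overlap,
    path_score,
    score_paths,
    select_important,
    transition_probabilities,
)
from panomnet.interactome import EdgeRecord, build_meta_interactome
from tests.conftest import make_ppi_network, make_table
from tests.oracles import oracle_simple_paths


@pytest.fixture
def chain_net():
    """S - P1 - M with S signaling and M a metabolic enzyme."""
    return make_ppi_network(
        [("S", "P1"), ("P1", "M")], signaling=["S"], metabolic=["M"]
    )


class TestWeightConfig:
    def test_at_most_four_options(self):
        with pytest.raises(ValueError):
            WeightConfig(
                options=frozenset(
                    {
                        "deregulated_gene",
                        "crosstalk_gene",
                        "rate_limiting_enzyme",
                        "hub",
                        "central_node",
                    }
                )
            )

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(options=frozenset({"bogus"}))


class TestEnumeration:
    def test_single_route_chain(self, chain_net):
        paths = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        assert [p.nodes for p in paths] == [("S", "P1", "M")]
        assert paths[0].path_type == "XPM"

    def test_max_intermediates_zero_only_direct(self):
        net = make_ppi_network(
            [("S", "M"), ("S", "P"), ("P", "M")],
            signaling=["S"],
            metabolic=["M"],
        )
        paths = enumerate_paths(
            net, SIGNALING_TO_METABOLIC, max_intermediates=0
        )
        assert [p.nodes for p in paths] == [("S", "M")]
        assert paths[0].path_type == "XM"

    def test_complete_graph_matches_dfs_oracle(self):
        nodes = [f"K{i}" for i in range(5)]
        edges = list(itertools.combinations(nodes, 2))
        net = make_ppi_network(
            edges, signaling=["K0"], metabolic=["K4"]
        )
        paths = enumerate_paths(net, SIGNALING_TO_METABOLIC)
        adj = {n: sorted(net.neighbors(n, "ppi")) for n in nodes}
        oracle = oracle_simple_paths(adj, ["K0"], ["K4"], max_edges=4)
        assert {p.nodes for p in paths} == oracle

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        graph = nx.gnp_random_graph(n, 0.45, seed=seed + 100)
        edges = [(f"N{u}", f"N{v}") for u, v in graph.edges]
        if not edges:
            edges = [("N0", "N1")]
        names = sorted({x for e in edges for x in e})
        sig = [names[0]]
        met = names[-2:]
        net = make_ppi_network(edges, signaling=sig, metabolic=met)
        paths = enumerate_paths(net, SIGNALING_TO_METABOLIC)
        adj = {m: sorted(net.neighbors(m, "ppi")) for m in names}
        oracle = oracle_simple_paths(adj, sig, met, max_edges=4)
        assert {p.nodes for p in paths} == oracle

    def test_regulatory_mode_records_regulator(self):
        meta = build_meta_interactome(
            [
                {EdgeRecord("X", "P", "ppi"), EdgeRecord("P", "M", "ppi")},
                {EdgeRecord("TF1", "X", "tf_target")},
            ],
            None,
        )
        # flag M as enzyme via an enzyme_metabolite edge
        meta.add_edge(EdgeRecord("M", "met1", "enzyme_metabolite"))
        from dataclasses import replace

        meta.nodes["M"] = replace(
            meta.nodes["M"], is_metabolic_enzyme=True
        )
        table = make_table(up=["TF1", "M"], expressed=["X", "P"])
        paths = enumerate_paths(meta, TF_TO_METABOLIC, table)
        assert [(p.regulator, p.nodes) for p in paths] == [
            ("TF1", ("X", "P", "M"))
        ]

    def test_non_deregulated_regulators_skipped(self):
        meta = build_meta_interactome(
            [
                {EdgeRecord("X", "M", "ppi")},
                {
                    EdgeRecord("TF1", "X", "tf_target"),
                    EdgeRecord("TF2", "X", "tf_target"),
                },
            ]
        )
        from dataclasses import replace

        meta.nodes["M"] = replace(
            meta.nodes["M"], is_metabolic_enzyme=True
        )
        table = make_table(up=["TF1", "M"], expressed=["X", "TF2"])
        paths = enumerate_paths(meta, TF_TO_METABOLIC, table)
        assert {p.regulator for p in paths} == {"TF1"}

    def test_missing_node_class_is_error(self, chain_net):
        no_met = make_ppi_network([("S", "A")], signaling=["S"])
        with pytest.raises(ValueError, match="metabolic"):
            enumerate_paths(no_met, SIGNALING_TO_METABOLIC)

    def test_deterministic_lexicographic_order(self, chain_net):
        p1 = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        p2 = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        assert p1 == p2
        assert p1 == sorted(p1, key=lambda p: (p.regulator or "", p.nodes))


class TestFilter:
    def test_kept_when_terminals_deregulated(self, chain_net):
        paths = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        table = make_table(up=["S"], down=["M"], expressed=["P1"])
        assert filter_paths(paths, table) == paths

    def test_expressed_terminal_dropped(self, chain_net):
        paths = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        table = make_table(up=["S"], expressed=["P1", "M"])
        assert filter_paths(paths, table) == []

    def test_absent_interior_dropped(self, chain_net):
        paths = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)
        table = make_table(up=["S"], down=["M"])  # P1 absent
        assert filter_paths(paths, table) == []

    def test_regulator_is_the_judged_terminal(self):
        meta = build_meta_interactome(
            [
                {EdgeRecord("X", "M", "ppi")},
                {EdgeRecord("hsa-miR-1", "X", "mirna_target")},
            ]
        )
        from dataclasses import replace

        meta.nodes["M"] = replace(
            meta.nodes["M"], is_metabolic_enzyme=True
        )
        table = make_table(
            down=["hsa-miR-1", "M"], expressed=["X"]
        )
        paths = enumerate_paths(meta, MIRNA_TO_METABOLIC, table)
        kept = filter_paths(paths, table)
        assert len(kept) == 1
        # X is interior here: expressed suffices
        assert kept[0].terminals == ("hsa-miR-1", "M")


class TestScores:
    def test_expression_score_values(self):
        table = make_table(
            up=["u"], down=["d"], expressed=["e"], scores={"u": 0.6, "d": -1.0}
        )
        assert expression_score("e", table) == 1.0
        assert expression_score("u", table) == pytest.approx(1.6)
        assert expression_score("d", table) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            expression_score("missing", table)

    def test_forced_transition_probability(self, chain_net):
        table = make_table(up=["S"], down=["M"], expressed=["P1"])
        path = enumerate_paths(chain_net, SIGNALING_TO_METABOLIC)[0]
        probs = transition_probabilities(path, table, chain_net)
        # S has a single eligible neighbor -> forced probability 1;
        # P1 splits its mass between S and M, which score equally
        assert probs[0] == pytest.approx(1.0)
        assert probs[1] == pytest.approx(0.5)

    def test_equal_scores_split_evenly(self):
        net = make_ppi_network(
            [("S", "A"), ("S", "B"), ("A", "M"), ("B", "M")],
            signaling=["S"],
            metabolic=["M"],
        )
        table = make_table(up=["S"], down=["M"], expressed=["A", "B"])
        paths = filter_paths(
            enumerate_paths(net, SIGNALING_TO_METABOLIC), table
        )
        for p in paths:
            if p.nodes[0] == "S" and len(p.nodes) == 3:
                probs = transition_probabilities(p, table, net)
                assert probs[0] == pytest.approx(0.5)

    def test_outgoing_probabilities_sum_to_one(self, bundle_network):
        # per-source normalization over eligible neighbors
        proteins = sorted(
            n
            for n, r in bundle_network.nodes.items()
            if r.kind == "protein"
        )
        table = make_table(
            up=proteins[: len(proteins) // 2],
            expressed=proteins[len(proteins) // 2:],
        )
        from panomnet.crosspath import _eligible_neighbors

        for node in proteins[:30]:
            neighbors = _eligible_neighbors(
                bundle_network, node, "ppi", table
            )
            if not neighbors:
                continue
            s = expression_score(node, table)
            denom = sum(
                s * expression_score(u, table) for u in neighbors
            )
            total = sum(
                s * expression_score(u, table) / denom for u in neighbors
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_local_entropy_uniform_and_degree_one(self):
        net = make_ppi_network(
            [("V", "A"), ("V", "B"), ("V", "C"), ("W", "A")],
            signaling=["V"],
            metabolic=["A"],
        )
        table = make_table(expressed=["V", "A", "B", "C", "W"])
        assert local_entropy("V", net, table) == pytest.approx(math.log(3))
        assert local_entropy("W", net, table) == 0.0

    def test_entropy_bounded_by_log_degree(self, bundle_network):
        proteins = sorted(
            n
            for n, r in bundle_network.nodes.items()
            if r.kind == "protein"
        )
        table = make_table(
            up=proteins[:50], expressed=proteins[50:]
        )
        for node in proteins[:40]:
            k = len(bundle_network.neighbors(node, "ppi"))
            if k:
                assert local_entropy(
                    node, bundle_network, table
                ) <= math.log(k) + 1e-12

    def test_node_weight_counts_predicates(self, chain_net):
        import pandas as pd

        table = make_table(up=["S"], down=["M"], expressed=["P1"])
        report = pd.DataFrame(
            {"is_hub": [True], "is_central": [False],
             "is_bottleneck": [False]},
            index=["S"],
        )
        config = WeightConfig(
            options=frozenset({"deregulated_gene", "hub"})
        )
        assert node_weight("S", config, chain_net, table, report) == 2
        assert node_weight("P1", config, chain_net, table, report) == 0

    def test_network_option_without_report_is_error(self, chain_net):
        table = make_table(up=["S"])
        config = WeightConfig(options=frozenset({"hub"}))
        with pytest.raises(ValueError, match="topology report"):
            node_weight("S", config, chain_net, table, None)

    def test_weight_bounded_by_selected_count(self, chain_net):
        table = make_table(up=["S"], down=["M"], expressed=["P1"])
        config = WeightConfig(
            options=frozenset(
                {"deregulated_gene", "crosstalk_gene", "rate_limiting_enzyme"}
            )
        )
        for node in ("S", "P1", "M"):
            w = node_weight(node, config, chain_net, table)
            assert 0 <= w <= len(config.options)

    def test_single_edge_reduction(self):
        net = make_ppi_network(
            [("S", "M")], signaling=["S"], metabolic=["M"]
        )
        table = make_table(up=["S"], down=["M"])
        config = WeightConfig(options=frozenset({"deregulated_gene"}))
        path = enumerate_paths(net, SIGNALING_TO_METABOLIC)[0]
        scored = path_score(path, config, net, table)
        e = (1 + 1) / (2 + 1)  # both nodes deregulated, one option
        assert scored.path_score == pytest.approx(
            math.log(1.0) + 2 * math.log(e)
        )

    def test_weighted_interior_scores_higher(self):
        # identical paths, one interior node crosstalk-flagged
        edges = [("S", "P1"), ("P1", "M"), ("S", "P2"), ("P2", "M")]
        net = make_ppi_network(
            edges, signaling=["S"], metabolic=["M"], crosstalk=["P1"]
        )
        table = make_table(
            up=["S"], down=["M"], expressed=["P1", "P2"]
        )
        config = WeightConfig(
            options=frozenset({"deregulated_gene", "crosstalk_gene"})
        )
        paths = filter_paths(
            enumerate_paths(net, SIGNALING_TO_METABOLIC), table
        )
        scored = {
            p.nodes: path_score(p, config, net, table).path_score
            for p in paths
            if len(p.nodes) == 3
        }
        assert scored[("S", "P1", "M")] > scored[("S", "P2", "M")]

    def test_score_invariant_under_relabeling(self):
        edges = [("S", "P"), ("P", "M")]
        relabel = {"S": "XS", "P": "XP", "M": "XM"}
        net1 = make_ppi_network(edges, signaling=["S"], metabolic=["M"])
        net2 = make_ppi_network(
            [(relabel[a], relabel[b]) for a, b in edges],
            signaling=["XS"],
            metabolic=["XM"],
        )
        t1 = make_table(up=["S"], down=["M"], expressed=["P"])
        t2 = make_table(up=["XS"], down=["XM"], expressed=["XP"])
        config = WeightConfig(options=frozenset({"deregulated_gene"}))
        s1 = path_score(
            enumerate_paths(net1, SIGNALING_TO_METABOLIC)[0],
            config, net1, t1,
        )
        s2 = path_score(
            enumerate_paths(net2, SIGNALING_TO_METABOLIC)[0],
            config, net2, t2,
        )
        assert s1.path_score == pytest.approx(s2.path_score)


class TestSelection:
    def _mk(self, score):
        return CandidatePath(
            mode=SIGNALING_TO_METABOLIC,
            nodes=("S", f"M{score}"),
            path_score=score,
        )

    def test_hand_z_computation(self):
        paths = [self._mk(0.0), self._mk(0.0), self._mk(10.0)]
        out = select_important(paths)
        top = out[0]
        # z of 10 among {0,0,10} with ddof=1
        assert top.z == pytest.approx(2 / math.sqrt(3), abs=1e-9)
        assert top.important
        assert not out[1].important and not out[2].important

    def test_inclusive_at_exactly_one(self):
        # symmetric pair: z = +-sqrt(2)/2 ... need a value at exactly 1
        scores = [0.0, 1.0, 2.0]  # z = -1, 0, +1 exactly
        out = select_important([self._mk(s) for s in scores])
        assert out[0].z == pytest.approx(1.0)
        assert out[0].important

    def test_important_subset(self):
        rng = np.random.default_rng(2)
        paths = [self._mk(float(s)) for s in rng.normal(size=30)]
        out = select_important(paths)
        assert sum(p.important for p in out) <= len(out)
        assert [p.z for p in out] == sorted(
            (p.z for p in out), reverse=True
        )

    def test_degenerate_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_important([self._mk(1.0), self._mk(1.0)])


class TestOverlap:
    def _paths(self, names):
        return [
            CandidatePath(
                mode=SIGNALING_TO_METABOLIC, nodes=("S", n)
            )
            for n in names
        ]

    def test_identical_runs_full_intersection(self):
        runs = {"r1": self._paths("AB"), "r2": self._paths("AB")}
        regions = path_overlap(runs)
        assert regions == {"r1": 0, "r2": 0, "r1&r2": 2}

    def test_disjoint_runs(self):
        runs = {"r1": self._paths("AB"), "r2": self._paths("CD")}
        regions = path_overlap(runs)
        assert regions["r1&r2"] == 0

    def test_regions_sum_to_union(self):
        runs = {
            "r1": self._paths("ABC"),
            "r2": self._paths("BCD"),
            "r3": self._paths("CDE"),
        }
        regions = path_overlap(runs)
        assert sum(regions.values()) == 5

    def test_mixed_modes_rejected(self):
        runs = {
            "r1": self._paths("A"),
            "r2": [
                CandidatePath(mode=TF_TO_METABOLIC, nodes=("X", "M"))
            ],
        }
        with pytest.raises(ValueError, match="modes"):
            path_overlap(runs)
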