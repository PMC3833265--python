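"""Network/expression I/O, alignment, influence matrix and assembly filters."""

import numpy as np
import pandas as pd
import pytest

from actichain.network import (
    ExpressionDataset,
    ExpressionParseError,
    FunctionalNetwork,
    Link,
    NetworkParseError,
    align,
    build_influence_matrix,
    connect_targets,
    de_rank_genes,
    read_expression,
    read_network,
    subnetwork_from_top_genes,
    write_network,
)
from oracles import random_test_network


def write(path, text):
    path.write_text(text)
    return str(path)


class TestReadNetwork:
    def test_sif_interactions_are_undirected(self, tmp_path):
        p = write(tmp_path / "net.sif", "A pp B\nB pp C\n")
        net = read_network(p)
        assert set(net.genes) == {"A", "B", "C"}
        assert len(net.links) == 2
        assert all(not ln.directed and ln.sign == "interaction" for ln in net.links)

    def test_sif_relations_map_direction_and_sign(self, tmp_path):
        p = write(tmp_path / "net.sif", "A activates B\nB inhibits C\n")
        net = read_network(p)
        by_pair = {(ln.source, ln.target): ln for ln in net.links}
        assert by_pair[("A", "B")].directed and by_pair[("A", "B")].sign == "stimulation"
        assert by_pair[("B", "C")].sign == "inhibition"

    def test_duplicate_rows_collapse_to_max_confidence(self, tmp_path):
        p = write(
            tmp_path / "net.tsv",
            "source\ttarget\tconfidence\nA\tB\t0.8\nA\tB\t0.95\n",
        )
        net = read_network(p)
        assert len(net.links) == 1
        assert net.links[0].confidence == 0.95

    def test_self_loop_dropped_gene_kept(self, tmp_path):
        p = write(tmp_path / "net.sif", "A pp A\nA pp B\n")
        net = read_network(p)
        assert "A" in net and len(net.links) == 1
        assert len(net.parse_warnings) == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = write(tmp_path / "net.sif", "A pp B\nA B\n")
        with pytest.raises(NetworkParseError, match="line 2"):
            read_network(p)

    def test_unknown_sign_rejected(self, tmp_path):
        p = write(tmp_path / "net.tsv", "source\ttarget\tsign\nA\tB\tmaybe\n")
        with pytest.raises(NetworkParseError, match="line 2"):
            read_network(p)

    def test_defaults_undirected_unweighted(self, tmp_path):
        p = write(tmp_path / "net.tsv", "source\ttarget\nA\tB\n")
        ln = read_network(p).links[0]
        assert (ln.directed, ln.sign, ln.raw_weight, ln.confidence) == (
            False,
            "interaction",
            1.0,
            None,
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_write_read_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        net = random_test_network(rng, 12, 0.25, 0.4, 0.3)
        net.add_gene("isolated_gene")
        path = tmp_path / "net.tsv"
        write_network(net, path)
        again = read_network(str(path))
        assert again == net
        write_network(again, tmp_path / "net2.tsv")
        assert (tmp_path / "net.tsv").read_text() == (tmp_path / "net2.tsv").read_text()


class TestLink:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            Link("A", "A")

    def test_sign_numeric_mapping(self):
        assert Link("A", "B", sign="inhibition").numeric_sign == -1
        assert Link("A", "B", sign="stimulation").numeric_sign == 1
        assert Link("A", "B", sign="interaction").numeric_sign == 1


class TestReadExpression:
    def test_basic_counts(self, tmp_path):
        p = write(
            tmp_path / "e.tsv",
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t0\t1\t0\t1\ng3\t5\t5\t5\t5\n",
        )
        ds = read_expression(p, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        assert (ds.n_A, ds.n_B) == (2, 2)
        assert ds.genes == ("g1", "g2", "g3")

    def test_single_replicate_is_hard_error(self, tmp_path):
        p = write(tmp_path / "e.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="two replicates"):
            read_expression(p, {"s1": "A", "s2": "B", "s3": "B", "s4": "B"})

    def test_non_numeric_cell_is_parse_error(self, tmp_path):
        p = write(tmp_path / "e.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\tx\t3\t4\n")
        with pytest.raises(ExpressionParseError, match="row"):
            read_expression(p, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"})

    def test_condition_map_file(self, tmp_path):
        e = write(tmp_path / "e.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n" "g2\t1\t1\t2\t2\n")
        c = write(tmp_path / "c.tsv", "sample\tcondition\ns1\tA\ns2\tA\ns3\tB\ns4\tB\n")
        ds = read_expression(e, c)
        assert ds.condition["s3"] == "B"


class TestAlign:
    def test_intersection(self, small_expression):
        net = FunctionalNetwork(links=[Link("B", "C"), Link("C", "E")])
        n2, e2 = align(net, small_expression)
        assert n2.genes == e2.genes == ("B", "C")

    def test_identity(self, small_expression):
        net = FunctionalNetwork(
            genes=small_expression.genes, links=[Link("A", "B"), Link("C", "D")]
        )
        n2, e2 = align(net, small_expression)
        assert set(n2.genes) == set(small_expression.genes)
        assert np.array_equal(e2.values, small_expression.values)

    def test_disjoint_sets_error(self, small_expression):
        net = FunctionalNetwork(links=[Link("X", "Y")])
        with pytest.raises(ValueError, match="no genes"):
            align(net, small_expression)


class TestInfluenceMatrix:
    def test_single_undirected_neighbour_gets_full_damping(self):
        net = FunctionalNetwork(links=[Link("g", "h", sign="stimulation")])
        infl = build_influence_matrix(net, damping=0.5)
        assert infl.weight("h", "g") == 0.5
        assert infl.weight("g", "h") == 0.5

    def test_two_in_links_split_with_signs(self):
        net = FunctionalNetwork(
            links=[
                Link("a", "g", directed=True, sign="inhibition"),
                Link("b", "g", directed=True, sign="stimulation"),
            ]
        )
        infl = build_influence_matrix(net, damping=0.5)
        assert infl.weight("a", "g") == -0.25
        assert infl.weight("b", "g") == 0.25

    def test_gene_with_no_in_links_has_zero_weights(self):
        net = FunctionalNetwork(links=[Link("a", "b", directed=True)])
        infl = build_influence_matrix(net, damping=0.5)
        gi = {g: i for i, g in enumerate(infl.genes)}
        assert np.all(infl.matrix[gi["a"], :] == 0)

    def test_damping_out_of_range(self, path_network):
        for lam in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                build_influence_matrix(path_network, damping=lam)

    @pytest.mark.parametrize("seed", range(8))
    def test_incoming_absolute_weights_sum_to_damping_or_zero(self, seed):
        """Row sums of |W| are exactly 0 or the damping factor, so I - W is
        strictly diagonally dominant and invertible."""
        rng = np.random.default_rng(seed)
        net = random_test_network(rng, 15, 0.2, 0.5, 0.3)
        lam = float(rng.uniform(0.1, 0.9))
        infl = build_influence_matrix(net, damping=lam)
        sums = np.abs(infl.matrix).sum(axis=1)
        for s in sums:
            assert s == pytest.approx(0.0, abs=1e-12) or s == pytest.approx(lam, abs=1e-12)
        assert np.all(infl.matrix.diagonal() == 0)
        # invertibility at these row sums
        np.linalg.inv(np.eye(infl.n) - infl.matrix)


class TestDeRankGenes:
    def test_pooled_t_hand_value(self):
        ds = ExpressionDataset(
            ("g",),
            ("s1", "s2", "s3", "s4"),
            np.array([[1.0, 2.0, 3.0, 4.0]]),
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        t = de_rank_genes(ds).loc[0, "t"]
        assert t == pytest.approx(2 / np.sqrt(0.5), rel=1e-12)

    def test_degenerate_rules_and_order(self, small_expression):
        # gene C constant everywhere -> t = 0, last; gene B has zero pooled
        # variance and nonzero difference -> +inf, first
        ranked = de_rank_genes(small_expression)
        assert ranked.iloc[0]["gene"] == "B" and np.isinf(ranked.iloc[0]["t"])
        assert ranked.iloc[-1]["gene"] == "C" and ranked.iloc[-1]["t"] == 0.0
        assert list(ranked["rank"]) == [1, 2, 3, 4]


class TestSubnetworkFromTopGenes:
    def reference(self):
        return FunctionalNetwork(
            links=[
                Link("a", "b", confidence=0.95),
                Link("b", "c", confidence=0.5),
                Link("c", "d", confidence=0.95),
                Link("d", "e", confidence=0.92),
            ]
        )

    def ranked(self, genes):
        return pd.DataFrame({"gene": list(genes), "t": 0.0, "rank": range(1, len(genes) + 1)})

    def test_full_induced_subgraph_minus_isolated(self):
        net = subnetwork_from_top_genes(self.ranked("abcde"), self.reference(), 5, 0.9)
        assert set(net.genes) == {"a", "b", "c", "d", "e"}
        assert len(net.links) == 3  # b-c filtered out but nobody isolated

    def test_nothing_survives_is_error(self):
        with pytest.raises(ValueError, match="empty network"):
            subnetwork_from_top_genes(self.ranked("abcde"), self.reference(), 5, 0.99)

    def test_isolated_genes_removed(self):
        # top-3 genes a, b, e induce exactly one qualifying link a-b; e isolated
        net = subnetwork_from_top_genes(self.ranked("abe"), self.reference(), 3, 0.9)
        assert set(net.genes) == {"a", "b"}
        assert len(net.links) == 1

    def test_no_isolated_gene_ever_survives(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ref = random_test_network(rng, 12, 0.2, 0.0, 0.0)
            ref2 = FunctionalNetwork(genes=ref.genes)
            for ln in ref.links:
                ref2.add_link(
                    Link(ln.source, ln.target, confidence=float(rng.uniform(0.5, 1.0)))
                )
            genes = list(ref2.genes)
            try:
                net = subnetwork_from_top_genes(self.ranked(genes), ref2, 8, 0.7)
            except ValueError:
                continue
            assert all(net.degree(g) > 0 for g in net.genes)


class TestConnectTargets:
    def test_target_already_present_is_identity(self, path_network):
        ref = path_network.copy()
        out = connect_targets(path_network, ref, ["A"])
        assert out == path_network

    def test_single_shortest_path_added(self):
        ref = FunctionalNetwork(links=[Link("t", "a"), Link("a", "b"), Link("b", "x")])
        net = FunctionalNetwork(links=[Link("b", "x")])
        out = connect_targets(net, ref, ["t"])
        assert set(out.genes) == {"t", "a", "b", "x"}
        assert out.find_link("t", "a") and out.find_link("a", "b")

    def test_tie_broken_lexicographically(self):
        ref = FunctionalNetwork(
            links=[Link("t", "a"), Link("a", "b"), Link("t", "c"), Link("c", "b"), Link("b", "x")]
        )
        net = FunctionalNetwork(links=[Link("b", "x")])
        out = connect_targets(net, ref, ["t"])
        assert "a" in out and "c" not in out

    def test_unreachable_target_logged_not_fatal(self):
        ref = FunctionalNetwork(links=[Link("a", "b"), Link("t", "z")])
        net = FunctionalNetwork(links=[Link("a", "b")])
        out = connect_targets(net, ref, ["t"])
        assert "t" not in out
        assert any("unconnected" in w for w in out.parse_warnings)

    def test_never_removes_anything(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ref = random_test_network(rng, 14, 0.2, 0.0, 0.0)
            genes = list(ref.genes)
            sub = ref.subgraph(genes[:5])
            targets = genes[8:11]
            out = connect_targets(sub, ref, targets)
            assert set(out.genes) >= set(sub.genes)
            assert {ln.key for ln in out.links} >= {ln.key for ln in sub.links}
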