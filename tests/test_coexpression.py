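"""Co-expression network construction, hubs, MCL modules and GO enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linckit import coexpression as coex
from oracles import hypergeom_upper_tail_exact, mcl_oracle


def graph_with_types(edges, types):
    G = nx.Graph()
    G.add_edges_from(edges)
    for node, t in types.items():
        if node in G:
            G.nodes[node]["gene_type"] = t
    return G


class TestVarianceFilter:
    def test_ceiling_of_three_quarters(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        assert len(coex.variance_filter(df)) == 3

    def test_constant_gene_is_dropped_first(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        df.loc["c"] = 7.0
        assert "c" not in coex.variance_filter(df).index

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 10)),
                          index=[f"g{i:02d}" for i in range(20)])
        kept = set(coex.variance_filter(df).index)
        order = sorted(df.index, key=lambda g: -float(np.var(df.loc[g], ddof=1)))
        assert kept == set(order[:15])


class TestPcc:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, p = coex.pcc_with_pvalue(x, 2 * x + 1)
        assert (r, p) == (pytest.approx(1.0), 0.0)
        r, p = coex.pcc_with_pvalue(x, -x)
        assert (r, p) == (pytest.approx(-1.0), 0.0)

    def test_matches_textbook_formula_on_fixed_vectors(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0, 3.0, 9.0, 6.0, 2.5])
        y = np.array([2.0, 5.0, 1.0, 9.0, 4.0, 8.0, 2.5, 8.5, 7.0, 3.0])
        r, p = coex.pcc_with_pvalue(x, y)
        # independent evaluation: covariance quotient and Fisher z by hand
        xm, ym = x - x.mean(), y - y.mean()
        r_ref = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
        z = 0.5 * math.log((1 + r_ref) / (1 - r_ref))
        p_ref = 2 * (1 - stats.norm.cdf(abs(z) * math.sqrt(10 - 3)))
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            coex.pcc_with_pvalue(np.ones(5), np.arange(5.0))


class TestBuildNetwork:
    def _matrix(self, seed=0, n_genes=40, n_tissues=10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.lognormal(1, 1, size=(n_genes, n_tissues)),
            index=[f"g{i:02d}" for i in range(n_genes)],
        )
        # one planted near-perfect pair
        df.loc["g01"] = df.loc["g00"] * 3.0 * (1 + rng.normal(0, 0.01, n_tissues))
        return df

    def test_edge_count_bounded_by_union_of_tails(self):
        df = self._matrix()
        types = pd.Series("mRNA", index=df.index)
        G = coex.build_network(df, types)
        m = G.graph["n_tested"]
        assert G.number_of_edges() <= 2 * math.floor(0.05 * m)

    def test_all_edges_satisfy_both_rules(self):
        df = self._matrix()
        G = coex.build_network(df, pd.Series("mRNA", index=df.index))
        assert G.has_edge("g00", "g01")
        for _a, _b, d in G.edges(data=True):
            assert d["p_adj"] < 0.05
            assert d["p_adj"] >= d["p_raw"]

    def test_median_rank_pair_is_excluded_despite_small_p(self):
        # perfectly correlated pair among pairs that are even more extreme:
        # with rank_fraction=0 no pair can be selected at all
        df = self._matrix()
        G = coex.build_network(df, pd.Series("mRNA", index=df.index), rank_fraction=0.0)
        assert G.number_of_edges() == 0

    def test_edge_set_invariant_under_gene_reordering(self):
        df = self._matrix(seed=3)
        types = pd.Series("mRNA", index=df.index)
        G1 = coex.build_network(df, types)
        shuffled = df.sample(frac=1.0, random_state=9)
        G2 = coex.build_network(shuffled, types)
        edges1 = {frozenset(e) for e in G1.edges}
        edges2 = {frozenset(e) for e in G2.edges}
        assert edges1 == edges2


class TestHubs:
    def test_star_of_ten_mrnas_is_a_hub(self):
        mrnas = [f"m{i}" for i in range(10)]
        G = graph_with_types(
            [("l1", m) for m in mrnas],
            {"l1": "lincRNA", **{m: "mRNA" for m in mrnas}},
        )
        assert coex.find_hubs(G) == {"l1": sorted(mrnas)}

    def test_lincRNA_neighbors_do_not_count(self):
        mrnas = [f"m{i}" for i in range(9)]
        lincs = [f"l{i}" for i in range(5)]
        G = graph_with_types(
            [("hub", x) for x in mrnas + lincs],
            {"hub": "lincRNA", **{m: "mRNA" for m in mrnas},
             **{l: "lincRNA" for l in lincs}},
        )
        assert coex.find_hubs(G) == {}

    def test_empty_network_has_no_hubs(self):
        assert coex.find_hubs(nx.Graph()) == {}


class TestMcl:
    @staticmethod
    def clique_graph(sizes, linc_per_clique):
        G = nx.Graph()
        names = []
        for ci, (size, n_linc) in enumerate(zip(sizes, linc_per_clique)):
            members = [f"c{ci}_{k}" for k in range(size)]
            names.append(members)
            for i in range(size):
                for j in range(i + 1, size):
                    G.add_edge(members[i], members[j])
            for k, node in enumerate(members):
                G.nodes[node]["gene_type"] = "lincRNA" if k < n_linc else "mRNA"
        return G, names

    def test_two_disjoint_cliques_give_two_reported_modules(self):
        G, names = self.clique_graph([12, 12], [1, 1])
        _all, reported, converged = coex.mcl_cluster(G)
        assert converged
        assert sorted(sorted(m.members) for m in reported) == sorted(
            sorted(c) for c in names
        )

    def test_clique_without_lincRNA_is_not_reported(self):
        G, _ = self.clique_graph([15], [0])
        _all, reported, _ = coex.mcl_cluster(G)
        assert reported == []

    def test_modules_partition_a_node_subset(self):
        G, _ = self.clique_graph([12, 11], [1, 2])
        G.add_edge("c0_0", "c1_0")  # weak bridge
        allm, _rep, _ = coex.mcl_cluster(G)
        seen = [g for m in allm for g in m.members]
        assert len(seen) == len(set(seen))
        assert set(seen) <= set(G.nodes)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(1 << 30)))
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
        for n in G.nodes:
            G.nodes[n]["gene_type"] = "mRNA"
        allm, _, _ = coex.mcl_cluster(G)
        ours = frozenset(m.members for m in allm)
        nodes = sorted(G.nodes)
        assert ours == mcl_oracle(nodes, list(G.edges))


class TestGoEnrichment:
    def test_exact_enumeration_example(self):
        background = {f"g{i}" for i in range(20)}
        annotated = {f"g{i}" for i in range(5)}
        ann = {g: {"GO:X"} for g in annotated}
        gene_set = set(list(annotated)[:4]) | {sorted(background - annotated)[0]}
        df = coex.go_enrichment(gene_set, background, ann)
        row = df.set_index("go_term").loc["GO:X"]
        assert row["p_raw"] == pytest.approx(76 / 15504)
        assert row["p_raw"] == pytest.approx(
            hypergeom_upper_tail_exact(20, 5, 5, 4)
        )

    def test_certain_event_has_p_one(self):
        genes = {f"g{i}" for i in range(6)}
        ann = {g: {"GO:Y"} for g in genes}
        df = coex.go_enrichment(genes, genes, ann)
        assert df.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_unannotated_set_yields_no_terms(self):
        background = {"a", "b", "c", "d"}
        df = coex.go_enrichment({"a"}, background, {"b": {"GO:Z"}})
        assert df.empty

    def test_bh_fdr_is_monotone_in_raw_p(self):
        rng = np.random.default_rng(5)
        background = {f"g{i}" for i in range(40)}
        ann = {}
        for i, g in enumerate(sorted(background)):
            ann[g] = {f"GO:{j}" for j in rng.choice(8, size=2, replace=False)}
        df = coex.go_enrichment(set(sorted(background)[:10]), background, ann)
        df = df.sort_values("p_raw")
        assert (df["p_fdr"].to_numpy() >= df["p_raw"].to_numpy() - 1e-12).all()
        assert df["p_fdr"].is_monotonic_increasing

    def test_empty_background_is_an_error(self):
        with pytest.raises(ValueError):
            coex.go_enrichment(set(), set(), {})


class TestAnnotation:
    def test_planted_module_term_is_inherited_by_its_lincRNA(self, default_dataset):
        eb = default_dataset.expression
        filtered = coex.variance_filter(eb.matrix.values)
        G = coex.build_network(filtered, eb.matrix.gene_types)
        hubs = coex.find_hubs(G)
        _allm, reported, _ = coex.mcl_cluster(G)
        annotations, summary = coex.annotate_lincRNAs(
            G, hubs, reported, eb.go_annotation
        )
        (plant,) = eb.planted_modules
        assert plant["go_term"] in annotations[plant["linc"]]
        assert summary["n_overlap_annotated"] >= 1
        assert summary["n_overlap_annotated"] <= min(
            summary["n_hub_annotated"], summary["n_module_annotated"]
        )

    def test_disjoint_hub_and_module_lincs_have_zero_overlap(self):
        mrnas = [f"m{i}" for i in range(10)]
        types = {"l1": "lincRNA", **{m: "mRNA" for m in mrnas}}
        G = graph_with_types([("l1", m) for m in mrnas], types)
        hubs = coex.find_hubs(G)
        ann = {m: {"GO:A"} for m in mrnas}
        background = set(G.nodes) | {f"bg{i}" for i in range(30)}
        combined, summary = coex.annotate_lincRNAs(G, hubs, [], ann, background)
        assert summary["n_overlap_annotated"] == 0
        assert combined == {"l1": {"GO:A"}}
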