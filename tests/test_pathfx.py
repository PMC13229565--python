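import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pathscreen.pathfx as pfx
from pathscreen.io_formats import Interactome, PhenotypeCatalog
from pathscreen.stats import fisher_enrichment_p


def _random_scored_graph(rng: np.random.Generator, n: int) -> Interactome:
    g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g.edges[u, v]["score"] = float(rng.uniform(0.05, 1.0))
    return Interactome(g)


def _brute_force_scores(interactome: Interactome, targets: set[str], max_depth: int):
    """score(v) = max path product over all simple paths of <= max_depth edges."""
    g = interactome.graph
    best: dict[str, float] = {t: 1.0 for t in targets if t in g}
    for t in sorted(best):
        for v in g.nodes:
            if v in targets:
                continue
            for path in nx.all_simple_paths(g, t, v, cutoff=max_depth):
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= g.edges[a, b]["score"]
                if prod > best.get(v, 0.0):
                    best[v] = prod
    return best


def _brute_force_threshold(downstream: dict[str, float]) -> float:
    """Exhaustive sweep of the threshold objective, ties to the largest cutoff."""
    values = np.array(sorted(downstream.values()))
    best_theta, best_obj = 1.0, -1
    for theta in np.unique(values):
        kept = values[values >= theta]
        obj = int((kept > kept.mean()).sum())
        if obj >= best_obj:
            best_obj, best_theta = obj, float(theta)
    return best_theta


class TestNodeScores:
    def test_hand_computed_path_products(self, toy_interactome):
        nsm = pfx.compute_node_scores(toy_interactome, ["T"], max_depth=2)
        assert nsm.scores["T"] == 1.0
        assert nsm.downstream == pytest.approx({"A": 0.9, "B": 0.4, "C": 0.72})

    def test_depth_bound_respected(self, toy_interactome):
        nsm = pfx.compute_node_scores(toy_interactome, ["T"], max_depth=1)
        assert set(nsm.downstream) == {"A", "B"}
        deep = pfx.compute_node_scores(toy_interactome, ["T"], max_depth=3)
        assert deep.downstream["D"] == pytest.approx(0.9 * 0.8 * 0.9)

    def test_best_path_wins_over_shorter_weaker_path(self):
        g = nx.Graph()
        g.add_edge("T", "X", score=0.3)  # direct but weak
        g.add_edge("T", "Y", score=0.9)
        g.add_edge("Y", "X", score=0.8)  # two hops, product 0.72 > 0.3
        nsm = pfx.compute_node_scores(Interactome(g), ["T"], max_depth=2)
        assert nsm.downstream["X"] == pytest.approx(0.72)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            net = _random_scored_graph(rng, 14)
            nodes = sorted(net.nodes)
            targets = set(rng.choice(nodes, size=2, replace=False))
            for depth in (1, 2, 3):
                nsm = pfx.compute_node_scores(net, sorted(targets), max_depth=depth)
                expected = _brute_force_scores(net, targets, depth)
                assert nsm.scores == pytest.approx(expected), f"trial {trial} depth {depth}"

    def test_missing_targets_dropped_then_error_when_none_left(self, toy_interactome):
        nsm = pfx.compute_node_scores(toy_interactome, ["T", "ZZZ"], max_depth=2)
        assert nsm.targets == {"T"}
        with pytest.raises(pfx.DrugNotConnectedError):
            pfx.compute_node_scores(toy_interactome, ["ZZZ"], max_depth=2)


class TestThresholdSelection:
    def test_hand_example(self, toy_interactome):
        # downstream scores 0.9, 0.4, 0.72: objective is 2 at cutoff 0.4
        # (two genes above mean 0.673) and lower at every larger cutoff
        nsm = pfx.compute_node_scores(toy_interactome, ["T"], max_depth=2)
        theta, net = pfx.select_threshold(nsm, toy_interactome)
        assert theta == pytest.approx(0.4)
        assert net.genes == {"T", "A", "B", "C"}

    def test_ties_break_to_largest_cutoff(self):
        # cutoffs 0.5 and 0.6 both keep exactly one gene above the kept mean
        # (0.9 > 0.667 and 0.9 > 0.75); the tie resolves to the larger cutoff
        nsm = pfx.NodeScoreMap(
            drug_id="D", max_depth=1,
            scores={"T": 1.0, "A": 0.9, "B": 0.6, "C": 0.5},
            provenance={"T": "target", "A": "downstream", "B": "downstream", "C": "downstream"},
        )
        theta, net = pfx.select_threshold(nsm)
        assert theta == pytest.approx(0.6)
        assert net.genes == {"T", "A", "B"}

    def test_no_downstream_gives_targets_only_network(self):
        nsm = pfx.NodeScoreMap("D", 2, {"T": 1.0}, {"T": "target"})
        theta, net = pfx.select_threshold(nsm)
        assert theta == 1.0
        assert net.genes == {"T"}
        assert net.downstream_scores == {}

    def test_matches_brute_force_sweep_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            net = _random_scored_graph(rng, 20)
            nodes = sorted(net.nodes)
            targets = [str(g) for g in rng.choice(nodes, size=3, replace=False)]
            nsm = pfx.compute_node_scores(net, targets, max_depth=2)
            if not nsm.downstream:
                continue
            theta, _ = pfx.select_threshold(nsm)
            assert theta == pytest.approx(_brute_force_threshold(nsm.downstream))

    def test_build_drug_network_is_deterministic(self, toy_interactome):
        a = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        b = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        assert a.genes == b.genes and a.threshold == b.threshold and a.edges == b.edges


class TestPhenotypeAssociation:
    def test_counts_and_p_values(self, toy_interactome, toy_catalog):
        net = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        table = pfx.associate_phenotypes(net, toy_catalog, toy_interactome.nodes)
        assert list(table["phenotype"]) == sorted(toy_catalog.entries)
        for _, row in table.iterrows():
            assert row["a"] + row["b"] + row["c"] + row["d"] == len(toy_interactome.nodes)
            assert row["a"] == len(row["overlap"])
            expected = fisher_enrichment_p(row["a"], row["b"], row["c"], row["d"])
            assert row["p_value"] == pytest.approx(expected)

    def test_phenotype_outside_universe_skipped(self, toy_interactome):
        catalog = PhenotypeCatalog(entries={"ghost": {"Q1", "Q2"}})
        net = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        table = pfx.associate_phenotypes(net, catalog, toy_interactome.nodes)
        assert table.empty


class TestNullFilter:
    def test_retained_iff_p_below_null_median(self, toy_interactome, toy_catalog):
        net = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        table = pfx.associate_phenotypes(net, toy_catalog, toy_interactome.nodes)
        out = pfx.null_filter(table, toy_interactome, toy_catalog, 1, n_iter=25, seed=4)
        assert (out["retained"] == (out["p_value"] < out["null_median_p"])).all()

    def test_null_model_cache_reused_and_deterministic(self, toy_interactome, toy_catalog):
        null = pfx.RandomNetworkNull(toy_interactome, toy_catalog, n_iter=10, seed=4)
        first = null.median_p(1)
        assert null.median_p(1) is first  # cached
        fresh = pfx.RandomNetworkNull(toy_interactome, toy_catalog, n_iter=10, seed=4)
        pd.testing.assert_series_equal(first, fresh.median_p(1))

    def test_target_pool_restricts_draws(self, toy_interactome, toy_catalog):
        null = pfx.RandomNetworkNull(
            toy_interactome, toy_catalog, n_iter=5, seed=1, target_pool={"T", "A"}
        )
        assert null.pool == ["A", "T"]
        with pytest.raises(ValueError, match="exceeds pool size"):
            null.median_p(3)

    def test_n_targets_validated(self, toy_interactome, toy_catalog):
        null = pfx.RandomNetworkNull(toy_interactome, toy_catalog, n_iter=5, seed=1)
        with pytest.raises(ValueError):
            null.median_p(0)


class TestBHFilter:
    def test_adjusts_only_null_retained_rows(self):
        table = pd.DataFrame(
            {
                "drug_id": ["D"] * 4,
                "phenotype": list("wxyz"),
                "overlap": [()] * 4,
                "p_value": [0.01, 0.02, 0.04, 0.05],
                "retained": [True, True, False, True],
            }
        )
        out = pfx.bh_filter(table, alpha=0.05)
        assert np.isnan(out.loc[2, "adjusted_p"])
        assert not out.loc[2, "retained"]
        # BH over the three retained p-values only
        assert out.loc[0, "adjusted_p"] == pytest.approx(0.03)
        assert out.loc[1, "adjusted_p"] == pytest.approx(0.03)
        assert out.loc[3, "adjusted_p"] == pytest.approx(0.05)
        assert out["retained"].tolist() == [True, True, False, True]

    def test_alpha_cutoff_applied(self):
        table = pd.DataFrame(
            {
                "drug_id": ["D"] * 2,
                "phenotype": ["x", "y"],
                "overlap": [()] * 2,
                "p_value": [0.001, 0.8],
                "retained": [True, True],
            }
        )
        out = pfx.bh_filter(table, alpha=0.05)
        assert out["retained"].tolist() == [True, False]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            pfx.bh_filter(pd.DataFrame({"retained": []}), alpha=1.5)


class TestSummary:
    @staticmethod
    def _table(drug, rows):
        return pd.DataFrame(
            [
                {
                    "drug_id": drug,
                    "phenotype": ph,
                    "overlap": ov,
                    "p_value": 0.01,
                    "retained": kept,
                }
                for ph, ov, kept in rows
            ]
        )

    def test_counts(self):
        tables = {
            "DB1": self._table("DB1", [("p1", ("G1", "G2"), True), ("p2", ("G1",), False)]),
            "DB2": self._table("DB2", [("p1", ("G2",), True), ("p3", ("G3",), True)]),
        }
        s = pfx.summarize_predictions(tables)
        assert s["total_pairs"] == 3
        assert s["n_unique_drugs"] == 2
        assert s["drugs_per_phenotype"].to_dict() == {"p1": 2, "p3": 1}
        assert s["gene_ranking"].to_dict() == {"G2": 2, "G1": 1, "G3": 1}

    def test_label_filter(self):
        tables = {
            "DB1": self._table("DB1", [("p1", ("G1",), True), ("p2", ("G2",), True)]),
        }
        s = pfx.summarize_predictions(tables, labels={"p2"})
        assert s["total_pairs"] == 1
        assert s["drugs_per_phenotype"].to_dict() == {"p2": 1}

    def test_empty_tables(self):
        s = pfx.summarize_predictions({"DB1": pd.DataFrame()})
        assert s["total_pairs"] == 0 and s["n_unique_drugs"] == 0


class TestNetworkFiles:
    def test_files_written_with_expected_rows(self, toy_interactome, toy_catalog, tmp_path):
        net = pfx.build_drug_network(toy_interactome, "DB00001", ["T"], 2)
        table = pfx.associate_phenotypes(net, toy_catalog, toy_interactome.nodes)
        table["retained"] = table["p_value"] < 1.0
        merged, node_type = pfx.write_network_files(net, table, tmp_path)
        assert merged.exists() and node_type.exists()
        lines = node_type.read_text().splitlines()
        assert lines[0] == "node\ttype"
        kinds = {l.split("\t")[1] for l in lines[1:]}
        assert {"drug", "target", "downstream"} <= kinds
        merged_lines = merged.read_text().splitlines()
        assert any("drug_target" in l for l in merged_lines)
        assert any("interaction" in l for l in merged_lines)
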