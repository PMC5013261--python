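import itertools
import math

import numpy as np
import pytest

from _oracles import normalized_ranks_by_sorting, statistic_by_pair_enumeration
from conftest import make_pathway
from pathlink.enrichment import (
    EnrichmentConfig,
    NotEvaluable,
    enrich_all,
    magnitude,
    pathway_statistic,
    permutation_pvalue,
    project_to_nodes,
    rank_transform,
    results_frame,
)
from pathlink.expression_io import ExpressionDataset, MeasureType
from pathlink.pathway_model import PathwayGraph, PathwayUniverse, node_distances


def ds(values, measure=MeasureType.ONE_MINUS_P):
    return ExpressionDataset(code="X", measure_type=measure, values=values)


CFG = EnrichmentConfig(permutations=999, seed=0)


class TestConfig:
    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(lambda_decay=0.0)

    def test_rejects_unknown_statistic(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            EnrichmentConfig(statistic_name="other")


class TestMagnitude:
    def test_log2_absolute_value(self):
        assert magnitude(ds({"g1": -2.0}, MeasureType.LOG2_RATIO)) == {"g1": 2.0}

    def test_one_minus_p_unchanged(self):
        assert magnitude(ds({"g1": 0.99})) == {"g1": 0.99}

    def test_indicator_unchanged(self):
        assert magnitude(ds({"g1": 1.0, "g2": 0.0}, MeasureType.INDICATOR)) == {
            "g1": 1.0, "g2": 0.0}


class TestRankTransform:
    def test_average_tie_example(self):
        rho = rank_transform({"g1": 0.9, "g2": 0.2, "g3": 0.9, "g4": 0.1})
        assert rho == pytest.approx(
            {"g1": 0.875, "g2": 0.5, "g3": 0.875, "g4": 0.25})

    def test_full_tie(self):
        n = 5
        rho = rank_transform({f"g{i}": 0.4 for i in range(n)})
        assert all(v == pytest.approx((n + 1) / (2 * n)) for v in rho.values())

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(13)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.random(1000))}
        expected = normalized_ranks_by_sorting(values)
        rho = rank_transform(values)
        for g in values:
            assert rho[g] == pytest.approx(expected[g])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_transform({})


class TestProjectToNodes:
    def test_max_over_measured_genes(self):
        p = PathwayGraph(pathway_id="p", nodes={"n1"}, edges=set(),
                         node_genes={"n1": {"g1", "g2"}})
        assert project_to_nodes(p, {"g1": 0.2, "g2": 0.9}) == {"n1": 0.9}

    def test_unmeasured_node_absent(self):
        p = PathwayGraph(pathway_id="p", nodes={"n1", "n2"}, edges=set(),
                         node_genes={"n1": {"g1"}, "n2": {"gX"}})
        assert project_to_nodes(p, {"g1": 0.5}) == {"n1": 0.5}

    def test_one_gene_per_node_is_rekeying(self):
        p = make_pathway("p", ["g1", "g2", "g3"])
        rho = {"g1": 0.1, "g2": 0.5, "g3": 0.9}
        assert project_to_nodes(p, rho) == {
            "p.n1": 0.1, "p.n2": 0.5, "p.n3": 0.9}


class TestPathwayStatistic:
    def test_two_nodes_one_edge(self):
        p = make_pathway("p", ["g1", "g2"])
        rho_node = {"p.n1": 0.5, "p.n2": 1.0}
        s = pathway_statistic(p, rho_node, node_distances(p), CFG)
        assert s == pytest.approx(2.0)

    def test_three_node_path_hand_value(self):
        p = make_pathway("p", ["ga", "gb", "gc"])
        rho_node = {"p.n1": 1.0, "p.n2": 0.5, "p.n3": 0.25}
        s = pathway_statistic(p, rho_node, node_distances(p), CFG)
        assert s == pytest.approx(2.5)

    def test_edgeless_graph_is_plain_sum(self):
        p = make_pathway("p", ["g1", "g2", "g3"], chain=False)
        rho_node = {"p.n1": 0.3, "p.n2": 0.6, "p.n3": 0.9}
        s = pathway_statistic(p, rho_node, node_distances(p), CFG)
        assert s == pytest.approx(1.8)

    def test_mean_rank_statistic(self):
        p = make_pathway("p", ["g1", "g2"])
        cfg = EnrichmentConfig(statistic_name="mean_rank")
        s = pathway_statistic(p, {"p.n1": 0.5, "p.n2": 1.0},
                              node_distances(p), cfg)
        assert s == pytest.approx(0.75)

    def test_empty_rho_not_evaluable(self):
        p = make_pathway("p", ["g1"])
        with pytest.raises(NotEvaluable):
            pathway_statistic(p, {}, node_distances(p), CFG)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            nodes = [f"n{i}" for i in range(n)]
            edges = {frozenset((a, b))
                     for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4}
            p = PathwayGraph(pathway_id="p", nodes=set(nodes), edges=edges,
                             node_genes={x: {x} for x in nodes})
            rho_node = {x: float(rng.random()) for x in nodes}
            table = node_distances(p)
            expected = statistic_by_pair_enumeration(
                rho_node, dict(table.dist), CFG.lambda_decay, CFG.max_distance)
            s = pathway_statistic(p, rho_node, table, CFG)
            assert s == pytest.approx(expected)


class TestPermutationPvalue:
    def test_full_tie_gives_p_one(self):
        p = make_pathway("p", ["g1", "g2"])
        rho = {f"g{i}": 0.5 for i in range(1, 8)}
        result = permutation_pvalue(p, rho, CFG)
        assert result.p_value == pytest.approx(1.0)

    def test_exhaustive_three_gene_universe(self):
        # pathway of one node/one gene holding the top rank of three:
        # exact null P(S_perm >= S_obs) = 1/3
        p = make_pathway("p", ["a"], chain=False)
        rho = rank_transform({"a": 0.9, "b": 0.5, "c": 0.1})
        R = 20000
        cfg = EnrichmentConfig(permutations=R, seed=2)
        result = permutation_pvalue(p, rho, cfg)
        exact = 1 / 3
        se = math.sqrt(exact * (1 - exact) / R)
        assert abs(result.p_value - exact) <= 3 * se

    def test_planted_top_genes_hit_floor(self):
        genes = [f"p{i}" for i in range(20)]
        p = make_pathway("P", genes)
        background = {f"b{i}": float(i) / 3000 for i in range(1980)}
        values = {**background, **{g: 0.9 + i / 1000 for i, g in enumerate(genes)}}
        rho = rank_transform(values)
        cfg = EnrichmentConfig(permutations=999, seed=3)
        result = permutation_pvalue(p, rho, cfg)
        assert result.p_value == pytest.approx(1 / 1000)

    def test_no_measured_genes_not_evaluable(self):
        p = make_pathway("p", ["gX"])
        result = permutation_pvalue(p, {"g1": 0.5, "g2": 0.1}, CFG)
        assert not result.evaluable
        assert result.n_measured_genes == 0
        assert math.isnan(result.p_value)

    def test_p_value_floor_invariant(self):
        rng = np.random.default_rng(37)
        p = make_pathway("p", ["g1", "g2", "g3", "g4"])
        rho = {f"g{i}": float(rng.random()) for i in range(1, 30)}
        cfg = EnrichmentConfig(permutations=99, seed=1)
        result = permutation_pvalue(p, rho, cfg)
        assert result.p_value >= 1 / 100

    def test_monotone_transform_leaves_p_unchanged(self):
        rng = np.random.default_rng(41)
        p = make_pathway("p", ["g1", "g2", "g3", "g4"])
        raw = {f"g{i}": float(rng.random()) for i in range(1, 50)}
        cfg = EnrichmentConfig(permutations=499, seed=6)
        p_raw = permutation_pvalue(p, rank_transform(raw), cfg).p_value
        bent = {g: math.atan(5 * v) for g, v in raw.items()}  # strictly monotone
        p_bent = permutation_pvalue(p, rank_transform(bent), cfg).p_value
        assert p_raw == p_bent


class TestEnrichAll:
    def _universe(self, n=1):
        return PathwayUniverse(pathways=[
            make_pathway(f"p{i}", [f"g{i}_{j}" for j in range(4)])
            for i in range(n)])

    def test_one_result_per_pathway_in_order(self):
        universe = self._universe(3)
        values = {f"g{i}_{j}": (i + j + 1) / 20 for i in range(3) for j in range(4)}
        results = enrich_all(universe, ds(values), CFG)
        assert [r.pathway_id for r in results] == ["p0", "p1", "p2"]

    def test_disjoint_dataset_all_non_evaluable(self):
        universe = self._universe(2)
        results = enrich_all(universe, ds({"other": 0.5}), CFG)
        assert all(not r.evaluable for r in results)

    def test_deterministic_across_runs(self):
        universe = self._universe(4)
        rng = np.random.default_rng(43)
        values = {f"g{i}_{j}": float(rng.random())
                  for i in range(4) for j in range(4)}
        a = enrich_all(universe, ds(values), CFG)
        b = enrich_all(universe, ds(values), CFG)
        assert results_frame(a).equals(results_frame(b))

    def test_lambda_zero_limit_matches_mean_rank_order_on_edgeless(self):
        # with D=1 on edgeless graphs pair terms vanish; the two statistics
        # order pathways identically
        universe = PathwayUniverse(pathways=[
            make_pathway(f"p{i}", [f"g{i}_{j}" for j in range(4)], chain=False)
            for i in range(5)])
        rng = np.random.default_rng(47)
        values = {f"g{i}_{j}": float(rng.random())
                  for i in range(5) for j in range(4)}
        cfg_top = EnrichmentConfig(lambda_decay=1e-9, max_distance=1,
                                   permutations=99, seed=5)
        cfg_mean = EnrichmentConfig(statistic_name="mean_rank",
                                    permutations=99, seed=5)
        s_top = [r.statistic for r in enrich_all(universe, ds(values), cfg_top)]
        s_mean = [r.statistic for r in enrich_all(universe, ds(values), cfg_mean)]
        assert np.argsort(s_top).tolist() == np.argsort(s_mean).tolist()

    def test_indicator_warns_low_resolution(self, caplog):
        universe = self._universe(1)
        values = {"g0_0": 1.0, "g0_1": 0.0, "g0_2": 0.0, "g0_3": 1.0}
        with caplog.at_level("WARNING"):
            enrich_all(universe, ds(values, MeasureType.INDICATOR), CFG)
        assert any("low resolution" in r.message for r in caplog.records)


class TestScorerAgreesWithScalarPath:
    """Dual route: the vectorized scorer must equal the scalar formula."""

    def test_random_graphs_with_multi_gene_nodes(self):
        rng = np.random.default_rng(53)
        for _ in range(15):
            n = int(rng.integers(2, 6))
            nodes = [f"n{i}" for i in range(n)]
            edges = {frozenset((a, b))
                     for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.5}
            node_genes = {}
            gid = 0
            for x in nodes:
                k = int(rng.integers(1, 4))
                node_genes[x] = {f"g{gid + i}" for i in range(k)}
                gid += k
            # one shared gene across two nodes to exercise slot expansion
            if n >= 2:
                node_genes[nodes[1]].add(next(iter(node_genes[nodes[0]])))
            p = PathwayGraph(pathway_id="p", nodes=set(nodes), edges=edges,
                             node_genes=node_genes)
            rho = {f"g{i}": float(rng.random()) for i in range(gid)}
            result = permutation_pvalue(p, rho, EnrichmentConfig(
                permutations=9, seed=1))
            expected = pathway_statistic(
                p, project_to_nodes(p, rho), node_distances(p), CFG)
            assert result.statistic == pytest.approx(expected)
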