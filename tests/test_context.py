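import numpy as np
import pytest

from mpxwalk import (
    GeneSet,
    NetworkLayer,
    RWRParams,
    make_multiplex_from_layers,
    merged_with_all_edgecounts,
    merged_with_all_layers,
    net_to_net_similarity,
    rewire_multiplex,
    run_loe,
    shortest_paths,
)
from mpxwalk.context import PATH_COLUMNS
from mpxwalk.fixtures import er_layers, three_layer_toy


def star_multiplex(n_leaves=5):
    edges = [("hub", f"leaf{i}", 1.0) for i in range(n_leaves)]
    return make_multiplex_from_layers([NetworkLayer("star", edges)])


class TestRunLoe:
    def test_star_leaves_tie_at_rank_one(self):
        mpx = star_multiplex()
        res, _ = run_loe(mpx, GeneSet("s", ["hub"]))
        leaf_idx = [mpx.node_index[f"leaf{i}"] for i in range(5)]
        assert all(res.ranks[i] == 1 for i in leaf_idx)

    def test_second_gene_set_is_flagged(self, tau_mpx):
        res, sub = run_loe(
            tau_mpx, GeneSet("s", ["A"]), GeneSet("t", ["C"]), top_n=3
        )
        flagged = sub.nodes.loc[sub.nodes["in_second_set"], "gene"].tolist()
        assert flagged == ["C"]

    def test_subnetwork_contains_seeds_plus_top_n(self, tau_mpx):
        res, sub = run_loe(tau_mpx, GeneSet("s", ["A", "B"]), top_n=1)
        assert len(sub.nodes) <= 3  # 2 seeds + top 1
        genes = set(sub.nodes["gene"])
        assert {"A", "B"} <= genes
        # every edge endpoint is a subnetwork node, one row per (pair, layer)
        assert set(sub.edges["source"]) | set(sub.edges["target"]) <= genes
        ab_rows = sub.edges[
            (sub.edges[["source", "target"]].apply(sorted, axis=1).map(tuple))
            == ("A", "B")
        ]
        assert sorted(ab_rows["layer"]) == ["clique", "path"]

    def test_top_n_clamped_with_warning(self, tau_mpx):
        with pytest.warns(UserWarning, match="clamp"):
            _, sub = run_loe(tau_mpx, GeneSet("s", ["A", "B"]), top_n=99)
        assert sub is not None


class TestShortestPaths:
    def test_adjacent_pair_single_edge(self, tau_mpx):
        df = shortest_paths(
            tau_mpx, GeneSet("s", ["C"]), GeneSet("t", ["D"])
        )
        assert list(df.columns) == PATH_COLUMNS
        assert (df["path_length"] == 2).all()
        assert df["path_elements"].iloc[0] == "C->D"
        # C-D exists only in the 6-edge clique layer: weight_norm = 1/6
        assert df["weight_norm"].iloc[0] == pytest.approx(1 / 6)

    def test_edge_in_multiple_layers_yields_one_row_per_layer(self, tau_mpx):
        df = shortest_paths(tau_mpx, GeneSet("s", ["A"]), GeneSet("t", ["B"]))
        assert sorted(df["type"]) == ["clique", "path"]
        norm = dict(zip(df["type"], df["weight_norm"]))
        assert norm["path"] == pytest.approx(1.0)   # 1 / total weight 1
        assert norm["clique"] == pytest.approx(1 / 6)

    def test_weight_norm_is_weight_over_layer_total(self):
        m = 1359
        nodes = [f"g{i:05d}" for i in range(m + 1)]
        edges = [(nodes[i], nodes[i + 1], 1.0) for i in range(m)]
        mpx = make_multiplex_from_layers([NetworkLayer("RE", edges)])
        df = shortest_paths(
            mpx, GeneSet("s", [nodes[0]]), GeneSet("t", [nodes[2]])
        )
        assert (df["path_length"] == 3).all()
        assert df["weight_norm"].iloc[0] == pytest.approx(1 / 1359)

    def test_path_length_counts_nodes(self):
        mpx = star_multiplex()
        df = shortest_paths(
            mpx, GeneSet("s", ["leaf0"]), GeneSet("t", ["leaf1"])
        )
        # leaf0 -> hub -> leaf1: 3 nodes, 2 edges, one record per edge
        assert (df["path_length"] == 3).all() and len(df) == 2
        assert (df["path_name"] == "leaf0_leaf1").all()

    def test_unreachable_pair_flagged(self):
        layers = [NetworkLayer("l", [("a", "b", 1.0), ("c", "d", 1.0)])]
        mpx = make_multiplex_from_layers(layers)
        df = shortest_paths(mpx, GeneSet("s", ["a"]), GeneSet("t", ["c"]))
        assert (df["type"] == "NO_PATH").all()

    def test_absent_gene_warns_and_skips(self, tau_mpx):
        with pytest.warns(UserWarning, match="absent"):
            df = shortest_paths(
                tau_mpx, GeneSet("s", ["ghost", "A"]), GeneSet("t", ["B"])
            )
        assert set(df["path_name"]) == {"A_B"}

    def test_deterministic_lexicographic_choice_vs_all_paths(self):
        # two equally short a-d paths: a-b-d and a-c-d
        layers = [NetworkLayer("l", [("a", "b", 1.0), ("b", "d", 1.0),
                                     ("a", "c", 1.0), ("c", "d", 1.0)])]
        mpx = make_multiplex_from_layers(layers)
        one = shortest_paths(mpx, GeneSet("s", ["a"]), GeneSet("t", ["d"]))
        assert set(one["path_elements"]) == {"a->b->d"}
        both = shortest_paths(
            mpx, GeneSet("s", ["a"]), GeneSet("t", ["d"]), all_paths=True
        )
        assert set(both["path_elements"]) == {"a->b->d", "a->c->d"}


class TestAggregation:
    def test_pair_weight_counts_carrying_layers(self):
        mpx = three_layer_toy()
        mono = merged_with_all_edgecounts(mpx)
        weights = {
            (r.source, r.target): r.weight for r in mono.itertuples()
        }
        # c-d appears in layers 1 and 3; a-b in layers 1 and 2
        assert weights[("c", "d")] == 2.0
        assert weights[("a", "b")] == 2.0
        assert weights[("b", "c")] == 1.0

    def test_row_counts_conserved(self):
        mpx = three_layer_toy()
        multi = merged_with_all_layers(mpx)
        mono = merged_with_all_edgecounts(mpx)
        assert len(multi) == sum(lyr.n_edges for lyr in mpx.layers)
        union = {
            lyr.edge_key(u, v) for lyr in mpx.layers for u, v, _ in lyr.edges
        }
        assert len(mono) == len(union)
        assert mono["weight"].sum() == len(multi)


class TestRewiring:
    def test_node_and_edge_counts_preserved(self):
        mpx = make_multiplex_from_layers(er_layers(30, 3, p=0.2, rng_seed=1))
        null = rewire_multiplex(mpx, rng_seed=4)
        for orig, new in zip(mpx.layers, null.layers):
            assert new.n_edges == orig.n_edges
            assert new.nodes == orig.nodes

    def test_degree_sequences_preserved(self):
        mpx = make_multiplex_from_layers(er_layers(30, 2, p=0.2, rng_seed=2))
        null = rewire_multiplex(mpx, rng_seed=8)
        for orig, new in zip(mpx.layers, null.layers):
            deg_o = sorted(d for _, d in orig.to_graph().degree())
            deg_n = sorted(d for _, d in new.to_graph().degree())
            assert deg_o == deg_n

    def test_same_seed_gives_identical_null(self):
        mpx = make_multiplex_from_layers(er_layers(25, 2, p=0.2, rng_seed=3))
        a = rewire_multiplex(mpx, rng_seed=11)
        b = rewire_multiplex(mpx, rng_seed=11)
        assert a.equals(b)

    def test_rewired_layers_share_few_edges_with_originals(self):
        # sparse ER: expected per-edge overlap ~ 2m/n^2, so jaccard stays low
        rng_seeds = range(20)
        sims = []
        for s in rng_seeds:
            mpx = make_multiplex_from_layers(
                er_layers(60, 1, m=80, rng_seed=100 + s)
            )
            null = rewire_multiplex(mpx, rng_seed=200 + s)
            sims.append(
                net_to_net_similarity(mpx.layers[0], null.layers[0], "jaccard")
            )
        assert np.mean(sims) < 0.2

    def test_tiny_layer_returned_unchanged_with_warning(self):
        lyr = NetworkLayer("tiny", [("a", "b", 1.0)])
        mpx = make_multiplex_from_layers([lyr])
        with pytest.warns(UserWarning, match="too small"):
            null = rewire_multiplex(mpx, rng_seed=0)
        assert null.layers[0].edges == lyr.edges

    def test_er_null_preserves_edge_count(self):
        mpx = make_multiplex_from_layers(er_layers(30, 2, p=0.2, rng_seed=5))
        null = rewire_multiplex(mpx, rng_seed=6, method="er")
        for orig, new in zip(mpx.layers, null.layers):
            assert new.n_edges == orig.n_edges
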