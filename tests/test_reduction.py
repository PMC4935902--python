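"""Clusters, convergent sets, and the full/partial reduction pipeline."""

import pytest

from phylonetdist import (
    GeneratorConfig,
    build_network,
    collapse_pendant_subtrees,
    expand_pendant_subtrees,
    leaf_clusters,
    load_fixture,
    maximal_convergent_sets,
    oracle_isomorphic,
    random_network,
    reduce_network,
    remove_convergent_paths,
    replay_trace,
    superconvergent_sets,
    suppress_unary_nodes,
)


class TestClusters:
    def test_root_reaches_all_taxa(self, fig1_pair):
        n1, _ = fig1_pair
        clusters = leaf_clusters(n1)
        assert clusters["R"].leaves == {"1", "2", "3", "4", "x"}

    def test_convergent_trio_shares_cluster(self, fig1_pair):
        clusters = leaf_clusters(fig1_pair[0])
        assert clusters["H1"].leaves == clusters["H2"].leaves == clusters["G"].leaves == {"x"}

    def test_leaf_cluster_is_own_label(self, fig1_pair):
        clusters = leaf_clusters(fig1_pair[0])
        for leaf in fig1_pair[0].leaves:
            assert clusters[leaf].leaves == {fig1_pair[0].leaf_labels[leaf]}

    def test_cluster_is_union_of_children(self, small_random_pool):
        for net in small_random_pool[:10]:
            clusters = leaf_clusters(net)
            for n in net.nodes:
                cs = net.children(n)
                if cs:
                    union = frozenset().union(*(clusters[c].leaves for c in cs))
                    assert clusters[n].leaves == union


class TestConvergentSets:
    def test_fig1_has_exactly_one_maximal_set_each(self, fig1_pair):
        n1, n2 = fig1_pair
        (s1,) = maximal_convergent_sets(n1)
        assert s1.members == {"H1", "H2", "G"}
        (s2,) = maximal_convergent_sets(n2)
        assert s2.members == {"h1", "h2", "g"}

    def test_trees_have_no_convergent_sets(self):
        """In a strict tree all internal clusters are distinct."""
        for seed in range(15):
            tree = random_network(GeneratorConfig(n_leaves=5, n_reticulations=0, seed=seed))
            assert maximal_convergent_sets(tree) == []
            # brute-force confirmation: pairwise distinct internal clusters
            clusters = leaf_clusters(tree)
            internals = [n for n in tree.nodes if tree.outdeg(n) >= 1]
            seen = [clusters[n].leaves for n in internals]
            assert len(seen) == len(set(seen))

    def test_fig4_superconvergent_is_exactly_hj(self, fig4_pair):
        for net in fig4_pair:
            (s,) = superconvergent_sets(net)
            assert s.members == {"H", "J"}

    def test_fig1_has_no_superconvergent_set(self, fig1_pair):
        for net in fig1_pair:
            assert superconvergent_sets(net) == []

    def test_partly_reduced_outputs_have_none(self, partly_reduced_pool):
        for net in partly_reduced_pool:
            assert superconvergent_sets(net) == []


class TestPendantSubtrees:
    def test_fig2_collapse_matches_stage_fixture(self):
        collapsed, registry = collapse_pendant_subtrees(load_fixture("fig2_N"))
        assert oracle_isomorphic(collapsed.copy(strict=True), load_fixture("fig2_N0"))
        # four multi-leaf pendants plus the two bare leaves 3 and 6
        assert len(registry.entries) == 6

    def test_collapse_then_expand_is_identity(self):
        for name in ("fig1_N1", "fig2_N", "fig4_N1"):
            net = load_fixture(name)
            collapsed, registry = collapse_pendant_subtrees(net)
            assert oracle_isomorphic(expand_pendant_subtrees(collapsed, registry), net)

    def test_pure_tree_passes_through(self):
        tree = random_network(GeneratorConfig(n_leaves=4, n_reticulations=0, seed=2))
        collapsed, registry = collapse_pendant_subtrees(tree)
        assert collapsed is tree
        assert registry.entries == {}


class TestRemovalAndSuppression:
    def test_fig1_removal_rewires_parents_onto_g(self, fig1_pair):
        n1, _ = fig1_pair
        collapsed, _ = collapse_pendant_subtrees(n1)
        (conv,) = maximal_convergent_sets(collapsed)
        out = remove_convergent_paths(collapsed, conv)
        # H1, H2 deleted; their former parents now feed G directly
        assert "H1" not in out.nodes and "H2" not in out.nodes
        assert set(out.parents("G")) == {"C", "D", "E", "F"}

    def test_fig2_stage_two_matches_fixture(self):
        collapsed, _ = collapse_pendant_subtrees(load_fixture("fig2_N"))
        (conv,) = maximal_convergent_sets(collapsed)
        out = suppress_unary_nodes(remove_convergent_paths(collapsed, conv))
        assert oracle_isomorphic(out.copy(strict=True), load_fixture("fig2_N1"))

    def test_unary_chain_collapses(self):
        net = build_network(
            [("r", "a"), ("a", "b"), ("b", "l"), ("r", "m")],
            {"l": "x", "m": "y"},
            strict=False,
        )
        out = suppress_unary_nodes(net)
        assert out.edges == {("r", "l"), ("r", "m")}

    def test_suppression_is_fixpoint_on_clean_networks(self, fig1_pair):
        n1, _ = fig1_pair
        out = suppress_unary_nodes(n1)
        assert out.edges == n1.edges


class TestReducePipeline:
    def test_fig1_reductions_agree_with_fig3(self, fig1_pair):
        n1, n2 = fig1_pair
        r1, _ = reduce_network(n1, "full")
        r2, _ = reduce_network(n2, "full")
        assert oracle_isomorphic(r1, r2)
        assert oracle_isomorphic(r1, load_fixture("fig3_reduced"))
        # ... although the inputs themselves are not isomorphic
        assert not oracle_isomorphic(n1, n2)

    def test_fig2_full_reduction_matches_fixture(self):
        red, _ = reduce_network(load_fixture("fig2_N"), "full")
        assert oracle_isomorphic(red, load_fixture("fig2_N2"))

    def test_partial_mode_fixes_fig1(self, fig1_pair):
        for net in fig1_pair:
            out, _ = reduce_network(net, "partial")
            assert oracle_isomorphic(out, net)

    def test_partial_mode_merges_fig4_cascade(self, fig4_pair):
        outs = []
        for net in fig4_pair:
            out, _ = reduce_network(net, "partial")
            assert "H" not in out.nodes and "J" not in out.nodes
            assert superconvergent_sets(out) == []
            outs.append(out)
        assert oracle_isomorphic(*outs)

    @pytest.mark.parametrize("mode", ["full", "partial"])
    def test_idempotence_and_taxa_preservation(self, mode, small_random_pool):
        for net in small_random_pool[:12]:
            out, _ = reduce_network(net, mode)
            assert out.taxa == net.taxa
            again, _ = reduce_network(out, mode)
            assert oracle_isomorphic(again, out)

    def test_full_output_is_partial_fixpoint(self, small_random_pool):
        """Reduced networks live inside the partly reduced space."""
        for net in small_random_pool[:12]:
            full, _ = reduce_network(net, "full")
            partial_again, _ = reduce_network(full, "partial")
            assert oracle_isomorphic(partial_again, full)

    def test_trace_replay_reproduces_output(self):
        for name in ("fig1_N1", "fig2_N", "fig4_N2"):
            net = load_fixture(name)
            out, trace = reduce_network(net, "full")
            assert oracle_isomorphic(replay_trace(net, trace), out)

    def test_removal_order_does_not_matter_on_fixtures(self, fig4_pair):
        """Processing the two maximal sets of the separation-failure network
        in either order yields isomorphic reduced versions."""
        net = fig4_pair[0]
        collapsed, _ = collapse_pendant_subtrees(net)
        sets = maximal_convergent_sets(collapsed)
        assert len(sets) == 2
        results = []
        for order in (sets, sets[::-1]):
            current = collapsed
            for conv in order:
                refreshed = [
                    s for s in maximal_convergent_sets(current)
                    if s.leaf_set == conv.leaf_set
                ]
                if refreshed:
                    current = suppress_unary_nodes(
                        remove_convergent_paths(current, refreshed[0])
                    )
            results.append(current)
        assert oracle_isomorphic(*results)
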