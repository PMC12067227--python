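"""Synthesis core: exemplification, decomposition, greedy BUILD assembly."""

import numpy as np
import pytest

from phylosynth.simgen import sample_input_trees, simulate_true_tree
from phylosynth.synth import (
    Subproblem,
    SynthError,
    exemplify,
    find_uncontested,
    solve_subproblem,
    synthesize,
)
from phylosynth.taxa import TaxonRecord, Taxonomy
from phylosynth.trees import (
    InputTree,
    assign_node_ids,
    clusters_of,
    default_ranking,
    leaf_labels,
    leafset,
    parse_newick,
    rf_distance,
    tree_to_newick,
)

from conftest import all_rooted_binary_newicks, make_taxonomy


def make_subspecies_taxonomy():
    records = [
        TaxonRecord("root", None, "root", "class"),
        TaxonRecord("g1", "root", "g1", "genus"),
        TaxonRecord("sp1", "g1", "sp1", "species"),
        TaxonRecord("sp1_a", "sp1", "sp1 a", "other"),
        TaxonRecord("sp1_b", "sp1", "sp1 b", "other"),
        TaxonRecord("sp2", "g1", "sp2", "species"),
        TaxonRecord("sp3", "g1", "sp3", "species"),
    ]
    return Taxonomy(records)


class TestExemplify:
    def test_subspecies_collapse_to_one_exemplar(self):
        tax = make_subspecies_taxonomy()
        itree = InputTree("t", "s", 2020, parse_newick("((sp1_a,sp1_b),sp2);"))
        out = exemplify(itree, tax)
        assert out.leaves == frozenset({"sp1", "sp2"})

    def test_species_level_tree_unchanged(self):
        tax = make_subspecies_taxonomy()
        itree = InputTree("t", "s", 2020, parse_newick("((sp1,sp2),sp3);"))
        out = exemplify(itree, tax)
        assert clusters_of(out.tree) == clusters_of(itree.tree)

    def test_exemplar_is_lexicographically_smallest(self):
        # sp1_a and sp1_b both map to sp1; the rule must keep sp1_a's slot.
        # Verify by brute force: of the two possible prunings, the result
        # matches the one that keeps the smaller original label.
        tax = make_subspecies_taxonomy()
        itree = InputTree("t", "s", 2020, parse_newick("((sp1_a,sp2),(sp1_b,sp3));"))
        out = exemplify(itree, tax)
        keep_a = clusters_of(parse_newick("((sp1,sp2),sp3);"))
        keep_b = clusters_of(parse_newick("(sp2,(sp1,sp3));"))
        assert clusters_of(out.tree) == keep_a
        assert clusters_of(out.tree) != keep_b

    def test_uninformative_after_exemplification_errors(self):
        tax = make_subspecies_taxonomy()
        itree = InputTree("t", "s", 2020, parse_newick("(sp1_a,sp1_b);"))
        with pytest.raises(SynthError, match="uninformative"):
            exemplify(itree, tax)


class TestFindUncontested:
    def test_conflicting_input_dissolves_genera(self, taxonomy_two_genera):
        itree = exemplify(
            InputTree("t", "s", 2020, parse_newick("((A,C),(B,D));")),
            taxonomy_two_genera,
        )
        subs = find_uncontested(taxonomy_two_genera, [itree])
        # g1 and g2 contested and dissolved; f1 (spanning all species,
        # hence conflict-free) is the single real subproblem
        roots = {s.root_taxon for s in subs}
        assert "g1" not in roots and "g2" not in roots
        f1 = next(s for s in subs if s.root_taxon == "f1")
        assert f1.leafset == frozenset({"A", "B", "C", "D"})

    def test_no_input_trees_all_taxa_uncontested(self, taxonomy_two_genera):
        subs = find_uncontested(taxonomy_two_genera, [])
        roots = {s.root_taxon for s in subs}
        assert {"g1", "g2", "f1"} <= roots
        # every species in exactly one subproblem span at the finest level
        genus_spans = [s.span for s in subs if s.root_taxon in ("g1", "g2")]
        assert sorted(map(sorted, genus_spans)) == [["A", "B"], ["C", "D"]]

    def test_input_equal_to_taxonomy_keeps_smallest_groups(self, taxonomy_two_genera):
        itree = exemplify(
            InputTree("t", "s", 2020, parse_newick("((A,B),(C,D));")),
            taxonomy_two_genera,
        )
        subs = find_uncontested(taxonomy_two_genera, [itree])
        assert {"g1", "g2"} <= {s.root_taxon for s in subs}


def make_star_subproblem(leaves, ranked):
    """Subproblem over ``leaves`` with an uninformative (star) taxonomy."""
    star = parse_newick("(" + ",".join(sorted(leaves)) + ");")
    assign_node_ids(star)
    restricted = []
    for tid, newick in ranked:
        t = parse_newick(newick)
        assign_node_ids(t)
        restricted.append((tid, t))
    return Subproblem(
        root_taxon=None,
        leafset=frozenset(leaves),
        restricted_trees=restricted,
        taxonomy_tree=star,
        span=frozenset(leaves),
    )


class TestSolveSubproblem:
    def test_rank_one_wins_and_conflict_recorded(self):
        sub = make_star_subproblem(
            "ABC", [("r1", "((A,B),C);"), ("r2", "((A,C),B);")]
        )
        out = solve_subproblem(sub)
        assert clusters_of(out) == {frozenset("AB")}
        node = next(
            n for n in out.preorder_internal_node_iter() if leafset(n) == frozenset("AB")
        )
        assert any(tid == "r1" for tid, _ in node.supported_by)
        assert any(tid == "r2" for tid, _ in node.conflicts_with)

    def test_joint_satisfiability_across_leafsets(self):
        # r1 on {A,B,D} asserts AB|D; r2 on {A,C,D} asserts AC|D: jointly
        # satisfiable over {A,B,C,D}; the output must display both.
        sub = make_star_subproblem(
            "ABCD", [("r1", "((A,B),D);"), ("r2", "((A,C),D);")]
        )
        out = solve_subproblem(sub)
        out_clusters = clusters_of(out)

        def displays(cluster, context):
            return any(
                frozenset(c & context) == cluster
                for c in out_clusters | {leaf_labels(out)}
            )

        assert displays(frozenset("AB"), frozenset("ABD"))
        assert displays(frozenset("AC"), frozenset("ACD"))
        # cross-check against exhaustive enumeration: some 4-leaf binary
        # tree displays both constraints, and ours is among them
        witnesses = []
        for newick in all_rooted_binary_newicks("ABCD"):
            t = parse_newick(newick)
            cl = clusters_of(t) | {leaf_labels(t)}
            ok = all(
                any(frozenset(c & ctx) == want for c in cl)
                for want, ctx in [
                    (frozenset("AB"), frozenset("ABD")),
                    (frozenset("AC"), frozenset("ACD")),
                ]
            )
            if ok:
                witnesses.append(clusters_of(t))
        assert witnesses
        assert any(out_clusters <= w for w in witnesses)

    def test_mutually_compatible_inputs_all_displayed(self):
        sub = make_star_subproblem(
            "ABCDE",
            [("r1", "(((A,B),C),(D,E));"), ("r2", "((A,B),(D,E));")],
        )
        out = solve_subproblem(sub)
        pooled = clusters_of(parse_newick("(((A,B),C),(D,E));"))
        assert pooled <= clusters_of(out)

    def test_every_internal_edge_supported(self):
        sub = make_star_subproblem(
            "ABCDEF",
            [("r1", "(((A,B),C),(D,E));"), ("r2", "(((B,C),F),D);")],
        )
        out = solve_subproblem(sub)
        for node in out.preorder_internal_node_iter():
            if node is out.seed_node:
                continue
            assert node.supported_by, f"edge {sorted(leafset(node))} unsupported"


class TestSynthesize:
    def test_zero_inputs_equals_taxonomy(self, taxonomy_two_genera):
        synth = synthesize([], default_ranking([]), taxonomy_two_genera)
        assert rf_distance(synth.tree, taxonomy_two_genera.to_tree()) == 0
        for node in synth.tree.preorder_node_iter():
            if node is synth.tree.seed_node:
                continue
            assert synth.annotation(node).terminal

    def test_single_full_tree_reproduced(self, taxonomy_two_genera):
        itree = InputTree("t", "s", 2020, parse_newick("(((A,C),B),D);"))
        synth = synthesize([itree], default_ranking([("t", 2020, False)]),
                           taxonomy_two_genera)
        assert rf_distance(synth.tree, itree.tree) == 0

    def test_simulated_recovery(self):
        true_tree, tax = simulate_true_tree(24, seed=42)
        inputs = sample_input_trees(true_tree, 3, 24, 0.0, seed=43)
        ranking = default_ranking([(t.tree_id, t.year, t.demoted) for t in inputs])
        synth = synthesize(inputs, ranking, tax)
        assert rf_distance(synth.tree, true_tree) == 0

    def test_uncontested_taxa_monophyletic(self):
        true_tree, tax = simulate_true_tree(20, seed=5)
        inputs = sample_input_trees(true_tree, 5, 10, 0.0, seed=6)
        ranking = default_ranking([(t.tree_id, t.year, t.demoted) for t in inputs])
        synth = synthesize(inputs, ranking, tax)
        from phylosynth.conflict import monophyly_report

        pct, verdicts = monophyly_report(synth, tax, "genus")
        assert pct == 0.0

    def test_taxonomy_never_displaces_input_clusters(self):
        # synthesising with a deliberately conflicting taxonomy must leave
        # every input-supported cluster intact
        tax = make_taxonomy({"f1": {"g1": ["A", "C"], "g2": ["B", "D"]}})
        itree = InputTree("t", "s", 2020, parse_newick("(((A,B),C),D);"))
        synth = synthesize([itree], default_ranking([("t", 2020, False)]), tax)
        assert clusters_of(itree.tree) <= synth.clusters()

    def test_deterministic_output(self):
        true_tree, tax = simulate_true_tree(15, seed=9)
        inputs = sample_input_trees(true_tree, 4, 8, 0.5, seed=10)
        ranking = default_ranking([(t.tree_id, t.year, t.demoted) for t in inputs])
        first = synthesize(inputs, ranking, tax)
        second = synthesize(inputs, ranking, tax)
        assert first.newick() == second.newick()
        assert first.annotation_table() == second.annotation_table()

    def test_unsampled_species_attach_as_terminal_polytomy(self):
        tax = make_taxonomy({"f1": {"g1": ["A", "B", "E"], "g2": ["C", "D"]}})
        itree = InputTree("t", "s", 2020, parse_newick("((A,B),(C,D));"))
        synth = synthesize([itree], default_ranking([("t", 2020, False)]), tax)
        # E (unsampled) sits inside its genus g1 alongside A and B
        assert synth.leaves == frozenset("ABCDE")
        assert frozenset("ABE") in synth.clusters()
        leaf_e = next(
            l for l in synth.tree.leaf_node_iter() if l.taxon.label == "E"
        )
        assert synth.annotation(leaf_e).terminal

    def test_phylo_only_prunes_and_stays_supported(self):
        tax = make_taxonomy({"f1": {"g1": ["A", "B", "E"], "g2": ["C", "D"]}})
        itree = InputTree("t", "s", 2020, parse_newick("((A,B),(C,D));"))
        synth = synthesize([itree], default_ranking([("t", 2020, False)]), tax)
        phylo = synth.phylo_only()
        assert phylo.leaves == frozenset("ABCD")
        for node in phylo.tree.preorder_internal_node_iter():
            if node is phylo.tree.seed_node:
                continue
            assert phylo.annotation(node).input_supported
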