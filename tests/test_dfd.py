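"""Cluster detection, retention completeness, DFD classification, WGD mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfdscan.dfd import (
    DFDConfig,
    WGDEvent,
    analyze_family,
    assign_cluster_names,
    classify_dfd,
    count_dual_retainers,
    detect_clusters,
    expected_genetic_distance,
    is_double_gene_phylum,
    map_to_wgd,
    prune_hybrid_leaves,
    retention_completeness,
)
from dfdscan.reconcile import DuplicationEvent, Verdict, infer_duplications
from dfdscan.treekit import GeneTree, SpeciesTree, TreeError

ANCHORS = {"AmbtriGUS1": "1", "AmbtriGUS3": "3", "AmbtriGUS4": "4"}


class TestDetectClusters:
    def test_demo_has_three_top_level_clusters(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        assert len(asg.clusters) == 3
        for name in asg.clusters:
            assert all(asg.coverage[name].values())

    def test_demo_cluster3_splits_into_two_eudicot_sublineages(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        assert len(asg.subclusters) == 2
        subs = sorted(asg.subclusters.values(), key=sorted)
        assert subs == [frozenset({"NicsylGUS3.1"}), frozenset({"NicsylGUS3.2"})]

    def test_single_copy_tree_is_one_cluster(self, demo_config):
        g = GeneTree.from_newick("AmbtriGUS1;", family_tag="GUS")
        cfg = DFDConfig(required_phyla={"ancestral_angiosperms": frozenset({"Ambtri"})})
        asg = detect_clusters(g, cfg)
        assert list(asg.clusters.values()) == [frozenset({"AmbtriGUS1"})]

    def test_no_covering_clade_yields_empty_assignment(self, demo):
        cfg = DFDConfig(required_phyla={"mosses": frozenset({"Phypat"})})
        asg = detect_clusters(demo.gene_tree, cfg,
                              outgroup_labels=demo.outgroup)
        assert asg.clusters == {}

    def test_invariant_under_child_rotation(self, demo, demo_config):
        rotated = demo.gene_tree.copy()
        for node in rotated.dendropy_tree.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) > 1:
                node.set_child_nodes(list(reversed(kids)))
        a = detect_clusters(rotated, demo_config, outgroup_labels=demo.outgroup)
        b = detect_clusters(demo.gene_tree, demo_config,
                            outgroup_labels=demo.outgroup)
        assert sorted(map(sorted, a.clusters.values())) == sorted(
            map(sorted, b.clusters.values())
        )


class TestAssignNames:
    def test_demo_anchored_naming(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        renamed = assign_cluster_names(asg, ANCHORS)
        labels = set(renamed.leaf_labels())
        assert {"NicsylGUS1", "NicsylGUS3.1", "NicsylGUS3.2", "NicsylGUS4"} <= labels
        assert {"AnacomGUS1", "AnacomGUS3", "AnacomGUS4"} <= labels
        assert "PhypatGUS1.a" in labels  # outgroup untouched

    def test_multiple_copies_get_ordinal_letters(self, demo_config):
        g = GeneTree.from_newick(
            "((AmbtriGUS1,(AnacomGUS1,AnacomGUS2)),(AmbtriGUS3,AnacomGUS3));",
            family_tag="GUS",
        )
        cfg = DFDConfig(required_phyla={
            "ancestral_angiosperms": frozenset({"Ambtri"}),
            "monocots": frozenset({"Anacom"}),
        })
        asg = detect_clusters(g, cfg)
        renamed = assign_cluster_names(asg, {"AmbtriGUS1": "1", "AmbtriGUS3": "3"})
        labels = set(renamed.leaf_labels())
        # subclusters 1.1/1.2 hold one Ananas copy each
        assert {"AnacomGUS1.1", "AnacomGUS1.2", "AnacomGUS3"} <= labels

    def test_split_anchor_conflict_raises(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        with pytest.raises(TreeError, match="split|different"):
            assign_cluster_names(asg, {"AmbtriGUS1": "1", "AmbtriGUS4": "1"})

    def test_unanchored_clusters_numbered_in_detection_order(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        renamed = assign_cluster_names(asg, {})
        labels = set(renamed.leaf_labels())
        # detection order: cluster 3-clade first, then 1, then 4
        assert {"AmbtriGUS1", "AmbtriGUS2", "AmbtriGUS3"} <= labels


class TestCompletenessAndClassification:
    def _demo_events(self, demo, demo_config):
        events, _, _, _ = analyze_family(
            demo.gene_tree, demo.species_tree, demo_config,
            wgd_table=list(demo.wgd_events), outgroup_labels=demo.outgroup,
        )
        return events

    def test_demo_crown_events_fully_retained(self, demo, demo_config):
        for ev in self._demo_events(demo, demo_config):
            assert ev.completeness == (1.0, 1.0)

    def test_double_gene_phylum_threshold_arithmetic(self):
        ev = DuplicationEvent(
            gene_node=None, species_node=None, gene_clade=frozenset(),
            mapped_species="x", age_lower=0, age_upper=1,
            child_species_sets=(frozenset("A"), frozenset("A")),
            child_leaf_sets=(frozenset(), frozenset()),
        )
        assert is_double_gene_phylum(ev, (1.0, 1.0), tol=0.0)
        assert not is_double_gene_phylum(ev, (1.0, 0.4), tol=0.0)
        assert is_double_gene_phylum(ev, (0.95, 0.92), tol=0.1)

    def test_set_equality_oracle_at_tol_zero(self, demo, demo_config):
        # strict double-gene phylum == both child species sets equal the
        # restricted descendant set
        for ev in self._demo_events(demo, demo_config):
            strict = is_double_gene_phylum(ev, ev.completeness, tol=0.0)
            expected = (
                ev.child_species_sets[0] == ev.denominator_taxa
                and ev.child_species_sets[1] == ev.denominator_taxa
            )
            assert strict == expected

    def test_demo_verdicts(self, demo, demo_config):
        events = self._demo_events(demo, demo_config)
        verdicts = [e.verdict for e in events]
        assert verdicts.count(Verdict.DFD_LIKELY) == 2  # ancient crown events
        assert verdicts.count(Verdict.RETAINED_RECENT) == 1  # eudicot 3.1/3.2
        # verdicts partition events
        assert all(v is not None for v in verdicts)

    def test_lossy_event_classification(self):
        # species ((A,B),C) with family in all three; duplication at the root
        # whose second daughter survives only in A: lost in 2/3 of taxa
        species = SpeciesTree.from_newick(
            "((Aaaaaa:50,Bbbbbb:50):100,Cccccc:150)root;"
        )
        gene = GeneTree.from_newick(
            "(((AaaaaaGUS1,BbbbbbGUS1),CcccccGUS1),AaaaaaGUS2);", family_tag="GUS"
        )
        cfg = DFDConfig(
            required_phyla={"all": frozenset({"Aaaaaa", "Bbbbbb", "Cccccc"})},
            lossy_fraction=0.5,
            taxon_families={"Aaaaaa": "F1", "Bbbbbb": "F1", "Cccccc": "F2"},
        )
        events, _, _, _ = analyze_family(gene, species, cfg)
        assert len(events) == 1
        assert events[0].completeness == (1.0, pytest.approx(1 / 3))
        assert events[0].verdict is Verdict.NON_DFD_LOSSY

    def test_incomplete_but_not_lossy_is_ambiguous(self):
        species = SpeciesTree.from_newick(
            "(((Aaaaaa:40,Bbbbbb:40):40,Cccccc:80):40,Dddddd:120);"
        )
        # daughter 2 misses only Bbbbbb: 1/3 of the denominator < lossy_fraction
        gene = GeneTree.from_newick(
            "((((AaaaaaGUS1,BbbbbbGUS1),CcccccGUS1),"
            "(AaaaaaGUS2,CcccccGUS2)),DddddddGUS1);".replace("Ddddddd", "Dddddd"),
            family_tag="GUS",
        )
        cfg = DFDConfig(
            required_phyla={"all": frozenset({"Aaaaaa", "Bbbbbb", "Cccccc"})},
            lossy_fraction=0.5,
        )
        events, _, _, _ = analyze_family(gene, species, cfg)
        dup = [e for e in events if len(e.gene_clade) == 5]
        assert len(dup) == 1
        assert dup[0].verdict is Verdict.AMBIGUOUS

    def test_classify_recent_complete_event(self):
        ev = DuplicationEvent(
            gene_node=None, species_node=None, gene_clade=frozenset({"x", "y"}),
            mapped_species="tip", age_lower=40.0, age_upper=70.0,
            child_species_sets=(frozenset({"A"}), frozenset({"A"})),
            child_leaf_sets=(frozenset({"x"}), frozenset({"y"})),
        )
        ev.denominator_taxa = frozenset({"A"})
        cfg = DFDConfig(required_phyla={"p": frozenset({"A"})})
        assert classify_dfd(ev, (1.0, 1.0), cfg) is Verdict.RETAINED_RECENT
        ev.age_lower = 200.0
        assert classify_dfd(ev, (1.0, 1.0), cfg) is Verdict.DFD_LIKELY


class TestWgdMapping:
    def test_demo_crown_events_match_ancient_wgds(self, demo, demo_config):
        events, _, _, _ = analyze_family(
            demo.gene_tree, demo.species_tree, demo_config,
            outgroup_labels=demo.outgroup,
        )
        crown = [e for e in events if e.mapped_species == "angiosperms"]
        for ev in crown:
            matches = map_to_wgd(ev, list(demo.wgd_events), demo.species_tree)
            names = {w.name for w, flag in matches if flag}
            assert names == {"seed-plant", "angiosperm-ancestor"}

    def test_tip_event_does_not_match_other_branches(self, demo, demo_config):
        events, _, _, _ = analyze_family(
            demo.gene_tree, demo.species_tree, demo_config,
            outgroup_labels=demo.outgroup,
        )
        tip_event = next(e for e in events if e.mapped_species == "Nicsyl")
        matches = map_to_wgd(
            tip_event,
            [WGDEvent("elsewhere", "angiosperms", 0.0, 500.0)],
            demo.species_tree,
        )
        assert matches == []

    def test_age_overlap_flag(self, demo, demo_config):
        events, _, _, _ = analyze_family(
            demo.gene_tree, demo.species_tree, demo_config,
            outgroup_labels=demo.outgroup,
        )
        tip_event = next(e for e in events if e.mapped_species == "Nicsyl")
        # same branch, but an age window entirely above the event's interval
        matches = map_to_wgd(
            tip_event, [WGDEvent("too-old", "Nicsyl", 130.0, 140.0)],
            demo.species_tree,
        )
        assert [(w.name, flag) for w, flag in matches] == [("too-old", False)]


class TestGeneticDistance:
    @pytest.mark.parametrize(
        "mb,ratio,cm,free",
        [(10.0, 2.0, 20.0, False), (0.0, 2.0, 0.0, False), (30.0, 2.0, 60.0, True)],
    )
    def test_products_and_flag(self, mb, ratio, cm, free):
        assert expected_genetic_distance(mb, ratio) == (cm, free)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            expected_genetic_distance(-1.0, 2.0)


class TestHybridsAndRetainers:
    def test_hybrid_pruning_reports_removed_leaves(self, demo):
        pruned, removed = prune_hybrid_leaves(demo.gene_tree, frozenset({"Nicsyl"}))
        assert sorted(removed) == [
            "NicsylGUS1.1", "NicsylGUS3.1", "NicsylGUS3.2", "NicsylGUS4",
        ]
        assert len(pruned.leaves()) == 10

    def test_demo_dual_retainers(self, demo, demo_config):
        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        renamed = assign_cluster_names(asg, ANCHORS)
        asg2 = detect_clusters(renamed, demo_config, outgroup_labels=demo.outgroup)
        # every angiosperm taxon keeps >=1 copy in each of clusters 1 and 3
        assert count_dual_retainers(asg2, "1", "3") == 4
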