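"""CDS filtering rules, summaries, paralog collapse and pseudogene flags."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfdscan.curation import (
    CDSRecord,
    FilterRule,
    apply_filters,
    collapse_tight_paralogs,
    flag_pseudogenization_candidates,
    kept_records,
    read_records,
    summarize_lengths,
)
from dfdscan.synthetic_data import make_curation_table
from dfdscan.treekit import GeneTree


def rec(i, taxon="Aaaaaa", locus="L1", length=1600, annotation="heparanase"):
    return CDSRecord(
        id=i, taxon=taxon, locus=locus, chromosome="chr1",
        length=length, annotation=annotation,
    )


class TestApplyFilters:
    def test_rule_order_on_reference_table(self):
        records = make_curation_table()
        decisions = {d.record_id: d for d in apply_filters(records)}
        expected = {
            "r01": FilterRule.KEPT,
            "r02": FilterRule.LEN_LT_300,
            "r03": FilterRule.LEN_LT_800_UNANNOTATED,
            "r04": FilterRule.KEPT,
            "r05": FilterRule.KEPT,
            "r06": FilterRule.DUP_LOCUS,
            "r07": FilterRule.LEN_LT_300,
            "r08": FilterRule.LEN_LT_800_UNANNOTATED,
            "r09": FilterRule.KEPT,
            "r10": FilterRule.DUP_LOCUS,
            "r11": FilterRule.KEPT,
            "r12": FilterRule.KEPT,
        }
        assert {k: d.rule for k, d in decisions.items()} == expected
        assert all(d.kept == (d.rule is FilterRule.KEPT) for d in decisions.values())

    def test_short_annotated_record_still_discarded_by_hard_rule(self):
        d, = apply_filters([rec("x", length=250, annotation="heparanase")])
        assert d.rule is FilterRule.LEN_LT_300

    def test_annotation_rescue_below_soft_length(self):
        d1, d2 = apply_filters([
            rec("x", length=500, annotation="hypothetical protein"),
            rec("y", locus="L2", length=500, annotation="putative heparanase"),
        ])
        assert d1.rule is FilterRule.LEN_LT_800_UNANNOTATED
        assert d2.rule is FilterRule.KEPT

    def test_first_listed_locus_duplicate_is_kept(self):
        d1, d2 = apply_filters([
            rec("first", length=500, annotation="heparanase"),
            rec("second", length=1600, annotation="heparanase"),
        ])
        assert (d1.kept, d2.rule) == (True, FilterRule.DUP_LOCUS)

    def test_idempotent(self):
        records = make_curation_table()
        decisions = apply_filters(records)
        survivors = kept_records(records, decisions)
        again = apply_filters(survivors)
        assert all(d.kept for d in again)

    def test_every_record_gets_exactly_one_decision(self):
        records = make_curation_table()
        decisions = apply_filters(records)
        assert sorted(d.record_id for d in decisions) == sorted(r.id for r in records)

    def test_kept_locus_multiset_is_order_invariant(self):
        records = make_curation_table()
        reference = None
        for perm in itertools.islice(itertools.permutations(records), 0, 120, 17):
            decisions = apply_filters(list(perm))
            kept = sorted(
                (r.taxon, r.locus) for r in kept_records(list(perm), decisions)
            )
            reference = kept if reference is None else reference
            assert kept == reference

    @given(st.lists(st.integers(100, 2000), min_size=1, max_size=12))
    def test_generated_lengths_follow_threshold_logic(self, lengths):
        records = [
            rec(f"g{i}", locus=f"L{i}", length=n, annotation="no match here")
            for i, n in enumerate(lengths)
        ]
        for d, n in zip(apply_filters(records), lengths):
            if n < 300:
                assert d.rule is FilterRule.LEN_LT_300
            elif n < 800:
                assert d.rule is FilterRule.LEN_LT_800_UNANNOTATED
            else:
                assert d.kept


class TestSummaries:
    def test_single_record_median(self):
        s = summarize_lengths([rec("x", length=1600)])
        assert (s.n, s.median) == (1, 1600)

    def test_even_count_median_is_midpoint(self):
        s = summarize_lengths([rec("x", length=1500), rec("y", length=1700)])
        assert s.median == 1600

    def test_demo_metadata_median_is_1600(self, demo):
        s = summarize_lengths(demo.records())
        assert s.median == 1600
        assert s.n == 14

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_lengths([])


class TestReadRecords(object):
    def _write(self, tmp_path, fasta, meta):
        f = tmp_path / "cds.fa"
        m = tmp_path / "meta.tsv"
        f.write_text(fasta)
        m.write_text(meta)
        return f, m

    def test_matched_records_load(self, tmp_path):
        f, m = self._write(
            tmp_path,
            ">a\nACGTAC\n>b\nACGT\n",
            "id\ttaxon\tlocus\tchromosome\tlength\tannotation\n"
            "a\tAaaaaa\tL1\tchr1\t6\theparanase\n"
            "b\tBbbbbb\tL1\tchr2\t4\tGUS\n",
        )
        records = read_records(f, m)
        assert [r.id for r in records] == ["a", "b"]
        assert records[0].sequence == "ACGTAC"

    def test_orphan_id_raises(self, tmp_path):
        f, m = self._write(
            tmp_path,
            ">a\nACGT\n>c\nACGT\n",
            "id\ttaxon\tlocus\tchromosome\tlength\tannotation\n"
            "a\tAaaaaa\tL1\tchr1\t4\theparanase\n",
        )
        with pytest.raises(ValueError, match="mismatch"):
            read_records(f, m)

    def test_length_disagreement_raises(self, tmp_path):
        f, m = self._write(
            tmp_path,
            ">a\nACGT\n",
            "id\ttaxon\tlocus\tchromosome\tlength\tannotation\n"
            "a\tAaaaaa\tL1\tchr1\t7\theparanase\n",
        )
        with pytest.raises(ValueError, match="length"):
            read_records(f, m)


class TestCollapse:
    def test_zero_distance_pair_collapses_to_longest(self):
        guide = GeneTree.from_newick(
            "((AaaaaaGUS1:0.0,AaaaaaGUS2:0.0):0.3,BbbbbbGUS1:0.3);",
            family_tag="GUS",
        )
        records = [
            rec("AaaaaaGUS1", length=1500),
            rec("AaaaaaGUS2", locus="L2", length=1700),
            rec("BbbbbbGUS1", taxon="Bbbbbb", length=1600),
        ]
        decisions = {d.record_id: d for d in collapse_tight_paralogs(records, guide)}
        assert decisions["AaaaaaGUS2"].representative
        assert not decisions["AaaaaaGUS1"].representative
        assert decisions["BbbbbbGUS1"].representative

    def test_distant_same_species_copies_both_kept(self, demo):
        # Arabidopsis-style: copies in different clusters are never collapsed
        records = [
            rec("NicsylGUS1.1", taxon="Nicsyl", length=1647),
            rec("NicsylGUS4", taxon="Nicsyl", locus="L2", length=650),
        ]
        decisions = collapse_tight_paralogs(records, demo.gene_tree)
        assert all(d.representative for d in decisions)

    def test_demo_tight_eudicot_pair_collapses(self, demo):
        records = [
            rec("NicsylGUS3.1", taxon="Nicsyl", length=1600),
            rec("NicsylGUS3.2", taxon="Nicsyl", locus="L2", length=1600),
        ]
        decisions = {
            d.record_id: d
            for d in collapse_tight_paralogs(records, demo.gene_tree)
        }
        # patristic distance 0.023 < 0.05 -> one representative, tie by id
        assert decisions["NicsylGUS3.1"].representative
        assert not decisions["NicsylGUS3.2"].representative

    def test_single_linkage_grouping(self):
        guide = GeneTree.from_newick(
            "(((AaaaaaGUS1:0.01,AaaaaaGUS2:0.01):0.2,AaaaaaGUS3:0.21):0.5,"
            "BbbbbbGUS1:0.7);",
            family_tag="GUS",
        )
        records = [
            rec("AaaaaaGUS1", length=1000),
            rec("AaaaaaGUS2", locus="L2", length=1200),
            rec("AaaaaaGUS3", locus="L3", length=1100),
            rec("BbbbbbGUS1", taxon="Bbbbbb"),
        ]
        decisions = collapse_tight_paralogs(records, guide)
        reps = sorted(d.record_id for d in decisions if d.representative)
        assert reps == ["AaaaaaGUS2", "AaaaaaGUS3", "BbbbbbGUS1"]

    def test_record_missing_from_guide_raises(self, demo):
        with pytest.raises(ValueError, match="absent"):
            collapse_tight_paralogs([rec("nope")], demo.gene_tree)


class TestPseudogenizationFlags:
    @pytest.mark.parametrize(
        "length,cluster,flagged",
        [(600, "4", True), (1600, "4", False), (600, "1", False)],
    )
    def test_flagging_rules(self, length, cluster, flagged):
        r = rec("x", length=length)
        got = flag_pseudogenization_candidates(
            [r], cluster_of={"x": cluster}, lossy_clusters={"3.1", "4"}
        )
        assert (r.id in got) is flagged

    def test_demo_short_gus4_copy_is_flagged(self, demo, demo_config):
        from dfdscan.dfd import assign_cluster_names, detect_clusters
        from dfdscan.treekit import parse_leaf_label

        asg = detect_clusters(demo.gene_tree, demo_config,
                              outgroup_labels=demo.outgroup)
        renamed = assign_cluster_names(
            asg, {"AmbtriGUS1": "1", "AmbtriGUS3": "3", "AmbtriGUS4": "4"}
        )
        # after renaming, a copy's cluster is its label suffix
        cluster_of = {
            lbl: parse_leaf_label(lbl, "GUS").cluster_suffix
            for lbl in renamed.leaf_labels()
        }
        records = [
            CDSRecord(
                id={"NicsylGUS1.1": "NicsylGUS1"}.get(row.id, row.id),
                taxon=row.taxon, locus=row.locus, chromosome=row.chromosome,
                length=int(row.length), annotation=row.annotation,
            )
            for row in demo.metadata.itertuples(index=False)
            if row.taxon == "Nicsyl"
        ]
        flagged = flag_pseudogenization_candidates(
            records, cluster_of, lossy_clusters={"3.1", "4"}
        )
        assert flagged == ["NicsylGUS4"]
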