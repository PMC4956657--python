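"""Mismatch matching, category assignment and family aggregation."""

import numpy as np
import pytest

from conftest import random_seq
from mircms.annotation import (AnnotationConfig, AnnotationRecord,
                               ConfigurationError, annotate_tags,
                               category_table, default_family, family_table,
                               load_family_alias, match_with_mismatches)
from mircms.sequence_io import (ReferenceSet, SequenceRecord, SequenceTag,
                                reverse_complement)


def brute_force_best(tag_seq, ref, k):
    """Independent exhaustive all-window Hamming scan with the same
    deterministic tie-break (fewest mismatches, then id, strand, position)."""
    best = None
    for rec in sorted(ref.records, key=lambda r: r.id):
        strands = [("+", rec.seq)]
        if ref.both_strands:
            strands.append(("-", reverse_complement(rec.seq)))
        for strand, seq in strands:
            for p in range(len(seq) - len(tag_seq) + 1):
                mism = sum(a != b for a, b in zip(tag_seq, seq[p:p + len(tag_seq)]))
                if mism <= k and (best is None or mism < best[1]):
                    best = (rec.id, mism)
    return best


class TestMatchWithMismatches:
    def test_identical_sequence_is_zero_mismatch_hit(self, rng):
        seq = random_seq(rng, 21)
        ref = ReferenceSet("m", [SequenceRecord("mir1", seq)], "mature")
        hit = match_with_mismatches(seq, ref, 2)
        assert hit.hit_id == "mir1" and hit.mismatches == 0

    def test_three_substitutions_rejected_at_k2(self, rng):
        seq = random_seq(rng, 21)
        mutated = list(seq)
        for p in (2, 9, 15):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        ref = ReferenceSet("m", [SequenceRecord("mir1", seq)], "mature")
        assert match_with_mismatches("".join(mutated), ref, 2) is None
        assert match_with_mismatches("".join(mutated), ref, 3).mismatches == 3

    def test_matches_brute_force_on_random_references(self, rng):
        """Vectorised matcher equals the exhaustive all-window Hamming scan."""
        refs = ReferenceSet(
            "r", [SequenceRecord(f"ref{i:02d}", random_seq(rng, int(rng.integers(25, 60))))
                  for i in range(50)], "genome")
        for _ in range(120):
            if rng.random() < 0.5:
                tag = random_seq(rng, 21)
            else:  # near-copy of a reference window to exercise hits
                rec = refs.records[int(rng.integers(0, 50))]
                p = int(rng.integers(0, len(rec.seq) - 21 + 1))
                tag = list(rec.seq[p:p + 21])
                for q in rng.choice(21, size=int(rng.integers(0, 4)), replace=False):
                    tag[q] = "ACGT"[int(rng.integers(0, 4))]
                tag = "".join(tag)
            got = match_with_mismatches(tag, refs, 2)
            want = brute_force_best(tag, refs, 2)
            if want is None:
                assert got is None
            else:
                assert (got.hit_id, got.mismatches) == want

    def test_strand_symmetry_for_genome_sets(self, rng):
        """A reverse-complement hit is found with equal mismatch count."""
        seq = random_seq(rng, 40)
        ref = ReferenceSet("g", [SequenceRecord("chr", seq)], "genome")
        tag = seq[10:31]
        fwd = match_with_mismatches(tag, ref, 2)
        rev = match_with_mismatches(reverse_complement(tag), ref, 2)
        assert fwd and rev and fwd.mismatches == rev.mismatches == 0

    def test_forward_only_for_mature_sets(self, rng):
        seq = random_seq(rng, 21)
        ref = ReferenceSet("m", [SequenceRecord("mir1", seq)], "mature")
        rc = reverse_complement(seq)
        if sum(a != b for a, b in zip(rc, seq)) > 2:
            assert match_with_mismatches(rc, ref, 2) is None


class TestAnnotateTags:
    def _refs(self, mirna_seq, rrna_seq):
        mature = ReferenceSet("m", [SequenceRecord("miR1", mirna_seq)], "mature")
        nc = ReferenceSet("nc", [SequenceRecord("rRNA_1", rrna_seq)], "ncRNA")
        return [nc, mature]

    def test_priority_rrna_over_mirna(self, rng, tag_factory):
        seq = random_seq(rng, 21)
        refs = self._refs(seq, seq)   # tag matches both sets
        recs = annotate_tags([tag_factory(seq, wa=5)], refs, AnnotationConfig())
        assert recs[0].category == "rRNA"

    def test_no_hit_is_unannotated(self, rng, tag_factory):
        refs = self._refs(random_seq(rng, 21), random_seq(rng, 80))
        recs = annotate_tags([tag_factory("ACGT" * 5 + "A", wa=1)], refs,
                             AnnotationConfig())
        assert recs[0].category == "unannotated" and recs[0].hit_id is None

    def test_missing_reference_set_is_configuration_error(self, tag_factory):
        mature = ReferenceSet("m", [SequenceRecord("miR1", "ACGT" * 5)], "mature")
        with pytest.raises(ConfigurationError):
            annotate_tags([tag_factory("ACGT" * 5, wa=1)], [mature],
                          AnnotationConfig())

    def test_partition_conserves_unique_and_total_counts(self, rng, tag_factory):
        """Every tag lands in exactly one category; totals add up."""
        mirna = random_seq(rng, 21)
        rrna = random_seq(rng, 100)
        refs = self._refs(mirna, rrna)
        tags = [tag_factory(mirna, wa=10), tag_factory(rrna[5:26], wa=3),
                *[tag_factory(random_seq(rng, 22), wa=i + 1) for i in range(8)]]
        recs = annotate_tags(tags, refs, AnnotationConfig())
        assert len(recs) == len(tags)
        table = category_table(recs, ("WA",))
        body = table[table.category != "Total"]
        total = table[table.category == "Total"]
        assert body["WA_unique"].sum() == total["WA_unique"].iloc[0] == len(tags)
        assert body["WA_total"].sum() == total["WA_total"].iloc[0] \
            == sum(t.count("WA") for t in tags)


class TestFamilyTable:
    def _rec(self, hit_id, wa, wb, seq_tail="A"):
        tag = SequenceTag("ACGTACGTACGTACGTACG" + seq_tail,
                          {"WA": wa, "WB": wb}, id=hit_id + "_tag")
        return AnnotationRecord(tag, "miRNA", hit_id, 0)

    def test_merged_family_ratio_and_total(self):
        recs = [self._rec("miR156a", 400_000, 300_000, "AA"),
                self._rec("miR157a", 10_237, 4_695, "AC")]
        (fam,) = family_table(recs, load_family_alias())
        assert fam.family == "miR156/157"
        assert fam.total == 714_932
        assert fam.ratio == 1.35

    def test_extreme_ratio(self):
        recs = [self._rec("miR395a", 45_236, 44)]
        (fam,) = family_table(recs, load_family_alias())
        assert fam.ratio == 1028.09

    def test_zero_denominator_reports_dash(self):
        recs = [self._rec("miR161", 152, 0)]
        (fam,) = family_table(recs, load_family_alias())
        assert fam.ratio is None and fam.ratio_str() == "-"
        assert fam.total == 152

    def test_grouping_conserves_reads(self, rng):
        """Family totals equal member sums under any grouping."""
        recs = [self._rec(f"miR{100 + i}a", int(rng.integers(0, 1000)),
                          int(rng.integers(0, 1000)), "ACGT"[i % 4] * 2)
                for i in range(12)]
        fams = family_table(recs, {})
        assert sum(f.total for f in fams) == \
            sum(r.tag.count("WA") + r.tag.count("WB") for r in recs)

    @pytest.mark.parametrize("mature_id,family", [
        ("rsa-miR156a-5p", "miR156"),
        ("miR395x", "miR395"),
        ("ath-miR172b", "miR172"),
        ("miRn3", "miRn3"),
    ])
    def test_default_family_stripping(self, mature_id, family):
        assert default_family(mature_id) == family
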