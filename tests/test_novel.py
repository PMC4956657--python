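"""Precursor excision arithmetic and hairpin/duplex screening."""

import numpy as np
import pytest

from conftest import make_hairpin, random_seq
from mircms.novel import (HairpinCandidate, NovelCriteria, Rejection,
                          discover, evaluate_hairpin, excise_candidates,
                          map_exact)
from mircms.sequence_io import (ReferenceSet, SequenceRecord, SequenceTag,
                                reverse_complement)


def genome_with(seq_at_100, rng, length=1000):
    g = random_seq(rng, length)
    g = g[:100] + seq_at_100 + g[100 + len(seq_at_100):]
    return ReferenceSet("g", [SequenceRecord("ref1", g)], "genome")


class TestExcise:
    def test_window_arithmetic_with_clipping(self, rng, tag_factory):
        """Tag at 101-121 (1-based): windows [81,281] and clipped [1,141]."""
        tag_seq = random_seq(rng, 21)
        genome = genome_with(tag_seq, rng)
        tag = tag_factory(tag_seq, wa=10)
        wins = excise_candidates(tag, genome, NovelCriteria())
        assert len(wins) == 2
        spans = sorted((w.locus.start + 1, w.locus.end) for w in wins)
        assert spans == [(1, 141), (81, 281)]
        by_bias = {w.bias: w for w in wins}
        assert by_bias["5p"].tag_start == 20
        assert by_bias["3p"].tag_start == 100

    def test_excessive_multimapping_gives_empty_list(self, tag_factory):
        tag_seq = "ACGGATTACCAGGATCCAGGT"
        genome = ReferenceSet("g", [SequenceRecord(
            "ref1", ("AAGGTTCC" + tag_seq) * 20)], "genome")
        tag = tag_factory(tag_seq, wa=10)
        assert len(map_exact(tag_seq, genome)) >= 20
        assert excise_candidates(tag, genome, NovelCriteria()) == []

    def test_unmappable_tag_gives_empty_list(self, rng, tag_factory):
        genome = genome_with(random_seq(rng, 21), rng)
        assert excise_candidates(tag_factory("TTTTAAAACCCCGGGGTTTTA", wa=9),
                                 genome, NovelCriteria()) == []

    def test_minus_strand_window_is_reverse_complement_of_plus_slice(
            self, rng, tag_factory):
        tag_seq = random_seq(rng, 21)
        genome = genome_with(reverse_complement(tag_seq), rng)
        wins = excise_candidates(tag_factory(tag_seq, wa=10), genome,
                                 NovelCriteria())
        ref_seq = genome.records[0].seq
        for w in wins:
            assert w.locus.strand == "-"
            plus_slice = ref_seq[w.locus.start:w.locus.end]
            assert w.record.seq == reverse_complement(plus_slice)
            assert w.record.seq[w.tag_start:w.tag_start + 21] == tag_seq


class TestEvaluateHairpin:
    CRIT = NovelCriteria(min_reads=1)

    def test_perfect_hairpin_accepted_with_canonical_star(self, rng, tag_factory):
        """mature + loop + revcomp(mature): 0 duplex mismatches; star is the
        mature's reverse complement shifted by the 2-nt overhang."""
        cassette, mature, star = make_hairpin(rng, 21, 8, arm_mismatches=0)
        tag = tag_factory(mature, wa=100)
        cand = evaluate_hairpin(SequenceRecord("w", cassette), tag, [], self.CRIT)
        assert isinstance(cand, HairpinCandidate)
        assert cand.duplex_mismatches == 0
        assert cand.mature_arm == "5p" and cand.star_arm == "3p"
        assert cand.star.seq == star == reverse_complement(mature)[2:] + cassette[-2:]
        assert not cand.star_observed

    def test_heavily_mutated_arm_rejected(self, rng, tag_factory):
        cassette, mature, _ = make_hairpin(rng, 21, 8, arm_mismatches=0)
        arm = list(cassette[29:50])
        for p in (2, 6, 10, 14, 18):
            arm[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arm[p]]
        broken = cassette[:29] + "".join(arm) + cassette[50:]
        res = evaluate_hairpin(SequenceRecord("w", broken),
                               tag_factory(mature, wa=100), [], self.CRIT)
        assert isinstance(res, Rejection)

    def test_mature_on_3p_arm_detected(self, rng, tag_factory):
        cassette, mature, _ = make_hairpin(rng, 21, 10, arm_mismatches=0)
        # fold the same cassette but query with the 3'-arm sequence
        arm3 = cassette[31:52]
        cand = evaluate_hairpin(SequenceRecord("w", cassette),
                                tag_factory(arm3, wa=50), [], self.CRIT)
        assert isinstance(cand, HairpinCandidate)
        assert cand.mature_arm == "3p" and cand.star_arm == "5p"

    def test_star_observed_flag_with_table3_style_counts(self, rng, tag_factory):
        cassette, mature, star = make_hairpin(rng, 22, 9, arm_mismatches=0)
        mature_tag = tag_factory(mature, wa=443, wb=0)
        star_tag = tag_factory(star, wa=8, wb=0)
        cand = evaluate_hairpin(SequenceRecord("w", cassette), mature_tag,
                                [mature_tag, star_tag], self.CRIT)
        assert isinstance(cand, HairpinCandidate)
        assert cand.star_observed and cand.star.count("WA") == 8

    def test_mature_length_bounds_enforced(self, rng, tag_factory):
        cassette, mature, _ = make_hairpin(rng, 21, 8)
        short = tag_factory("ACGTACGTACGTACGTACG", wa=50)  # 19 nt < 20
        res = evaluate_hairpin(SequenceRecord("w", cassette), short, [], self.CRIT)
        assert isinstance(res, Rejection) and res.reason == "mature_length"

    def test_reported_mismatches_track_planted(self, tag_factory):
        """Planted arm substitutions reappear as duplex mismatches; a planted
        substitution may still pair as G:U (undershoot by 1) or destabilise a
        neighbouring pair in the thermodynamic model (overshoot by <= 2)."""
        rng = np.random.default_rng(7)
        checked = exact = 0
        for _ in range(50):
            k = int(rng.integers(0, 3))
            cassette, mature, _ = make_hairpin(
                rng, int(rng.choice([20, 21, 22, 23, 24])),
                int(rng.integers(8, 16)), arm_mismatches=k)
            cand = evaluate_hairpin(SequenceRecord("w", cassette),
                                    tag_factory(mature, wa=60), [],
                                    self.CRIT)
            if isinstance(cand, HairpinCandidate):
                checked += 1
                exact += cand.duplex_mismatches == k
                assert cand.duplex_mismatches <= k + 2
        assert checked >= 40 and exact >= checked // 2


class TestDiscover:
    def _planted_setup(self, rng, n=6):
        from mircms.simulate import SimulationConfig, make_genome
        cfg = SimulationConfig(seed=11, genome_len=30_000, n_known=0, n_novel=n,
                               n_ncrna=0, arm_mismatch_max=0)
        truth = make_genome(cfg, rng)
        tags = []
        for m in truth.mirnas:
            tags.append(SequenceTag(m.mature, {"WA": 100}, id=m.name))
            tags.append(SequenceTag(m.star, {"WA": 5}, id=m.name + "*"))
        return truth, tags

    def test_planted_canonical_hairpins_recovered_exactly(self, rng):
        """Noise-free canonical hairpins: full recall, no extra loci, and
        every acceptance lies at a planted locus."""
        truth, tags = self._planted_setup(rng)
        cands = discover(tags, truth.genome, NovelCriteria())
        planted = {m.mature for m in truth.mirnas}
        assert {c.mature.seq for c in cands} == planted
        assert len(cands) == len(planted)
        for c in cands:
            spans = [(m.locus.start, m.locus.end) for m in truth.mirnas]
            slack = NovelCriteria().flank_long + NovelCriteria().flank_short
            assert any(c.locus.start >= s - slack and c.locus.end <= e + slack
                       for s, e in spans)

    def test_star_counts_not_above_mature_counts(self, rng):
        truth, tags = self._planted_setup(rng)
        cands = discover(tags, truth.genome, NovelCriteria())
        for c in cands:
            if c.star_observed:
                assert c.star.total <= c.mature.total

    def test_low_abundance_tags_skipped(self, rng):
        truth, tags = self._planted_setup(rng)
        starved = [SequenceTag(t.seq, {"WA": 2}, id=t.id) for t in tags]
        assert discover(starved, truth.genome, NovelCriteria(min_reads=5)) == []

    def test_names_assigned_in_discovery_order(self, rng):
        truth, tags = self._planted_setup(rng)
        cands = discover(tags, truth.genome, NovelCriteria())
        assert [c.name for c in cands] == \
            [f"miRn{i + 1}" for i in range(len(cands))]
        for c in cands:
            if c.star is not None and not c.star_observed:
                assert c.star.id == c.name + "*"
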