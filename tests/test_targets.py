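"""Plant complementarity scoring, transcript scanning and network export."""

import itertools

import pytest

from conftest import random_seq
from mircms.differential import DifferentialResult
from mircms.sequence_io import ReferenceSet, SequenceRecord, reverse_complement
from mircms.targets import (AlignmentError, NetworkEdge, TargetScoringConfig,
                            build_network, scan_transcripts, score_duplex,
                            write_sif)

CFG = TargetScoringConfig()
WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def oracle_score(mirna, site, cfg=CFG):
    """Independent re-scorer: enumerate all <=1-indel alignments by hand."""
    mirna = mirna.replace("U", "T")
    site_rev = site.replace("U", "T")[::-1]

    def penalty(m, t, pos):
        if t == "-" or m == "-":
            pen = cfg.indel_penalty
        elif WC[m] == t:
            pen = 0.0
        elif (m, t) in (("G", "T"), ("T", "G")):
            pen = cfg.wobble_penalty
        else:
            pen = cfg.mismatch_penalty
        if pen and cfg.seed_start <= pos <= cfg.seed_end:
            pen *= cfg.seed_multiplier
        return pen

    def score(cols):
        total, mpos = 0.0, 0
        for m, t in cols:
            pos = mpos + 1 if m != "-" else min(mpos + 1, len(mirna))
            total += penalty(m, t, pos)
            if m != "-":
                mpos += 1
        return total

    diff = len(site_rev) - len(mirna)
    if diff == 0:
        return score(list(zip(mirna, site_rev)))
    best = None
    n = max(len(mirna), len(site_rev))
    for g in range(n):
        cols, mi, si = [], 0, 0
        for c in range(n):
            if c == g:
                if diff < 0:
                    cols.append((mirna[mi], "-")); mi += 1
                else:
                    cols.append(("-", site_rev[si])); si += 1
            else:
                cols.append((mirna[mi], site_rev[si])); mi += 1; si += 1
        s = score(cols)
        best = s if best is None else min(best, s)
    return best


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        mirna = "TATTCCGACGACAATTCCGACG"
        score = score_duplex(mirna, reverse_complement(mirna))
        assert score.expectation == 0.0

    def test_mismatch_position_controls_seed_doubling(self):
        """Same substitution costs 1.0 outside the seed, 2.0 inside."""
        mirna = "A" * 21
        site = list(reverse_complement(mirna))   # all T
        # miRNA position 15 -> site_rev index 14 -> site index 21-15=6
        site15 = site.copy(); site15[21 - 15] = "C"
        assert score_duplex(mirna, "".join(site15)).expectation == 1.0
        site5 = site.copy(); site5[21 - 5] = "C"
        assert score_duplex(mirna, "".join(site5)).expectation == 2.0

    def test_wobble_plus_mismatch(self):
        """G:U at position 3 (0.5 x 2) plus mismatch at 20 (1.0) -> 2.0."""
        mirna = "AA" + "G" + "A" * 18          # G at position 3, length 21
        site = list(reverse_complement(mirna))
        site[21 - 3] = "T"                      # G:U wobble at miRNA pos 3
        site[21 - 20] = "C"                     # mismatch vs A at pos 20
        assert score_duplex(mirna, "".join(site)).expectation == 2.0

    def test_length_difference_beyond_one_indel_rejected(self):
        with pytest.raises(AlignmentError):
            score_duplex("A" * 21, "T" * 24)

    def test_matches_hand_scoring_oracle_on_random_duplexes(self, rng):
        """Implementation == exhaustive per-position re-scoring, <=25 nt."""
        for _ in range(150):
            L = int(rng.integers(19, 26))
            mirna = random_seq(rng, L)
            site = list(reverse_complement(mirna))
            for p in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                site[p] = "ACGT"[int(rng.integers(0, 4))]
            mode = int(rng.integers(0, 3))
            if mode == 1 and L > 19:        # deletion in site
                del site[int(rng.integers(0, len(site)))]
            elif mode == 2:                 # insertion in site
                site.insert(int(rng.integers(0, len(site) + 1)),
                            "ACGT"[int(rng.integers(0, 4))])
            site = "".join(site)
            got = score_duplex(mirna, site)
            assert got.expectation == pytest.approx(oracle_score(mirna, site))

    def test_limit_pruning_never_loses_hits(self, rng):
        """With limit=cutoff, a site at or below the cutoff is always scored."""
        for _ in range(100):
            mirna = random_seq(rng, 21)
            site = list(reverse_complement(mirna))
            for p in rng.choice(21, size=2, replace=False):
                site[p] = "ACGT"[int(rng.integers(0, 4))]
            site = "".join(site)
            full = score_duplex(mirna, site)
            limited = score_duplex(mirna, site, limit=CFG.max_expectation)
            if full.expectation <= CFG.max_expectation:
                assert limited is not None
                assert limited.expectation == full.expectation


class TestScanTranscripts:
    def test_planted_perfect_site_found_at_exact_position(self, rng):
        mirna = SequenceRecord("miR1", random_seq(rng, 21))
        site = reverse_complement(mirna.seq)
        for _ in range(10):
            pos = int(rng.integers(0, 480))
            tx = random_seq(rng, 500)
            tx = tx[:pos] + site + tx[pos + 21:]
            hits = scan_transcripts(
                mirna, ReferenceSet("t", [SequenceRecord("tx1", tx)],
                                    "transcript"), CFG)
            exact = [h for h in hits if h.expectation == 0.0]
            assert exact and exact[0].site_start == pos + 1
            assert exact[0].site_end == pos + 21
            assert exact[0].inhibition == "cleavage"

    def test_poly_a_transcript_has_no_hits(self):
        mirna = SequenceRecord("miR1", "GCGCGCGCGCGCGCGCGCGCG")
        tx = ReferenceSet("t", [SequenceRecord("tx1", "A" * 300)], "transcript")
        assert scan_transcripts(mirna, tx, CFG) == []

    def test_lowering_cutoff_never_adds_hits(self, rng):
        mirna = SequenceRecord("miR1", random_seq(rng, 21))
        site = list(reverse_complement(mirna.seq))
        site[3] = "ACGT"[int(rng.integers(0, 4))]
        tx_seq = random_seq(rng, 200) + "".join(site) + random_seq(rng, 200)
        tx = ReferenceSet("t", [SequenceRecord("tx1", tx_seq)], "transcript")
        strict = scan_transcripts(mirna, tx, TargetScoringConfig(max_expectation=1.0))
        loose = scan_transcripts(mirna, tx, TargetScoringConfig(max_expectation=3.0))
        strict_keys = {(h.transcript, h.site_start) for h in strict}
        loose_keys = {(h.transcript, h.site_start) for h in loose}
        assert strict_keys <= loose_keys

    def test_short_mirna_yields_no_hits(self):
        mirna = SequenceRecord("short", "ACGTACGTACGTACGTAC")  # 18 < 19
        tx = ReferenceSet("t", [SequenceRecord(
            "tx1", reverse_complement(mirna.seq) * 3)], "transcript")
        assert scan_transcripts(mirna, tx, CFG) == []

    def test_central_mismatch_marks_translational_inhibition(self, rng):
        mirna = SequenceRecord("miR1", random_seq(rng, 21))
        site = list(reverse_complement(mirna.seq))
        i = 21 - 10                      # miRNA position 10
        site[i] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[i]]
        tx = ReferenceSet("t", [SequenceRecord("tx1", "".join(site))],
                          "transcript")
        hits = scan_transcripts(mirna, tx, CFG)
        assert hits and hits[0].inhibition == "translation"


class TestNetwork:
    def _de(self, mirna, call):
        return DifferentialResult(mirna=mirna, log2_fc=2.0 if call == "up" else -2.0,
                                  p_value=0.001, call=call)

    def _hit(self, mirna, tx):
        from mircms.targets import TargetHit
        return TargetHit(mirna=mirna, transcript=tx, expectation=1.0,
                         alignment="", site_start=1, site_end=21,
                         inhibition="cleavage")

    def test_de_mirna_with_three_hits_gives_three_edges(self):
        de = [self._de("miR1", "up")]
        hits = [self._hit("miR1", f"tx{i}") for i in range(3)]
        edges, graph, skipped = build_network(de, hits)
        assert len(edges) == 3 and graph.number_of_edges() == 3

    def test_non_de_mirna_contributes_no_edges(self):
        de = [self._de("miR1", "ns")]
        edges, _, _ = build_network(de, [self._hit("miR1", "tx1")])
        assert edges == []

    def test_dangling_mirna_skipped_and_counted(self):
        edges, _, skipped = build_network([], [self._hit("ghost", "tx1")])
        assert edges == [] and skipped == 1

    def test_negative_correlation_when_target_moves_opposite(self):
        de = [self._de("miR1", "up")]
        edges, _, _ = build_network(de, [self._hit("miR1", "tx1")],
                                    target_expr={"tx1": "down"})
        assert edges[0].correlation == "negative"

    def test_sif_export(self, tmp_path):
        edges = [NetworkEdge("miR1", "tx1", "up", "negative")]
        p = tmp_path / "net.sif"
        write_sif(edges, p)
        assert p.read_text() == "miR1\ttargets\ttx1\n"
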