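"""Plant miRNA target prediction and the miRNA-target network.

Complementarity is scored with the classic plant expectation scheme: each
duplex position costs 1 for a mismatch, 0.5 for a G:U wobble and 2 for an
indel, doubled inside the 5' seed (miRNA positions 2-13); a site qualifies
when the summed expectation stays at or below the cutoff (3.0 by default,
the psRNATarget-style setting).  Cleavage vs translational inhibition is
decided by pairing at the central positions 9-11.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .sequence_io import ReferenceSet, SequenceRecord
from .differential import DifferentialResult

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}   # rna G:U, in DNA spelling


class AlignmentError(ValueError):
    pass


@dataclass
class TargetScoringConfig:
    max_expectation: float = 3.0
    seed_start: int = 2           # miRNA positions (1-based, from 5')
    seed_end: int = 13
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    indel_penalty: float = 2.0
    seed_multiplier: float = 2.0
    max_indels: int = 1
    min_complementary_len: int = 19
    central_start: int = 9        # cleavage/translation rule
    central_end: int = 11

    def __post_init__(self) -> None:
        for name in ("mismatch_penalty", "wobble_penalty", "indel_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed_start < 1 or self.seed_end < self.seed_start:
            raise ValueError("bad seed region")


@dataclass
class DuplexScore:
    expectation: float
    alignment: str                # three-line pretty alignment
    per_position: Dict[int, float]  # miRNA position -> penalty paid


@dataclass
class TargetHit:
    mirna: str
    transcript: str
    expectation: float
    alignment: str
    site_start: int               # 1-based inclusive on the transcript
    site_end: int
    inhibition: str               # cleavage | translation


@dataclass
class NetworkEdge:
    mirna: str
    target_gene: str
    direction: str                # up | down (miRNA DE call)
    correlation: str              # negative | unknown


def _pair_kind(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "match"
    if (m, t) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _score_alignment(mirna: str, site_rev: str, gap: Optional[Tuple[str, int]],
                     cfg: TargetScoringConfig, limit: Optional[float] = None):
    """Score one alignment of mirna (5'->3') vs reversed site.

    ``gap`` is None (equal length) or ("site"|"mirna", g): a single gap
    opened before alignment column g (0-based).  With ``limit`` set the
    scan aborts (returns None) once the running total exceeds it; an
    alignment over the cutoff can never yield a hit, so this is exact.
    """
    per: Dict[int, float] = {}
    lines_m, lines_s, lines_b = [], [], []
    mi = si = 0
    pos = 0          # 1-based miRNA position of the current column
    total = 0.0
    ncols = max(len(mirna), len(site_rev))
    for col in range(ncols):
        if gap is not None and col == gap[1]:
            kind, _ = gap
            if kind == "site":     # miRNA base bulged out
                mpos = mi + 1
                pen = cfg.indel_penalty
                if cfg.seed_start <= mpos <= cfg.seed_end:
                    pen *= cfg.seed_multiplier
                per[mpos] = per.get(mpos, 0.0) + pen
                total += pen
                if limit is not None and total > limit:
                    return None
                lines_m.append(mirna[mi]); lines_s.append("-"); lines_b.append(" ")
                mi += 1
                continue
            else:                  # target base bulged out; charge next miRNA pos
                mpos = min(mi + 1, len(mirna))
                pen = cfg.indel_penalty
                if cfg.seed_start <= mpos <= cfg.seed_end:
                    pen *= cfg.seed_multiplier
                per[mpos] = per.get(mpos, 0.0) + pen
                total += pen
                if limit is not None and total > limit:
                    return None
                lines_m.append("-"); lines_s.append(site_rev[si]); lines_b.append(" ")
                si += 1
                continue
        m, t = mirna[mi], site_rev[si]
        mpos = mi + 1
        kind = _pair_kind(m, t)
        pen = {"match": 0.0, "wobble": cfg.wobble_penalty,
               "mismatch": cfg.mismatch_penalty}[kind]
        if pen and cfg.seed_start <= mpos <= cfg.seed_end:
            pen *= cfg.seed_multiplier
        if pen:
            per[mpos] = per.get(mpos, 0.0) + pen
        total += pen
        if limit is not None and total > limit:
            return None
        lines_m.append(m)
        lines_s.append(t)
        lines_b.append({"match": "|", "wobble": "o", "mismatch": " "}[kind])
        mi += 1
        si += 1
    aln = (f"miRNA  5' {''.join(lines_m)} 3'\n"
           f"          {''.join(lines_b)}\n"
           f"target 3' {''.join(lines_s)} 5'")
    return total, aln, per


def score_duplex(mirna_seq: str, site_seq: str,
                 cfg: TargetScoringConfig = TargetScoringConfig(),
                 limit: Optional[float] = None) -> Optional[DuplexScore]:
    """Expectation for a miRNA aligned antiparallel to a target site.

    Both sequences are given 5'->3'; the site is reversed internally so that
    miRNA position 1 faces the site's 3' end.  At most ``max_indels`` length
    difference is allowed; the minimum over single-gap placements is taken,
    ties resolved toward the 5'-most gap.  With ``limit`` set, None is
    returned when every alignment exceeds it (used by the transcript scan).
    """
    mirna = mirna_seq.upper().replace("U", "T")
    site = site_seq.upper().replace("U", "T")
    diff = len(site) - len(mirna)
    if abs(diff) > cfg.max_indels:
        raise AlignmentError(
            f"length difference {abs(diff)} exceeds max_indels={cfg.max_indels}")
    site_rev = site[::-1]
    if diff == 0:
        scored = _score_alignment(mirna, site_rev, None, cfg, limit)
        return DuplexScore(*scored) if scored else None
    kind = "site" if diff < 0 else "mirna"   # gap opened in the shorter strand
    ncols = max(len(mirna), len(site))
    best = None
    for g in range(ncols):
        if limit is not None:
            # a gap inside the seed costs indel*multiplier on its own; skip
            # placements that could never stay under the limit (exact pruning)
            gap_pos = min(g + 1, len(mirna))
            pen = cfg.indel_penalty
            if cfg.seed_start <= gap_pos <= cfg.seed_end:
                pen *= cfg.seed_multiplier
            if pen > limit:
                continue
        scored = _score_alignment(mirna, site_rev, (kind, g), cfg, limit)
        if scored and (best is None or scored[0] < best[0]):
            best = scored
    return DuplexScore(*best) if best else None


def scan_transcripts(mirna: SequenceRecord, transcripts: ReferenceSet,
                     cfg: TargetScoringConfig = TargetScoringConfig()) -> List[TargetHit]:
    """All target sites with expectation <= cutoff, deduplicated and ordered.

    Overlapping sites on one transcript keep only the lowest expectation;
    output order is (expectation, transcript id, position).
    """
    L = len(mirna.seq)
    if L < cfg.min_complementary_len:
        return []
    raw_hits: List[TargetHit] = []
    for rec in sorted(transcripts.records, key=lambda r: r.id):
        n = len(rec.seq)
        for wlen in range(L - cfg.max_indels, L + cfg.max_indels + 1):
            if wlen <= 0 or wlen > n:
                continue
            for start in range(0, n - wlen + 1):
                window = rec.seq[start:start + wlen]
                score = score_duplex(mirna.seq, window, cfg,
                                     limit=cfg.max_expectation)
                if score is not None and score.expectation <= cfg.max_expectation:
                    central = any(
                        p in score.per_position
                        for p in range(cfg.central_start, cfg.central_end + 1))
                    raw_hits.append(TargetHit(
                        mirna=mirna.id, transcript=rec.id,
                        expectation=score.expectation, alignment=score.alignment,
                        site_start=start + 1, site_end=start + wlen,
                        inhibition="translation" if central else "cleavage"))
    # deduplicate overlapping sites per transcript, keep lowest expectation
    raw_hits.sort(key=lambda h: (h.expectation, h.transcript, h.site_start))
    kept: List[TargetHit] = []
    for hit in raw_hits:
        clash = any(k.transcript == hit.transcript
                    and not (hit.site_end < k.site_start or hit.site_start > k.site_end)
                    for k in kept)
        if not clash:
            kept.append(hit)
    return kept


def hits_frame(hits: List[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna": h.mirna, "transcript": h.transcript,
        "expectation": h.expectation, "site_start": h.site_start,
        "site_end": h.site_end, "inhibition": h.inhibition,
    } for h in hits])


def build_network(de: List[DifferentialResult], hits: List[TargetHit],
                  target_expr: Optional[Dict[str, str]] = None):
    """Edges for DE miRNAs only; returns (edges, graph, skipped_count).

    ``target_expr`` optionally maps transcript id -> "up"/"down"; an edge is
    negatively correlated when the target moves opposite to the miRNA call.
    """
    calls = {r.mirna: r.call for r in de}
    edges: List[NetworkEdge] = []
    skipped = 0
    seen = set()
    for hit in hits:
        call = calls.get(hit.mirna)
        if call is None:
            skipped += 1
            continue
        if call not in ("up", "down"):
            continue
        key = (hit.mirna, hit.transcript)
        if key in seen:
            continue
        seen.add(key)
        corr = "unknown"
        if target_expr and hit.transcript in target_expr:
            texpr = target_expr[hit.transcript]
            if (call == "up" and texpr == "down") or (call == "down" and texpr == "up"):
                corr = "negative"
        edges.append(NetworkEdge(hit.mirna, hit.transcript, call, corr))
    graph = nx.DiGraph()
    for e in edges:
        graph.add_edge(e.mirna, e.target_gene, direction=e.direction,
                       correlation=e.correlation)
    return edges, graph, skipped


def write_sif(edges: List[NetworkEdge], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for e in edges:
            fh.write(f"{e.mirna}\ttargets\t{e.target_gene}\n")


def write_edge_tsv(edges: List[NetworkEdge], path) -> None:
    pd.DataFrame([{
        "mirna": e.mirna, "target": e.target_gene,
        "mirna_call": e.direction, "correlation": e.correlation,
    } for e in edges]).to_csv(path, sep="\t", index=False)
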