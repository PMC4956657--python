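"""Novel miRNA hairpin discovery from unannotated tags.

Unannotated tags of mature length mapping perfectly to <= ``max_multimap_loci``
genomic loci are excised in two windows (tag biased toward either hairpin
arm), folded, and screened with the community duplex criteria: mature arm on
one side of the loop, limited duplex mismatches and asymmetric bulges, a
mostly-paired mature, and a star strand defined by the canonical 2-nt 3'
overhang.  A star actually present in the sequenced tags upgrades the
candidate to star-observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .fold import FoldResult, fold, pair_table
from .sequence_io import (Locus, ReferenceSet, SequenceRecord, SequenceTag,
                          reverse_complement)


@dataclass
class NovelCriteria:
    """Numeric hairpin/duplex criteria (all config-exposed)."""

    mature_len: Tuple[int, int] = (20, 24)
    flank_short: int = 20
    flank_long: int = 160
    max_duplex_mismatch: int = 4
    max_asym_bulge: int = 2
    star_overhang: int = 2
    min_mfe_magnitude: float = 18.0
    min_paired_frac_mature: float = 0.6
    max_multimap_loci: int = 15
    min_reads: int = 5          # abundance prescreen before excision
    # "auto" = thermodynamic folder when available, scored DP otherwise
    fold_backend: str = "auto"

    def __post_init__(self) -> None:
        for name in ("flank_short", "flank_long", "max_multimap_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ExcisedWindow:
    """A candidate precursor window on the mature strand."""

    record: SequenceRecord     # window sequence, precursor orientation
    locus: Locus               # window location, forward reference coords
    tag_start: int             # mature offset within the window
    bias: str                  # "5p" (tag near 5' end) or "3p"


@dataclass
class Rejection:
    reason: str
    detail: str = ""

    def __bool__(self) -> bool:
        return False


@dataclass
class HairpinCandidate:
    name: str
    precursor: SequenceRecord
    locus: Locus
    fold: FoldResult
    mature: SequenceTag
    mature_arm: str            # "5p" | "3p"
    star: Optional[SequenceTag]
    star_arm: Optional[str]
    star_observed: bool
    duplex_mismatches: int
    asymmetry: int
    paired_frac: float
    mature_offset: int = 0

    def __bool__(self) -> bool:
        return True

    @property
    def lp(self) -> int:
        return len(self.precursor.seq)

    @property
    def mfe(self) -> float:
        return self.fold.mfe


def map_exact(tag_seq: str, genome: ReferenceSet) -> List[Locus]:
    """All perfect-match loci of the tag, both strands, deterministic order."""
    loci = []
    rc = reverse_complement(tag_seq)
    for rec in sorted(genome.records, key=lambda r: r.id):
        for strand, query in (("+", tag_seq), ("-", rc)):
            start = rec.seq.find(query)
            while start != -1:
                loci.append(Locus(rec.id, start, start + len(query), strand))
                start = rec.seq.find(query, start + 1)
    return loci


def excise_candidates(tag: SequenceTag, genome: ReferenceSet,
                      crit: NovelCriteria) -> List[ExcisedWindow]:
    """Two precursor windows per mapped locus, clipped to reference bounds.

    Minus-strand loci are reverse-complemented so the mature tag always sits
    on the precursor strand.
    """
    loci = map_exact(tag.seq, genome)
    if not loci or len(loci) > crit.max_multimap_loci:
        return []
    seqs = {rec.id: rec.seq for rec in genome.records}
    out = []
    for locus in loci:
        ref_seq = seqs[locus.ref]
        n = len(ref_seq)
        if locus.strand == "+":
            plans = (("5p", locus.start - crit.flank_short, locus.end + crit.flank_long),
                     ("3p", locus.start - crit.flank_long, locus.end + crit.flank_short))
        else:
            # on the minus strand, upstream of the tag = downstream in + coords
            plans = (("5p", locus.start - crit.flank_long, locus.end + crit.flank_short),
                     ("3p", locus.start - crit.flank_short, locus.end + crit.flank_long))
        for bias, lo, hi in plans:
            lo, hi = max(0, lo), min(n, hi)
            window = ref_seq[lo:hi]
            if locus.strand == "-":
                window = reverse_complement(window)
                tag_start = hi - locus.end
            else:
                tag_start = locus.start - lo
            rec = SequenceRecord(
                f"{locus.ref}:{lo + 1}-{hi}({locus.strand})", window)
            out.append(ExcisedWindow(rec, Locus(locus.ref, lo, hi, locus.strand),
                                     tag_start, bias))
    return out


def _project(pt, mature_lo: int, mature_hi: int, x: int) -> int:
    """Project mature coordinate x onto the opposite arm via the pair table.

    Uses the nearest paired mature base and the antiparallel register.
    """
    paired = [i for i in range(mature_lo, mature_hi) if pt[i] is not None]
    c = min(paired, key=lambda i: (abs(i - x), i))
    return pt[c] - (x - c)


def evaluate_hairpin(window: Union[ExcisedWindow, SequenceRecord],
                     tag: SequenceTag, all_tags: Iterable[SequenceTag],
                     crit: NovelCriteria) -> Union[HairpinCandidate, Rejection]:
    """Screen one precursor window; returns a candidate or a typed rejection."""
    if isinstance(window, ExcisedWindow):
        rec, locus, m0 = window.record, window.locus, window.tag_start
    else:
        rec, locus = window, Locus(window.id, 0, len(window.seq), "+")
        m0 = rec.seq.find(tag.seq)

    L = len(tag.seq)
    if not (crit.mature_len[0] <= L <= crit.mature_len[1]):
        return Rejection("mature_length", f"{L} nt")
    if m0 < 0 or rec.seq[m0:m0 + L] != tag.seq:
        return Rejection("mature_not_in_window")
    m1 = m0 + L

    result = fold(rec.seq, backend=crit.fold_backend)
    pt = pair_table(result.structure)

    partners = [pt[i] for i in range(m0, m1) if pt[i] is not None]
    if not partners:
        return Rejection("mature_unpaired")
    if all(p >= m1 for p in partners):
        arm = "5p"
    elif all(p < m0 for p in partners):
        arm = "3p"
    else:
        return Rejection("spans_loop", "mature pairs on both sides of itself")

    paired_frac = len(partners) / L
    mismatches = L - len(partners)
    if mismatches > crit.max_duplex_mismatch:
        return Rejection("duplex_mismatches", f"{mismatches} > {crit.max_duplex_mismatch}")
    if paired_frac < crit.min_paired_frac_mature:
        return Rejection("low_pairing", f"{paired_frac:.2f}")

    paired_idx = [i for i in range(m0, m1) if pt[i] is not None]
    asym = 0
    for a, b in zip(paired_idx, paired_idx[1:]):
        gap_m = b - a - 1
        gap_s = abs(pt[a] - pt[b]) - 1
        asym = max(asym, abs(gap_m - gap_s))
    if asym > crit.max_asym_bulge:
        return Rejection("asymmetric_bulge", f"{asym} nt > {crit.max_asym_bulge}")

    if (result.energy_model == "thermodynamic"
            and abs(result.mfe) < crit.min_mfe_magnitude):
        return Rejection("weak_mfe", f"|{result.mfe}| < {crit.min_mfe_magnitude}")

    # star: duplex partner with the canonical 2-nt 3' overhang
    ovh = crit.star_overhang
    s_lo = _project(pt, m0, m1, m1 - 1 - ovh)
    s_hi = _project(pt, m0, m1, m0) + ovh
    s_lo, s_hi = min(s_lo, s_hi), max(s_lo, s_hi)
    s_lo, s_hi = max(0, s_lo), min(len(rec.seq) - 1, s_hi)
    star_seq = rec.seq[s_lo:s_hi + 1]
    star_arm = "3p" if arm == "5p" else "5p"
    observed: Dict[str, SequenceTag] = {t.seq: t for t in all_tags}
    star_tag = observed.get(star_seq)
    star_observed = star_tag is not None
    if star_tag is None and star_seq:
        star_tag = SequenceTag(seq=star_seq, counts={"predicted": 1},
                               id=f"{tag.id}*")

    return HairpinCandidate(
        name="", precursor=rec, locus=locus, fold=result, mature=tag,
        mature_arm=arm, star=star_tag, star_arm=star_arm,
        star_observed=star_observed, duplex_mismatches=mismatches,
        asymmetry=asym, paired_frac=paired_frac, mature_offset=m0)


def discover(tags: List[SequenceTag], genome: ReferenceSet, crit: NovelCriteria,
             name_prefix: str = "miRn") -> List[HairpinCandidate]:
    """Full discovery pass over unannotated tags.

    Tags are visited in descending abundance (then sequence); accepted
    candidates are deduplicated by mature locus so either excision window may
    supply the hairpin, and named ``miRn1..k`` in discovery order.
    """
    order = sorted(tags, key=lambda t: (-t.total, t.seq))
    accepted: List[HairpinCandidate] = []

    def duplicate_locus(win: ExcisedWindow, L: int) -> bool:
        # one hairpin, two arms: a tag whose genomic footprint falls inside
        # an already-accepted precursor is the same locus (e.g. the star)
        if win.locus.strand == "+":
            s = win.locus.start + win.tag_start
        else:
            s = win.locus.end - win.tag_start - L
        return any(c.locus.ref == win.locus.ref
                   and s < c.locus.end and c.locus.start < s + L
                   for c in accepted)

    for tag in order:
        if tag.total < crit.min_reads:
            continue
        if not (crit.mature_len[0] <= len(tag.seq) <= crit.mature_len[1]):
            continue
        for win in excise_candidates(tag, genome, crit):
            if duplicate_locus(win, len(tag.seq)):
                continue
            cand = evaluate_hairpin(win, tag, tags, crit)
            if cand:
                cand.name = f"{name_prefix}{len(accepted) + 1}"
                if cand.star is not None:
                    cand.star.id = f"{cand.name}*"
                accepted.append(cand)
                break
    return accepted


def candidate_frame(candidates: List[HairpinCandidate],
                    libraries=("WA", "WB")):
    """Tabular novel-candidate report (mature + star rows per candidate)."""
    import pandas as pd

    rows = []
    for c in candidates:
        loc_1based = f"{c.locus.ref}:{c.locus.start + 1}-{c.locus.end}({c.locus.strand})"
        rows.append({
            "name": c.name,
            **{lib: c.mature.count(lib) for lib in libraries},
            "mature_seq": c.mature.seq, "arm": c.mature_arm,
            "size": len(c.mature.seq), "lp": c.lp,
            "mfe": round(c.mfe, 2), "energy_model": c.fold.energy_model,
            "location": loc_1based, "star_observed": c.star_observed,
        })
        if c.star is not None and c.star_observed:
            rows.append({
                "name": f"{c.name}*",
                **{lib: c.star.count(lib) for lib in libraries},
                "mature_seq": c.star.seq, "arm": c.star_arm,
                "size": len(c.star.seq), "lp": c.lp,
                "mfe": round(c.mfe, 2), "energy_model": c.fold.energy_model,
                "location": loc_1based, "star_observed": True,
            })
    return pd.DataFrame(rows)
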