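"""Tag classification (ncRNA / known miRNA / unannotated) and family tables.

Matching is ungapped Hamming distance of the whole tag against every
equal-length window of each reference sequence (both strands for genome-like
sets, forward only otherwise), the gapless mismatch mode of short-read
aligners.  The ncRNA structural categories take priority over miRNA, which
reproduces the usual subtract-then-identify order of small-RNA pipelines.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_io import ReferenceSet, SequenceTag, reverse_complement

CATEGORIES = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "unannotated")
NCRNA_SUBTYPES = ("rRNA", "tRNA", "snRNA", "snoRNA")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class ConfigurationError(ValueError):
    pass


@dataclass
class AnnotationConfig:
    max_mismatch_ref: int = 2
    max_mismatch_mirbase: int = 2
    category_priority: Tuple[str, ...] = (
        "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "unannotated")

    def __post_init__(self) -> None:
        if self.max_mismatch_ref < 0 or self.max_mismatch_mirbase < 0:
            raise ConfigurationError("mismatch bounds must be >= 0")


@dataclass
class Hit:
    hit_id: str
    mismatches: int
    strand: str = "+"
    pos: int = 0  # 0-based window start on the reference (forward coords)


@dataclass
class AnnotationRecord:
    tag: SequenceTag
    category: str
    hit_id: Optional[str] = None
    mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "unannotated") != (self.hit_id is None):
            raise ValueError("unannotated <=> hit_id absent")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _WindowIndex:
    """All equal-length windows of a reference set, grouped by length.

    Window order encodes the deterministic tie-break: ascending record id
    (lexicographic), '+' strand before '-', then position.
    """

    def __init__(self, ref: ReferenceSet):
        self.ref = ref
        entries = []  # (rec_id, strand, rec_seq)
        for rec in sorted(ref.records, key=lambda r: r.id):
            entries.append((rec.id, "+", rec.seq))
            if ref.both_strands:
                entries.append((rec.id, "-", reverse_complement(rec.seq)))
        self.entries = entries
        self._cache: Dict[int, tuple] = {}

    def windows(self, length: int):
        """(matrix n_windows x length, meta list of (id, strand, pos))."""
        if length in self._cache:
            return self._cache[length]
        rows, meta = [], []
        for rid, strand, seq in self.entries:
            n = len(seq)
            if n < length:
                continue
            enc = _encode(seq)
            win = np.lib.stride_tricks.sliding_window_view(enc, length)
            rows.append(win)
            for p in range(n - length + 1):
                # report forward-strand coordinates for '-' windows
                pos = p if strand == "+" else n - length - p
                meta.append((rid, strand, pos))
        if rows:
            mat = np.concatenate(rows, axis=0)
        else:
            mat = np.empty((0, length), dtype=np.uint8)
        self._cache[length] = (mat, meta)
        return self._cache[length]


def _batch_best_hits(seqs: Sequence[str], index: _WindowIndex, k: int,
                     chunk: int = 2048) -> List[Optional[Hit]]:
    """Best hit (fewest mismatches, then window order) per tag sequence."""
    out: List[Optional[Hit]] = [None] * len(seqs)
    by_len: Dict[int, List[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idxs in by_len.items():
        mat, meta = index.windows(length)
        if mat.shape[0] == 0:
            continue
        enc = np.stack([_encode(seqs[i]) for i in idxs])
        for lo in range(0, len(idxs), chunk):
            sub = enc[lo:lo + chunk]
            # mismatches: N never matches (distinct byte) => counted, which is
            # conservative and consistent with the brute-force definition
            mism = length - (sub[:, None, :] == mat[None, :, :]).sum(axis=2)
            best_w = np.argmin(mism, axis=1)
            best_m = mism[np.arange(len(sub)), best_w]
            for row, (w, m) in enumerate(zip(best_w, best_m)):
                if m <= k:
                    rid, strand, pos = meta[int(w)]
                    out[idxs[lo + row]] = Hit(rid, int(m), strand, pos)
    return out


def match_with_mismatches(tag_seq: str, ref: ReferenceSet, k: int) -> Optional[Hit]:
    """Best ungapped hit of ``tag_seq`` in ``ref`` with <= k mismatches.

    Ties break by fewest mismatches, then lexicographically smallest hit id
    (then '+' strand, then leftmost window).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return _batch_best_hits([tag_seq], _WindowIndex(ref), k)[0]


def _ncrna_subtype(hit_id: str) -> str:
    low = hit_id.lower()
    for sub in NCRNA_SUBTYPES:
        if sub.lower() in low:
            return sub
    return "rRNA"  # untyped structural ncRNA defaults to the top category


def annotate_tags(tags: List[SequenceTag], refs: List[ReferenceSet],
                  cfg: AnnotationConfig) -> List[AnnotationRecord]:
    """Assign each tag exactly one category by the configured priority."""
    by_kind: Dict[str, List[ReferenceSet]] = {}
    for ref in refs:
        by_kind.setdefault(ref.kind, []).append(ref)
    if "ncRNA" not in by_kind or "mature" not in by_kind:
        raise ConfigurationError("need at least an ncRNA and a mature reference set")

    seqs = [t.seq for t in tags]
    nc_hits: List[Optional[Hit]] = [None] * len(tags)
    for ref in by_kind["ncRNA"]:
        hits = _batch_best_hits(seqs, _WindowIndex(ref), cfg.max_mismatch_ref)
        for i, h in enumerate(hits):
            if h and (nc_hits[i] is None or (h.mismatches, h.hit_id)
                      < (nc_hits[i].mismatches, nc_hits[i].hit_id)):
                nc_hits[i] = h

    mi_hits: List[Optional[Hit]] = [None] * len(tags)
    for kind in ("mature", "precursor"):
        for ref in by_kind.get(kind, []):
            hits = _batch_best_hits(seqs, _WindowIndex(ref), cfg.max_mismatch_mirbase)
            for i, h in enumerate(hits):
                if h and (mi_hits[i] is None or (h.mismatches, h.hit_id)
                          < (mi_hits[i].mismatches, mi_hits[i].hit_id)):
                    mi_hits[i] = h

    records = []
    for i, tag in enumerate(tags):
        per_category: Dict[str, Hit] = {}
        if nc_hits[i]:
            per_category[_ncrna_subtype(nc_hits[i].hit_id)] = nc_hits[i]
        if mi_hits[i]:
            per_category["miRNA"] = mi_hits[i]
        chosen = None
        for cat in cfg.category_priority:
            if cat in per_category:
                chosen = (cat, per_category[cat])
                break
        if chosen is None:
            records.append(AnnotationRecord(tag, "unannotated"))
        else:
            cat, hit = chosen
            records.append(AnnotationRecord(tag, cat, hit.hit_id, hit.mismatches))
    return records


def category_table(records: List[AnnotationRecord],
                   libraries: Sequence[str]) -> pd.DataFrame:
    """Category x library table of (unique, total) counts with percentages."""
    rows = []
    for cat in ("Total",) + CATEGORIES:
        row: Dict[str, object] = {"category": cat}
        for lib in libraries:
            if cat == "Total":
                uni = sum(1 for r in records if r.tag.count(lib) > 0)
                tot = sum(r.tag.count(lib) for r in records)
            else:
                uni = sum(1 for r in records
                          if r.category == cat and r.tag.count(lib) > 0)
                tot = sum(r.tag.count(lib) for r in records if r.category == cat)
            row[f"{lib}_unique"] = uni
            row[f"{lib}_total"] = tot
        rows.append(row)
    df = pd.DataFrame(rows)
    from .preprocess import fraction_pct
    for lib in libraries:
        tot_u = df.loc[df.category == "Total", f"{lib}_unique"].iloc[0]
        tot_t = df.loc[df.category == "Total", f"{lib}_total"].iloc[0]
        df[f"{lib}_unique_pct"] = [fraction_pct(v, tot_u) for v in df[f"{lib}_unique"]]
        df[f"{lib}_total_pct"] = [fraction_pct(v, tot_t) for v in df[f"{lib}_total"]]
    return df


# ---------------------------------------------------------------------------
# miRNA families
# ---------------------------------------------------------------------------

@dataclass
class FamilyAbundance:
    family: str
    members: List[str]
    reads: Dict[str, int]
    total: int
    ratio: Optional[float]  # None rendered as "-" when the denominator is 0

    def ratio_str(self) -> str:
        return "-" if self.ratio is None else f"{self.ratio:.2f}"


_FAMILY_RE = re.compile(r"(?:[a-zA-Z0-9]+-)?([mM]iRn?[0-9]+)")


def default_family(mature_id: str) -> str:
    """Strip species prefix and letter/arm suffix: 'rsa-miR156a-5p' -> 'miR156'."""
    m = _FAMILY_RE.search(mature_id)
    if m:
        name = m.group(1)
        return "miR" + name[3:] if name.startswith("MiR") else name
    return mature_id


def load_family_alias(path=None) -> Dict[str, str]:
    """Family alias TSV (family merging is curation, shipped as data)."""
    if path is None:
        ref = importlib.resources.files("mircms").joinpath("data/family_alias.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    alias = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, fam = line.split("\t")[:2]
        alias[key] = fam
    return alias


def family_table(records: List[AnnotationRecord],
                 alias: Optional[Dict[str, str]] = None,
                 libraries: Sequence[str] = ("WA", "WB")) -> List[FamilyAbundance]:
    """Aggregate miRNA-annotated tags into families with per-library reads.

    The WA/WB ratio is raw read counts rounded to 2 decimals; a family absent
    from the denominator library reports no ratio.
    """
    alias = alias or {}
    groups: Dict[str, Dict[str, object]] = {}
    for rec in records:
        if rec.category != "miRNA":
            continue
        base = default_family(rec.hit_id)
        fam = alias.get(rec.hit_id, alias.get(base, base))
        g = groups.setdefault(fam, {"members": set(), "reads": {l: 0 for l in libraries}})
        g["members"].add(rec.hit_id)
        for lib in libraries:
            g["reads"][lib] += rec.tag.count(lib)
    out = []
    for fam in sorted(groups):
        g = groups[fam]
        reads = g["reads"]
        total = sum(reads.values())
        num, den = reads[libraries[0]], reads[libraries[1]]
        ratio = round(num / den, 2) if den > 0 else None
        out.append(FamilyAbundance(fam, sorted(g["members"]), dict(reads), total, ratio))
    return out


def family_frame(families: List[FamilyAbundance],
                 libraries: Sequence[str] = ("WA", "WB")) -> pd.DataFrame:
    rows = [{"family": f.family, "members": len(f.members),
             **{lib: f.reads.get(lib, 0) for lib in libraries},
             "total": f.total, "ratio": f.ratio_str()} for f in families]
    return pd.DataFrame(rows)
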