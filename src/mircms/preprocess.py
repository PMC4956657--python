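"""Raw reads -> clean, collapsed tags and per-library summary statistics.

The cleaning cascade follows the usual small-RNA recipe: quality filter,
5' primer-contaminant filter, 3' adapter trim, poly-A filter, N filter and
finally the 18-30 nt length gate.  Every filter is conservative accounting:
reads_in == reads_kept + sum(reads_removed per reason).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .sequence_io import SequenceRecord, SequenceTag

FILTER_ORDER = ("low_quality", "contaminant_5p", "poly_a", "with_n", "length")


@dataclass
class PreprocessConfig:
    """Knobs for read cleaning (defaults are the pipeline's study settings)."""

    min_len: int = 18
    max_len: int = 30
    adapter3: Optional[str] = None
    min_qual: Optional[float] = 20.0
    drop_polyA: bool = True
    drop_5p_contaminant: Optional[str] = None
    polyA_frac: float = 0.8
    adapter_min_overlap: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass
class FilterResult:
    """Clean reads plus an itemised removal log."""

    kept: List[SequenceRecord]
    removed: Dict[str, int]
    n_input: int

    def __iter__(self):
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)

    @property
    def conserved(self) -> bool:
        return self.n_input == len(self.kept) + sum(self.removed.values())


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def _find_adapter(seq: str, adapter: str, min_overlap: int) -> int:
    """Leftmost 3' adapter start, allowing 1 mismatch per 10 nt of overlap.

    Returns len(seq) when no acceptable occurrence is found.
    """
    n, la = len(seq), len(adapter)
    for i in range(n - min_overlap + 1):
        overlap = min(la, n - i)
        allowed = overlap // 10
        mism = 0
        for a, b in zip(seq[i:i + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return i
    return n


def clean_reads(reads: List[SequenceRecord], cfg: PreprocessConfig) -> FilterResult:
    """Apply the cleaning cascade; never raises on read content."""
    kept: List[SequenceRecord] = []
    removed = Counter({k: 0 for k in FILTER_ORDER})
    for rec in reads:
        if (cfg.min_qual is not None and rec.qual is not None
                and _mean_phred(rec.qual) < cfg.min_qual):
            removed["low_quality"] += 1
            continue
        if cfg.drop_5p_contaminant and rec.seq.startswith(cfg.drop_5p_contaminant):
            removed["contaminant_5p"] += 1
            continue
        seq, qual = rec.seq, rec.qual
        if cfg.adapter3:
            cut = _find_adapter(seq, cfg.adapter3, cfg.adapter_min_overlap)
            seq = seq[:cut]
            qual = qual[:cut] if qual is not None else None
        if not seq:
            removed["length"] += 1
            continue
        if cfg.drop_polyA and seq.count("A") / len(seq) >= cfg.polyA_frac:
            removed["poly_a"] += 1
            continue
        if "N" in seq:
            removed["with_n"] += 1
            continue
        if not (cfg.min_len <= len(seq) <= cfg.max_len):
            removed["length"] += 1
            continue
        kept.append(SequenceRecord(rec.id, seq, qual))
    return FilterResult(kept=kept, removed=dict(removed), n_input=len(reads))


def collapse(reads: List[SequenceRecord], library: str) -> List[SequenceTag]:
    """Collapse identical sequences to tags; sum of counts == len(reads).

    Tags are ordered by descending count then sequence, ids ``t1..tN``.
    """
    counts = Counter(rec.seq for rec in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [SequenceTag(seq=s, counts={library: c}, id=f"t{i+1}")
            for i, (s, c) in enumerate(ordered)]


def fraction_pct(part: float, total: float) -> float:
    """Percentage 100*part/total reported to 2 decimals (0.0 for empty total)."""
    if total == 0:
        return 0.0
    return round(100.0 * part / total, 2)


@dataclass
class LibraryStats:
    """Table-style per-library summary (length histogram, category mix)."""

    library: str
    total_clean: int
    unique_clean: int
    length_hist: Dict[int, Tuple[int, int]]  # length -> (reads, tags)
    category_counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def length_pct(self, length: int) -> float:
        reads, _ = self.length_hist.get(length, (0, 0))
        return fraction_pct(reads, self.total_clean)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"length": ln, "reads": r, "tags": t,
             "reads_pct": fraction_pct(r, self.total_clean)}
            for ln, (r, t) in sorted(self.length_hist.items())
        ]
        return pd.DataFrame(rows, columns=["length", "reads", "tags", "reads_pct"])


def library_stats(tags: List[SequenceTag], library: str) -> LibraryStats:
    hist: Dict[int, List[int]] = {}
    total = 0
    for tag in tags:
        c = tag.count(library)
        if c == 0:
            continue
        bucket = hist.setdefault(len(tag.seq), [0, 0])
        bucket[0] += c
        bucket[1] += 1
        total += c
    return LibraryStats(
        library=library,
        total_clean=total,
        unique_clean=sum(t[1] for t in hist.values()),
        length_hist={k: (v[0], v[1]) for k, v in hist.items()},
    )
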