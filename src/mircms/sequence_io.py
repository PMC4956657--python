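"""Readers/writers and canonical in-memory sequence records.

Every sequence entering the pipeline is normalised to the DNA alphabet
(``U`` -> ``T`` on input); ``T`` is turned back into ``U`` only when an
RNA-facing string is emitted (e.g. secondary structures).  Coordinates are
0-based half-open internally and 1-based inclusive in every written file.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")

_U2T = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed record in an external file."""


def normalize_seq(seq: str, *, context: str = "") -> str:
    """Uppercase, map U->T, reject characters outside {A,C,G,T,U,N}."""
    out = seq.translate(_U2T).upper()
    bad = set(out) - VALID_BASES
    if bad:
        where = f" in {context}" if context else ""
        raise FormatError(f"invalid sequence character(s) {sorted(bad)}{where}")
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA representation for structure-facing output."""
    return seq.replace("T", "U").replace("t", "u")


@dataclass
class SequenceRecord:
    """A single named sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        self.seq = normalize_seq(self.seq, context=f"record {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with per-library read counts."""

    seq: str
    counts: Dict[str, int]
    id: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq, context=f"tag {self.id!r}")
        for lib, c in self.counts.items():
            if c < 0:
                raise ValueError(f"tag {self.id!r}: negative count for {lib}")
        if self.total <= 0:
            raise ValueError(f"tag {self.id!r}: no positive library count")
        if not self.id:
            self.id = f"t_{self.seq}"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """A named collection of reference sequences of one kind.

    ``kind`` controls strand handling in matching: ``genome`` and
    ``transcript`` sets are searched on both strands, the rest forward-only.
    """

    name: str
    records: List[SequenceRecord]
    kind: str  # mature | precursor | ncRNA | genome | transcript

    KINDS = ("mature", "precursor", "ncRNA", "genome", "transcript")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"reference set {self.name!r}: duplicate ids {dupes}")

    @property
    def both_strands(self) -> bool:
        return self.kind in ("genome", "transcript")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Locus:
    """Location on a reference sequence, 0-based half-open internally."""

    ref: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"locus {self.ref}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise ValueError(f"locus {self.ref}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> List[SequenceRecord]:
    """Parse a 4-line-record FASTQ file into SequenceRecords.

    U is normalised to T; N is allowed.  A record whose quality string does
    not match its sequence length raises :class:`FormatError` naming the
    offending line.
    """
    records: List[SequenceRecord] = []
    seen = set()
    with open(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                line = 4 * i + 1
                rid = title.split()[0]
                if rid in seen:
                    raise FormatError(f"{path}: duplicate read id {rid!r} at line {line}")
                seen.add(rid)
                try:
                    records.append(SequenceRecord(rid, seq, qual))
                except FormatError as exc:
                    raise FormatError(f"{path}: line {line}: {exc}") from exc
        except ValueError as exc:  # Biopython's own malformed-record errors
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: line {4 * len(records) + 1}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_fasta(path) -> List[SequenceRecord]:
    records = []
    seen = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0]
            if rid in seen:
                raise FormatError(f"{path}: duplicate id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, *, rna: bool = False,
                width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            seq = to_rna(rec.seq) if rna else rec.seq
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Collapsed-tag FASTA
# ---------------------------------------------------------------------------

def _parse_collapsed_header(title: str, path) -> tuple:
    """Accept '<name>-<count>' and '<name> count=<n>' dialects."""
    count_s = None
    if " " in title or "\t" in title:
        name, rest = title.split(None, 1)
        for tok in rest.split():
            if tok.startswith("count="):
                count_s = tok[len("count="):]
        if count_s is None:
            raise FormatError(f"{path}: header {title!r}: no count field")
    else:
        import re
        m = re.match(r"^(.+?)-(-?\d+)$", title)
        if not m:
            raise FormatError(f"{path}: header {title!r}: expected '<name>-<count>'")
        name, count_s = m.group(1), m.group(2)
    try:
        count = int(count_s)
    except ValueError:
        raise FormatError(f"{path}: header {title!r}: non-integer count {count_s!r}")
    if count <= 0:
        raise FormatError(f"{path}: header {title!r}: count must be positive")
    return name, count


def read_collapsed_fasta(path, library: str) -> List[SequenceTag]:
    """Read collapsed tags, booking all counts into ``library``."""
    tags = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name, count = _parse_collapsed_header(title.strip(), path)
            tags.append(SequenceTag(seq=seq, counts={library: count}, id=name))
    return tags


def write_collapsed_fasta(tags: Iterable[SequenceTag], path, library: str) -> None:
    """Write tags with positive counts in ``library`` as '<name>-<count>'."""
    with open(path, "w", newline="\n") as fh:
        for tag in tags:
            c = tag.count(library)
            if c > 0:
                fh.write(f">{tag.id}-{c}\n{tag.seq}\n")


# ---------------------------------------------------------------------------
# GFF-like locus table
# ---------------------------------------------------------------------------

GFF_COLUMNS = ("seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes")


def write_gff_like_loci(candidates, path, *, source: str = "mircms") -> None:
    """Write hairpin candidates as GFF3-style rows (1-based inclusive).

    ``candidates`` carry ``.locus`` (a :class:`Locus`) and ``.name``; the
    mature/star sub-loci are emitted in the attribute column.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write("#" + "\t".join(GFF_COLUMNS) + "\n")
        for cand in candidates:
            loc = cand.locus
            if loc.end < loc.start:
                raise ValueError(f"{cand.name}: end < start")
            score = getattr(cand, "mfe", None)
            attrs = f"ID={cand.name}"
            mature = getattr(cand, "mature", None)
            if mature is not None:
                attrs += f";mature_seq={mature.seq}"
            fh.write("\t".join([
                loc.ref, source, "miRNA_primary_transcript",
                str(loc.start + 1), str(loc.end),
                f"{score:.2f}" if score is not None else ".",
                loc.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Tag merging across libraries
# ---------------------------------------------------------------------------

def merge_tags(*tag_lists: List[SequenceTag]) -> List[SequenceTag]:
    """Merge per-library tag lists into one list keyed by sequence.

    Counts are summed per library; the merged list is ordered by descending
    total count, then sequence, and re-identified ``t1..tN``.
    """
    by_seq: Dict[str, Dict[str, int]] = {}
    for tags in tag_lists:
        for tag in tags:
            acc = by_seq.setdefault(tag.seq, {})
            for lib, c in tag.counts.items():
                acc[lib] = acc.get(lib, 0) + c
    ordered = sorted(by_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [SequenceTag(seq=s, counts=c, id=f"t{i+1}")
            for i, (s, c) in enumerate(ordered)]
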