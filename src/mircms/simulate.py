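"""Synthetic two-condition small-RNA study generator.

Emulates the structure of a CMS ("WA") vs fertile-maintainer ("WB")
small-RNA sequencing experiment: a random genome with planted canonical
hairpin loci, a known-mature reference, structural-ncRNA decoys, and two
read libraries of 18-30 nt tags where each miRNA carries a known log2 fold
change between conditions.  Every read traces back to a truth record, so
recovery at each pipeline stage is measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .sequence_io import (Locus, ReferenceSet, SequenceRecord, SequenceTag,
                          reverse_complement, write_fasta, write_fastq)

BASES = np.array(list("ACGT"))
NCRNA_SUBTYPES = ("rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_len: int = 100_000
    n_known: int = 30
    n_novel: int = 20
    n_ncrna: int = 10
    depth: int = 200_000
    fc_table: Optional[Dict[str, float]] = None   # mirna -> true log2 FC
    star_fraction: float = 0.05
    noise: float = 0.001
    # package defaults beyond the core knobs
    ncrna_fraction: float = 0.20
    mean_count_range: Tuple[float, float] = (50.0, 2000.0)
    loop_len_range: Tuple[int, int] = (8, 15)
    arm_mismatch_max: int = 2
    n_transcripts: int = 25
    transcript_len: int = 300
    target_site_fraction: float = 0.5
    libraries: Tuple[str, str] = ("WA", "WB")

    def __post_init__(self) -> None:
        for name in ("genome_len", "n_known", "n_novel", "n_ncrna", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.star_fraction < 1):
            raise ValueError("star_fraction must be in [0,1)")


@dataclass
class MirnaTruth:
    name: str
    kind: str                      # "known" | "novel"
    mature: str                    # DNA, precursor strand
    star: Optional[str]
    locus: Optional[Locus]         # genomic mature locus (novel only)
    fc: float                      # log2(WA/WB); +-inf = library-specific
    mean: float                    # WA Poisson mean
    planted_mismatches: int = 0
    counts: Dict[str, int] = field(default_factory=dict)
    star_counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class TruthTable:
    mirnas: List[MirnaTruth]
    genome: ReferenceSet
    mature_ref: ReferenceSet
    ncrna_ref: ReferenceSet
    category_reads: Dict[str, Dict[str, int]] = field(default_factory=dict)
    target_sites: List[Tuple[str, str, int]] = field(default_factory=list)

    def by_name(self, name: str) -> MirnaTruth:
        return next(m for m in self.mirnas if m.name == name)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, k: int,
            lo: int, hi: int) -> str:
    """Substitute k positions drawn from [lo, hi)."""
    if k == 0:
        return seq
    pos = rng.choice(np.arange(lo, hi), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _default_fc(rng: np.random.Generator, names: List[str]) -> Dict[str, float]:
    """60% unchanged; the rest split across log2 FCs in {+-1,+-2,+-3}."""
    table = {}
    choices = [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]
    for name in names:
        if rng.random() < 0.6:
            table[name] = 0.0
        else:
            table[name] = float(rng.choice(choices))
    return table


def make_genome(cfg: SimulationConfig,
                rng: Optional[np.random.Generator] = None) -> TruthTable:
    """Random genome with planted canonical hairpins + reference sets."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    mirnas: List[MirnaTruth] = []
    # known matures: reference sequences only (identified against the
    # mature set, no genomic locus needed)
    mature_records = []
    for i in range(cfg.n_known):
        L = int(rng.choice([20, 21, 21, 21, 22, 23, 24]))
        seq = _random_seq(rng, L)
        name = f"kno-miR{i + 1:03d}"
        mature_records.append(SequenceRecord(name, seq))
        mirnas.append(MirnaTruth(name, "known", seq, None, None, 0.0, 0.0))

    # novel hairpins planted into the genome
    genome = list(_random_seq(rng, cfg.genome_len))
    taken: List[Tuple[int, int]] = []
    novel: List[Tuple[str, str, str, int, int, str, int]] = []
    for i in range(cfg.n_novel):
        L = int(rng.choice([20, 21, 21, 21, 22, 23, 24]))
        mature = _random_seq(rng, L)
        loop = _random_seq(rng, int(rng.integers(*cfg.loop_len_range)))
        n_mm = int(rng.integers(0, cfg.arm_mismatch_max + 1))
        star_arm = _mutate(rng, reverse_complement(mature), n_mm, 2, L - 2)
        # 2-nt tail so the canonical star (duplex partner + 2-nt 3' overhang)
        # lies entirely inside the cassette
        cassette = mature + loop + star_arm + _random_seq(rng, 2)
        strand = "+" if rng.random() < 0.5 else "-"
        # spacing > the excision span so windows of adjacent loci never merge
        gap = 250
        placed = False
        for _ in range(200):
            pos = int(rng.integers(0, cfg.genome_len - len(cassette)))
            if all(pos + len(cassette) + gap < s or pos > e + gap
                   for s, e in taken):
                placed = True
                break
        if not placed:
            raise ValueError("cannot place hairpins without overlap; "
                             "increase genome_len or reduce n_novel")
        taken.append((pos, pos + len(cassette)))
        insert = cassette if strand == "+" else reverse_complement(cassette)
        genome[pos:pos + len(cassette)] = list(insert)
        name = f"miRn{i + 1}"
        # mature genomic locus in forward coordinates
        if strand == "+":
            locus = Locus("chrSim", pos, pos + L, "+")
        else:
            locus = Locus("chrSim", pos + len(cassette) - L, pos + len(cassette), "-")
        # canonical star: star-arm slice shifted by the 2-nt 3' overhang
        star_seq = cassette[L + len(loop) + 2: 2 * L + len(loop) + 2]
        mirnas.append(MirnaTruth(name, "novel", mature, star_seq, locus, 0.0,
                                 0.0, planted_mismatches=n_mm))

    genome_rec = SequenceRecord("chrSim", "".join(genome))
    genome_ref = ReferenceSet("genome", [genome_rec], "genome")
    mature_ref = ReferenceSet("mature_known", mature_records, "mature")

    ncrna_records = []
    for i in range(cfg.n_ncrna):
        sub = NCRNA_SUBTYPES[i % len(NCRNA_SUBTYPES)]
        length = int(rng.integers(100, 200))
        ncrna_records.append(SequenceRecord(f"{sub}_{i + 1}", _random_seq(rng, length)))
    ncrna_ref = ReferenceSet("ncRNA_decoys", ncrna_records, "ncRNA")

    # per-miRNA expression model
    names = [m.name for m in mirnas]
    fc = dict(cfg.fc_table) if cfg.fc_table else _default_fc(rng, names)
    lo, hi = cfg.mean_count_range
    for m in mirnas:
        m.fc = float(fc.get(m.name, 0.0))
        m.mean = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return TruthTable(mirnas=mirnas, genome=genome_ref, mature_ref=mature_ref,
                      ncrna_ref=ncrna_ref)


def _apply_noise(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq
    return _mutate(rng, seq, min(n_mut, len(seq)), 0, len(seq))


def simulate_libraries(cfg: SimulationConfig, truth: TruthTable,
                       rng: Optional[np.random.Generator] = None
                       ) -> Dict[str, List[SequenceRecord]]:
    """Two read libraries; fills truth.counts/star_counts/category_reads.

    Library WA counts ~ Poisson(mean), WB ~ Poisson(mean * 2^-fc); stars are
    sampled at star_fraction of the mature rate, ncRNA and genomic background
    reads fill each library to ``depth``, and substitution noise is applied
    at the configured per-base rate.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    la, lb = cfg.libraries
    libs: Dict[str, List[SequenceRecord]] = {la: [], lb: []}
    truth.category_reads = {la: {"miRNA": 0, "ncRNA": 0, "background": 0},
                            lb: {"miRNA": 0, "ncRNA": 0, "background": 0}}
    if cfg.depth == 0:
        for m in truth.mirnas:
            m.counts = {la: 0, lb: 0}
            m.star_counts = {la: 0, lb: 0}
        return libs

    def emit(lib: str, seq: str, origin: str, category: str) -> None:
        noisy = _apply_noise(rng, seq, cfg.noise)
        rid = f"{lib}_r{len(libs[lib]) + 1}_{origin}"
        libs[lib].append(SequenceRecord(rid, noisy, "I" * len(noisy)))
        truth.category_reads[lib][category] += 1

    for m in truth.mirnas:
        lam = {la: m.mean}
        if np.isinf(m.fc):
            lam[lb] = 0.0 if m.fc > 0 else m.mean
            if m.fc < 0:
                lam[la] = 0.0
        else:
            lam[lb] = m.mean * 2.0 ** (-m.fc)
        for lib in (la, lb):
            c = int(rng.poisson(lam[lib])) if lam[lib] > 0 else 0
            m.counts[lib] = c
            for _ in range(c):
                emit(lib, m.mature, m.name, "miRNA")
            sc = int(rng.poisson(cfg.star_fraction * lam[lib])) if m.star else 0
            m.star_counts[lib] = sc
            for _ in range(sc):
                emit(lib, m.star, f"{m.name}star", "miRNA")

    genome_seq = truth.genome.records[0].seq
    for lib in (la, lb):
        used = len(libs[lib])
        n_nc = max(0, min(int(round(cfg.ncrna_fraction * cfg.depth)),
                          cfg.depth - used))
        for _ in range(n_nc):
            rec = truth.ncrna_ref.records[int(rng.integers(0, len(truth.ncrna_ref)))]
            L = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(rec.seq) - L))
            emit(lib, rec.seq[start:start + L], rec.id, "ncRNA")
        n_bg = max(0, cfg.depth - used - n_nc)
        for _ in range(n_bg):
            L = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(genome_seq) - L))
            frag = genome_seq[start:start + L]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            emit(lib, frag, "bg", "background")
    return libs


def make_transcripts(cfg: SimulationConfig, truth: TruthTable,
                     rng: Optional[np.random.Generator] = None) -> ReferenceSet:
    """Random transcripts with perfect-complement sites planted for a
    deterministic subset of miRNAs (recorded in truth.target_sites)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    records = [SequenceRecord(f"TXN{i + 1:04d}", _random_seq(rng, cfg.transcript_len))
               for i in range(cfg.n_transcripts)]
    truth.target_sites = []
    if not records:
        return ReferenceSet("transcripts", records, "transcript")
    used: Dict[int, list] = {i: [] for i in range(len(records))}
    for m in truth.mirnas:
        if rng.random() >= cfg.target_site_fraction:
            continue
        site = reverse_complement(m.mature)
        for _ in range(50):  # find a non-overlapping planting spot
            idx = int(rng.integers(0, len(records)))
            rec = records[idx]
            start = int(rng.integers(0, len(rec.seq) - len(site)))
            if all(start + len(site) <= s or start >= e
                   for s, e in used[idx]):
                used[idx].append((start, start + len(site)))
                new_seq = rec.seq[:start] + site + rec.seq[start + len(site):]
                records[idx] = SequenceRecord(rec.id, new_seq)
                truth.target_sites.append((m.name, rec.id, start + 1))
                break
    return ReferenceSet("transcripts", records, "transcript")


def truth_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for m in truth.mirnas:
        rows.append({
            "name": m.name, "kind": m.kind, "mature": m.mature,
            "star": m.star or "", "fc": m.fc, "mean": round(m.mean, 2),
            "locus": (f"{m.locus.ref}:{m.locus.start + 1}-{m.locus.end}"
                      f"({m.locus.strand})" if m.locus else ""),
            **{f"count_{lib}": m.counts.get(lib, 0) for lib in ("WA", "WB")},
            **{f"star_count_{lib}": m.star_counts.get(lib, 0) for lib in ("WA", "WB")},
        })
    return pd.DataFrame(rows)


def write_simulation(outdir, cfg: SimulationConfig) -> TruthTable:
    """Generate and write the full synthetic study to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = make_genome(cfg, rng)
    libs = simulate_libraries(cfg, truth, rng)
    transcripts = make_transcripts(cfg, truth, rng)
    write_fasta(truth.genome.records, outdir / "genome.fa")
    write_fasta(truth.mature_ref.records, outdir / "mature_known.fa")
    write_fasta(truth.ncrna_ref.records, outdir / "ncrna.fa")
    write_fasta(transcripts.records, outdir / "transcripts.fa")
    for lib, reads in libs.items():
        write_fastq(reads, outdir / f"reads_{lib}.fastq")
    truth_frame(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth
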