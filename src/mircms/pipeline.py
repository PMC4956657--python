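"""Stage orchestration: preprocess -> annotate -> {discover, diffexpr} ->
targets -> network, with study-style report tables and a JSON run log.

All thresholds live in the config; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .annotation import (AnnotationConfig, AnnotationRecord, annotate_tags,
                         category_table, family_frame, family_table,
                         load_family_alias)
from .differential import DEConfig, call_de, de_frame
from .novel import NovelCriteria, candidate_frame, discover
from .preprocess import PreprocessConfig, clean_reads, collapse, library_stats
from .sequence_io import (ReferenceSet, SequenceRecord, SequenceTag,
                          merge_tags, read_fasta, read_fastq,
                          write_gff_like_loci)
from .simulate import SimulationConfig
from .targets import (TargetScoringConfig, build_network, hits_frame,
                      scan_transcripts, write_edge_tsv, write_sif)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    reads: Dict[str, str] = field(default_factory=dict)   # library -> fastq
    genome: Optional[str] = None
    mature_ref: Optional[str] = None
    ncrna_ref: Optional[str] = None
    transcripts: Optional[str] = None
    family_alias: Optional[str] = None
    outdir: str = "mircms_out"
    seed: int = 0
    libraries: Tuple[str, str] = ("WA", "WB")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    novel: NovelCriteria = field(default_factory=NovelCriteria)
    de: DEConfig = field(default_factory=DEConfig)
    targets: TargetScoringConfig = field(default_factory=TargetScoringConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (("preprocess", PreprocessConfig),
                         ("annotation", AnnotationConfig),
                         ("novel", NovelCriteria),
                         ("de", DEConfig),
                         ("targets", TargetScoringConfig),
                         ("simulation", SimulationConfig)):
            if key in raw:
                val = raw.pop(key)
                for k, v in list(val.items()):
                    if isinstance(v, list):
                        val[k] = tuple(v)
                kwargs[key] = sub(**val)
        if "libraries" in raw:
            raw["libraries"] = tuple(raw["libraries"])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate_inputs(self) -> None:
        missing = []
        for lib, p in self.reads.items():
            if not Path(p).exists():
                missing.append(f"reads[{lib}]={p}")
        for name in ("genome", "mature_ref", "ncrna_ref", "transcripts"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                missing.append(f"{name}={p}")
        if missing:
            raise PipelineError("configure", f"missing input file(s): {missing}")


@dataclass
class PipelineResult:
    annotation_records: List[AnnotationRecord]
    candidates: list
    de_results: list
    target_hits: list
    edges: list
    tables: Dict[str, pd.DataFrame]
    log: dict


def _stage(log: dict, name: str, t0: float, **info) -> None:
    log["stages"].append({"stage": name,
                          "seconds": round(time.perf_counter() - t0, 3), **info})


def run_stages(reads_by_lib: Dict[str, List[SequenceRecord]],
               genome: Optional[ReferenceSet],
               mature_ref: ReferenceSet,
               ncrna_ref: ReferenceSet,
               cfg: PipelineConfig,
               transcripts: Optional[ReferenceSet] = None,
               outdir=None) -> PipelineResult:
    """Run every stage on in-memory inputs; write reports when ``outdir`` set."""
    la, lb = cfg.libraries
    log: dict = {"version": __version__, "python": platform.python_version(),
                 "seed": cfg.seed, "stages": []}
    tables: Dict[str, pd.DataFrame] = {}

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    per_lib_tags = {}
    filter_logs = {}
    for lib in (la, lb):
        result = clean_reads(reads_by_lib.get(lib, []), cfg.preprocess)
        if not result.conserved:  # pragma: no cover - accounting guard
            raise PipelineError("preprocess", "read accounting violated")
        per_lib_tags[lib] = collapse(result.kept, lib)
        filter_logs[lib] = {"input": result.n_input, "kept": len(result.kept),
                            "removed": result.removed}
    tags = merge_tags(*(per_lib_tags[lib] for lib in (la, lb)))
    denoms = {lib: sum(t.count(lib) for t in tags) for lib in (la, lb)}
    stats = {lib: library_stats(tags, lib) for lib in (la, lb)}
    tables["length_hist"] = pd.concat(
        [stats[lib].to_frame().assign(library=lib) for lib in (la, lb)],
        ignore_index=True)
    _stage(log, "preprocess", t0, filters=filter_logs, denominators=denoms)

    # --- annotate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        records = annotate_tags(tags, [ncrna_ref, mature_ref], cfg.annotation)
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc
    tables["category_table"] = category_table(records, (la, lb))
    alias = (load_family_alias(cfg.family_alias) if cfg.family_alias
             else load_family_alias())
    families = family_table(records, alias, (la, lb))
    tables["family_table"] = family_frame(families, (la, lb))
    _stage(log, "annotate", t0,
           n_tags=len(records),
           n_mirna_tags=sum(r.category == "miRNA" for r in records))

    # --- novel discovery --------------------------------------------------
    t0 = time.perf_counter()
    candidates = []
    if genome is not None:
        unannotated = [r.tag for r in records if r.category == "unannotated"]
        candidates = discover(unannotated, genome, cfg.novel)
    tables["novel_candidates"] = candidate_frame(candidates, (la, lb))
    _stage(log, "discover", t0, n_candidates=len(candidates))

    # --- differential expression -----------------------------------------
    t0 = time.perf_counter()
    known_counts: Dict[str, Dict[str, int]] = {}
    for rec in records:
        if rec.category != "miRNA":
            continue
        acc = known_counts.setdefault(rec.hit_id, {la: 0, lb: 0})
        for lib in (la, lb):
            acc[lib] += rec.tag.count(lib)
    count_rows = [(mid, c[la], c[lb]) for mid, c in sorted(known_counts.items())]
    count_rows += [(c.name, c.mature.count(la), c.mature.count(lb))
                   for c in candidates]
    de_results = call_de(count_rows, (denoms[la], denoms[lb]), cfg.de, (la, lb))
    tables["de_table"] = de_frame(de_results, (la, lb))
    _stage(log, "diffexpr", t0,
           n_de=sum(r.call != "ns" for r in de_results))

    # --- targets + network ------------------------------------------------
    t0 = time.perf_counter()
    hits = []
    if transcripts is not None:
        mature_seqs = {r.id: r.seq for r in mature_ref.records}
        mirna_records = ([SequenceRecord(mid, mature_seqs[mid])
                          for mid, _, _ in count_rows if mid in mature_seqs]
                         + [SequenceRecord(c.name, c.mature.seq)
                            for c in candidates])
        for rec in mirna_records:
            hits.extend(scan_transcripts(rec, transcripts, cfg.targets))
    tables["target_hits"] = hits_frame(hits)
    edges, graph, skipped = build_network(de_results, hits)
    tables["network_edges"] = pd.DataFrame(
        [{"mirna": e.mirna, "target": e.target_gene, "mirna_call": e.direction,
          "correlation": e.correlation} for e in edges])
    _stage(log, "targets_network", t0, n_hits=len(hits), n_edges=len(edges),
           skipped_dangling=skipped)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("length_hist", "category_table", "family_table",
                     "novel_candidates", "de_table", "target_hits"):
            tables[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        write_sif(edges, outdir / "network.sif")
        write_edge_tsv(edges, outdir / "network_edges.tsv")
        write_gff_like_loci(candidates, outdir / "novel_loci.gff")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)

    return PipelineResult(records, candidates, de_results, hits, edges,
                          tables, log)


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """File-based entry point: read configured inputs and run every stage."""
    cfg.validate_inputs()
    if not cfg.reads:
        raise PipelineError("configure", "no read libraries configured")
    reads = {lib: read_fastq(path) for lib, path in cfg.reads.items()}
    genome = (ReferenceSet("genome", read_fasta(cfg.genome), "genome")
              if cfg.genome else None)
    if cfg.mature_ref is None or cfg.ncrna_ref is None:
        raise PipelineError("configure", "mature_ref and ncrna_ref are required")
    mature = ReferenceSet("mature", read_fasta(cfg.mature_ref), "mature")
    ncrna = ReferenceSet("ncRNA", read_fasta(cfg.ncrna_ref), "ncRNA")
    transcripts = (ReferenceSet("transcripts", read_fasta(cfg.transcripts),
                                "transcript") if cfg.transcripts else None)
    return run_stages(reads, genome, mature, ncrna, cfg, transcripts,
                      outdir=cfg.outdir)
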