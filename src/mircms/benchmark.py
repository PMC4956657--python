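"""Worked examples and end-to-end recovery benchmarks.

Two kinds of self-checks live here:

* worked examples recomputing summary arithmetic from the published
  two-library radish floral-bud small-RNAome study (family ratios, category
  percentages, the fold-change of the WA-specific novel miRNA rsa-miRn3) —
  the printed counts are the inputs, every reported value is computed by the
  package at run time;
* recovery metrics of the full pipeline on the default synthetic study,
  where the generator's truth table says exactly what should be found.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .annotation import AnnotationRecord, family_table, load_family_alias
from .differential import count_test_p, log2_fold_change, normalize
from .pipeline import PipelineConfig, PipelineResult, run_stages
from .preprocess import fraction_pct
from .sequence_io import SequenceTag
from .simulate import (SimulationConfig, TruthTable, make_genome,
                       make_transcripts, simulate_libraries)

# Printed summary numbers of the radish WA (sterile) / WB (fertile) study,
# used as *inputs* to the worked examples below.
WA_TOTAL_CLEAN = 20_287_225
WB_TOTAL_CLEAN = 21_989_236
WA_UNIQUE_CLEAN = 5_528_061
WA_MIRNA_TOTAL_READS = 1_453_994
WA_UNANNOTATED_UNIQUE = 5_388_388
FAMILY_READS = {            # family -> (WA reads, WB reads)
    "miR156/157": (410_237, 304_695),
    "miR158": (15_565, 7_641),
    "miR395": (45_236, 44),
    "miR161": (152, 0),
}
MIRN3_COUNTS = (443, 0)     # WA-specific novel miRNA
MIRN3_MATURE = "TATTCCGACGACAATTCCGACG"


def _family_records() -> list:
    """AnnotationRecords carrying the printed family read counts."""
    recs = []
    base = "ACGTACGTACGTACGTACGTA"
    for i, (fam, (wa, wb)) in enumerate(sorted(FAMILY_READS.items())):
        member = fam.split("/")[0] + "a"
        seq = base[:-1] + "ACGT"[i % 4]
        tag = SequenceTag(seq, {"WA": wa, "WB": wb}, id=f"wtag{i}")
        recs.append(AnnotationRecord(tag, "miRNA", member, 0))
    return recs


def worked_examples() -> Dict[str, Dict[str, float]]:
    """Recompute the in-study worked-example quantities from printed inputs."""
    fams = {f.family: f for f in family_table(_family_records(),
                                              load_family_alias())}
    rpm_wa = normalize(MIRN3_COUNTS[0], WA_TOTAL_CLEAN)
    rpm_wb = normalize(MIRN3_COUNTS[1], WB_TOTAL_CLEAN)
    return {
        "t1": {"value": fams["miR156/157"].ratio, "n": 2},
        "t2": {"value": fams["miR395"].ratio, "n": 2},
        "t3": {"value": fams["miR158"].total, "n": 2},
        "t4": {"value": fraction_pct(WA_MIRNA_TOTAL_READS, WA_TOTAL_CLEAN),
               "n": WA_TOTAL_CLEAN},
        "t5": {"value": round(log2_fold_change(rpm_wa, rpm_wb), 2),
               "n": WA_TOTAL_CLEAN + WB_TOTAL_CLEAN},
        "t6": {"value": fraction_pct(WA_UNANNOTATED_UNIQUE, WA_UNIQUE_CLEAN),
               "n": WA_UNIQUE_CLEAN},
        "t7": {"value": len(MIRN3_MATURE), "n": 1},
    }


def run_synthetic_study(seed: int, sim_cfg: Optional[SimulationConfig] = None,
                        outdir=None):
    """Generate the default synthetic study and run every stage on it."""
    cfg = sim_cfg if sim_cfg is not None else SimulationConfig(seed=seed)
    rng = np.random.default_rng(cfg.seed)
    truth = make_genome(cfg, rng)
    libs = simulate_libraries(cfg, truth, rng)
    transcripts = make_transcripts(cfg, truth, rng)
    pipe_cfg = PipelineConfig(seed=cfg.seed, libraries=cfg.libraries)
    result = run_stages(libs, truth.genome, truth.mature_ref, truth.ncrna_ref,
                        pipe_cfg, transcripts, outdir=outdir)
    return truth, result


def recovery_metrics(truth: TruthTable, result: PipelineResult,
                     fc_cut: float = 2.0) -> Dict[str, float]:
    """Planted-truth recovery of the pipeline run, in percent."""
    known = [m for m in truth.mirnas if m.kind == "known"]
    annotated_ids = {r.hit_id for r in result.annotation_records
                     if r.category == "miRNA"}
    known_rec = sum(m.name in annotated_ids for m in known)

    novel = [m for m in truth.mirnas if m.kind == "novel"]
    cand_by_seq = {c.mature.seq: c for c in result.candidates}
    novel_rec = sum(m.mature in cand_by_seq for m in novel)

    mature_to_known = {m.mature: m for m in known}
    calls: Dict[str, str] = {}
    for r in result.de_results:
        calls[r.mirna] = r.call
    strong = [m for m in truth.mirnas
              if np.isfinite(m.fc) and abs(m.fc) >= fc_cut]
    correct = 0
    for m in strong:
        if m.kind == "known":
            call = calls.get(m.name)
        else:
            cand = cand_by_seq.get(m.mature)
            call = calls.get(cand.name) if cand else None
        if call == ("up" if m.fc > 0 else "down"):
            correct += 1
    return {
        "known_mirna_recovery_pct": round(100.0 * known_rec / len(known), 2)
        if known else 100.0,
        "novel_hairpin_recovery_pct": round(100.0 * novel_rec / len(novel), 2)
        if novel else 100.0,
        "de_call_accuracy_pct": round(100.0 * correct / len(strong), 2)
        if strong else 100.0,
        "n_strong_fc": len(strong),
        "n_candidates": len(result.candidates),
    }


def type_i_error(seed: int, n_mirnas: int = 2000, alpha: float = 0.05,
                 depth: int = 1_000_000) -> float:
    """Null rejection rate: equal-RPM Poisson count pairs, one test each."""
    rng = np.random.default_rng(seed)
    lam = rng.uniform(10, 500, size=n_mirnas)
    x = rng.poisson(lam)
    y = rng.poisson(lam)
    rejected = sum(count_test_p(int(a), int(b), depth, depth) <= alpha
                   for a, b in zip(x, y))
    return rejected / n_mirnas
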