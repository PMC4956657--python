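#!/usr/bin/env python
"""Predict miRNA targets and export the miRNA-target regulatory network.

Scans the transcript set with the plant complementarity expectation score
(cutoff 3.0, doubled penalties in miRNA positions 2-13), restricts edges to
differentially expressed miRNAs, and writes the hit table plus SIF/TSV
network files.
"""

import argparse
from pathlib import Path

import pandas as pd

from mircms.differential import DifferentialResult
from mircms.sequence_io import ReferenceSet, read_fasta
from mircms.targets import (TargetScoringConfig, build_network, hits_frame,
                            scan_transcripts, write_edge_tsv, write_sif)

ROOT = Path(__file__).resolve().parents[1]


def main():
    argparse.ArgumentParser().parse_args()
    sim = ROOT / "scratch" / "synthetic"
    results = ROOT / "results"

    de_df = pd.read_csv(results / "05_de_table.tsv", sep="\t")
    transcripts = ReferenceSet("tx", read_fasta(sim / "transcripts.fa"),
                               "transcript")
    mature = {r.id: r for r in read_fasta(sim / "mature_known.fa")}
    novel = pd.read_csv(results / "04_novel_candidates.tsv", sep="\t")
    from mircms.sequence_io import SequenceRecord
    for _, row in novel.iterrows():
        if not str(row["name"]).endswith("*"):
            mature[row["name"]] = SequenceRecord(row["name"], row["mature_seq"])

    cfg = TargetScoringConfig()
    hits = []
    for mid in de_df.mirna:
        if mid in mature:
            hits.extend(scan_transcripts(mature[mid], transcripts, cfg))
    hits_frame(hits).to_csv(results / "06_target_hits.tsv", sep="\t", index=False)

    de = [DifferentialResult(mirna=r.mirna, log2_fc=r.log2_fc,
                             p_value=r.p_value, call=r.call)
          for r in de_df.itertuples()]
    edges, graph, skipped = build_network(de, hits)
    write_sif(edges, results / "06_network.sif")
    write_edge_tsv(edges, results / "06_network_edges.tsv")

    print(f"{len(hits)} target sites over {de_df.shape[0]} miRNAs "
          f"({len({h.transcript for h in hits})} transcripts)")
    print(f"network: {graph.number_of_nodes()} nodes, {len(edges)} edges "
          f"restricted to DE miRNAs ({skipped} dangling hits skipped)")
    print("wrote results/06_target_hits.tsv, 06_network.sif, 06_network_edges.tsv")


if __name__ == "__main__":
    main()
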