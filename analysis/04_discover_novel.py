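#!/usr/bin/env python
"""Predict novel miRNA hairpins from the unannotated tags.

Maps abundant unannotated tags to the reference, excises and folds candidate
precursors, applies the duplex/star criteria, and writes the novel-candidate
table (reads per library, mature sequence, arm, size, precursor length, MFE,
location) plus precursor FASTA, structures and a locus GFF.
"""

import argparse
from pathlib import Path

from mircms.novel import NovelCriteria, candidate_frame, discover
from mircms.sequence_io import (ReferenceSet, SequenceRecord, merge_tags,
                                read_collapsed_fasta, read_fasta, to_rna,
                                write_fasta, write_gff_like_loci)

ROOT = Path(__file__).resolve().parents[1]


def main():
    argparse.ArgumentParser().parse_args()
    sim = ROOT / "scratch" / "synthetic"
    results = ROOT / "results"

    tags = merge_tags(
        read_collapsed_fasta(ROOT / "scratch" / "03_unannotated_WA.fa", "WA"),
        read_collapsed_fasta(ROOT / "scratch" / "03_unannotated_WB.fa", "WB"))
    genome = ReferenceSet("genome", read_fasta(sim / "genome.fa"), "genome")

    cands = discover(tags, genome, NovelCriteria())
    candidate_frame(cands).to_csv(results / "04_novel_candidates.tsv",
                                  sep="\t", index=False)
    write_fasta([SequenceRecord(c.name, c.precursor.seq) for c in cands],
                results / "04_precursors.fa", rna=True)
    with open(results / "04_structures.txt", "w") as fh:
        for c in cands:
            fh.write(f">{c.name} mfe={c.mfe:.2f} ({c.fold.energy_model})\n"
                     f"{to_rna(c.precursor.seq)}\n{c.fold.structure}\n")
    write_gff_like_loci(cands, results / "04_novel_loci.gff")

    with open(results / "04_novel_counts.tsv", "w") as fh:
        fh.write("mirna\tcount_WA\tcount_WB\n")
        for c in cands:
            fh.write(f"{c.name}\t{c.mature.count('WA')}\t{c.mature.count('WB')}\n")

    n_star = sum(c.star_observed for c in cands)
    lps = [c.lp for c in cands]
    print(f"{len(cands)} hairpin candidates ({n_star} with an observed star)")
    if cands:
        print(f"precursor length {min(lps)}-{max(lps)} nt; "
              f"MFE {min(c.mfe for c in cands):.2f}"
              f"..{max(c.mfe for c in cands):.2f} kcal/mol")
    print("wrote results/04_novel_candidates.tsv (+ precursors, structures, gff)")


if __name__ == "__main__":
    main()
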