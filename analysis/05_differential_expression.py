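#!/usr/bin/env python
"""Call differentially expressed miRNAs between the WA and WB libraries.

Counts are normalised to reads-per-million of each library's clean total
(zero counts -> 0.01), fold change is log2(WA/WB), significance is the
two-sided Audic-Claverie count test; calls need p <= 0.05 and |log2FC| >= 1.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mircms.differential import DEConfig, call_de, de_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    argparse.ArgumentParser().parse_args()
    results = ROOT / "results"

    counts = pd.concat([
        pd.read_csv(results / "03_known_counts.tsv", sep="\t"),
        pd.read_csv(results / "04_novel_counts.tsv", sep="\t"),
    ], ignore_index=True)
    with open(results / "02_filter_log.json") as fh:
        log = json.load(fh)
    denoms = (log["WA"]["clean"], log["WB"]["clean"])

    rows = list(counts.itertuples(index=False, name=None))
    de = call_de(rows, denoms, DEConfig())
    df = de_frame(de)
    df.to_csv(results / "05_de_table.tsv", sep="\t", index=False)

    up = df[df.call == "up"]
    down = df[df.call == "down"]
    known = df[~df.mirna.str.startswith("miRn")]
    novel = df[df.mirna.str.startswith("miRn")]
    print(f"{len(df)} miRNAs tested against denominators {denoms}")
    print(f"  up-regulated  : {len(up)} ({(known.call == 'up').sum()} known, "
          f"{(novel.call == 'up').sum()} novel)")
    print(f"  down-regulated: {len(down)} ({(known.call == 'down').sum()} known, "
          f"{(novel.call == 'down').sum()} novel)")
    spec = df[df.specificity != ""]
    print(f"  library-specific: {len(spec)}")
    print("wrote results/05_de_table.tsv")


if __name__ == "__main__":
    main()
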