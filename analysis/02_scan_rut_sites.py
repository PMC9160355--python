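#!/usr/bin/env python
"""Extract terminator zones and score their rut sites.

Reads the study genome + annotations, applies the operon-position rule to
pick each gene's analyzed interval, scans 70 nt windows for C>G bubbles,
computes the 13 descriptors (78 nt windows), and scans for elemental
pause sites.  Tables land in results/tables/rut_sites/.
"""

import argparse
from pathlib import Path

import pandas as pd

from rhoterm.pipeline import PipelineConfig, run_full_analysis

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "tables" / "rut_sites")
    args = ap.parse_args()

    cfg = PipelineConfig(
        genome_fasta=str(args.study / "genome.fasta"),
        annotation_tsv=str(args.study / "annotations.tsv"),
    )
    run_full_analysis(cfg, args.outdir)

    desc = pd.read_csv(args.outdir / "descriptors.tsv", sep="\t", comment="#")
    bubbles = pd.read_csv(args.outdir / "bubbles.tsv", sep="\t", comment="#")
    pauses = pd.read_csv(args.outdir / "pause_hits.tsv", sep="\t", comment="#")
    print(f"scored {len(desc)} terminator zones -> {args.outdir}")
    print(f"  {len(bubbles)} C>G bubbles at the bare %C>%G rule; "
          f"longest-bubble lengths {desc.L1_longest_bubble_len.min()}-"
          f"{desc.L1_longest_bubble_len.max()} nt")
    print(f"  {len(pauses)} elemental pause-site hits "
          f"({', '.join(pauses.gene.unique()) if len(pauses) else 'none'})")


if __name__ == "__main__":
    main()
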