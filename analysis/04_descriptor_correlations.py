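#!/usr/bin/env python
"""Correlate fold changes with rut-site descriptors; contrast NusG classes.

Fits y = y0 + a*x for each descriptor against the Rho-mutant fold change,
both on all genes and gated to fold changes below 10 (where the
descriptor/efficiency relationship is expected to hold), and summarizes
descriptor distributions of highly NusG-dependent vs NusG-independent
terminators as box statistics with percent median reductions.
Tables land in results/tables/associations/.
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
                    default=ROOT / "results" / "tables" / "associations")
    args = ap.parse_args()

    cfg = PipelineConfig(
        genome_fasta=str(args.study / "genome.fasta"),
        annotation_tsv=str(args.study / "annotations.tsv"),
        ct_tsv=str(args.study / "ct.tsv"),
    )
    run_full_analysis(cfg, args.outdir)

    reg = pd.read_csv(args.outdir / "regressions.tsv", sep="\t", comment="#")
    box = pd.read_csv(args.outdir / "box_summaries.tsv", sep="\t", comment="#")
    print(f"fitted {len(reg)} gated regressions -> {args.outdir}")
    best = reg.sort_values("r2", ascending=False).head(3)
    for _, r in best.iterrows():
        print(f"  {r.descriptor} [{r.gate}]: r2={r.r2:.2f} (n={r.n}, p={r.p:.3g})")
    red = box.dropna(subset=["median_reduction_pct"])
    for _, r in red.iterrows():
        print(f"  {r.descriptor}: median reduction "
              f"{float(r.median_reduction_pct):.0f}% in NusG-dependent group")


if __name__ == "__main__":
    main()
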