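#!/usr/bin/env python
"""Quantify in vivo termination efficiencies and classify terminators.

Turns the study's Ct tables into 2^-ddCt fold changes per gene x strain,
classifies terminator strength from the Rho N340S fold change, and
NusG dependency from the NusG-mutant/Rho-mutant fold-change ratio.
Tables land in results/tables/qpcr/.
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
                    default=ROOT / "results" / "tables" / "qpcr")
    args = ap.parse_args()

    cfg = PipelineConfig(ct_tsv=str(args.study / "ct.tsv"))
    run_full_analysis(cfg, args.outdir)

    cls = pd.read_csv(args.outdir / "classifications.tsv", sep="\t", comment="#")
    print(f"classified {len(cls)} terminators -> {args.outdir}")
    for label, n in cls.strength_class.value_counts().items():
        print(f"  strength {label}: {n}")
    for label, n in cls.nusg_class.value_counts().items():
        print(f"  NusG {label}: {n}")


if __name__ == "__main__":
    main()
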