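#!/usr/bin/env python
"""Generate the synthetic miniature study all downstream steps analyze.

Writes a 12-gene, 5-strain study (genome + annotations, Ct tables for the
Rho N340S and three NusG mutants against WT, decay time courses and
binding titrations) with its planted ground truth to results/study/.
"""

import argparse
import json
from pathlib import Path

from rhoterm.pipeline import make_fixture_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()

    outdir = make_fixture_study(args.outdir, seed=args.seed)
    truth = json.loads((outdir / "truth.json").read_text())
    genes = truth["genes"]
    print(f"wrote study to {outdir}")
    print(f"  {len(genes)} genes; planted Rho-mutant fold changes "
          f"{min(g['rho_fc'] for g in genes.values())}-"
          f"{max(g['rho_fc'] for g in genes.values())}")
    print(f"  {len(truth['decay'])} decay series, "
          f"{len(truth['binding'])} binding titrations")


if __name__ == "__main__":
    main()
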