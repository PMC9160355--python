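"""ΔΔCt fold-change quantification and terminator classification.

In a strain whose Rho (or NusG) is termination-defective, transcription
reads through Rho-dependent terminators into downstream probes, so the
fold change in a gene's mRNA relative to the wild-type strain —
``2**(-ΔΔCt)`` with rpoC as the internal reference — is a semiquantitative
measure of the terminator's in vivo strength.  Strength classes:

* weak or nonterminator: fold change < 2
* moderate:              2 <= fc < 10
* strong:               10 <= fc < 30
* very strong:           fc >= 30

NusG dependency is the ratio of the average fold change across the three
Rho-binding-defective NusG mutants to the fold change in the Rho N340S
mutant: > 0.5 highly dependent, 0.2–0.5 moderately dependent, < 0.2
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, PairingError, ValidationError

#: Internal reference transcript held invariant across strains.
REFERENCE_GENE = "rpoC"

WT_STRAIN = "WT"
RHO_MUTANT = "rho_N340S"
NUSG_MUTANTS = ("nusG_G146D", "nusG_V160N", "nusG_L158Q")

STRENGTH_THRESHOLDS = (2.0, 10.0, 30.0)
NUSG_THRESHOLDS = (0.2, 0.5)


class StrengthClass(str, Enum):
    WEAK_OR_NON = "weak_or_non"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


class NusGLabel(str, Enum):
    HIGHLY_DEPENDENT = "highly_dependent"
    MODERATELY_DEPENDENT = "moderately_dependent"
    INDEPENDENT = "independent"


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference Ct for a replicate."""

    gene: str
    strain: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{self.gene}/{self.strain} rep {self.replicate}: "
                    f"{name} must be finite and > 0, got {v}"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class FoldChange:
    gene: str
    strain: str
    mean_fc: float
    sd_fc: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.mean_fc <= 0:
            raise ValidationError(f"{self.gene}/{self.strain}: mean_fc must be > 0")
        if self.n_replicates < 1:
            raise ValidationError(f"{self.gene}/{self.strain}: need >= 1 replicate")


@dataclass(frozen=True)
class NusGClass:
    gene: str
    ratio: float
    label: NusGLabel


def fold_change_from_ct(
    records: Iterable[CtRecord],
    gene: str,
    strain: str,
    aggregation: str = "arithmetic",
) -> FoldChange:
    """Fold change of ``gene`` in ``strain`` relative to the WT baseline.

    Each mutant replicate's ΔCt (target − reference) is compared against the
    mean WT ΔCt; per-replicate fold change is ``2**(-ΔΔCt)``.  Replicates are
    aggregated by arithmetic mean with sd (the default) or geometric mean
    (``aggregation='geometric'``; sd then reported on log2 scale folds).
    """
    recs = list(records)
    wt = [r.delta_ct for r in recs if r.gene == gene and r.strain == WT_STRAIN]
    mut = [r.delta_ct for r in recs if r.gene == gene and r.strain == strain]
    if not wt:
        raise PairingError(f"gene {gene!r}: no WT baseline replicates")
    if not mut:
        raise PairingError(f"gene {gene!r}: no replicates for strain {strain!r}")
    wt_mean = float(np.mean(wt))
    fcs = np.array([2.0 ** -(d - wt_mean) for d in mut])
    if aggregation == "arithmetic":
        mean_fc = float(fcs.mean())
        sd_fc = float(fcs.std(ddof=1)) if len(fcs) > 1 else 0.0
    elif aggregation == "geometric":
        logs = np.log2(fcs)
        mean_fc = float(2.0 ** logs.mean())
        sd_fc = float(2.0 ** logs.std(ddof=1) - 1.0) * mean_fc if len(fcs) > 1 else 0.0
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return FoldChange(gene, strain, mean_fc, sd_fc, len(fcs))


def classify_strength(fc: FoldChange | float) -> StrengthClass:
    """Classify a terminator by its fold change in the Rho mutant.

    Intervals are half-open on the right: [2, 10) moderate, [10, 30)
    strong, >= 30 very strong.
    """
    value = fc.mean_fc if isinstance(fc, FoldChange) else float(fc)
    if value <= 0:
        raise ValidationError(f"fold change must be > 0, got {value}")
    weak_hi, strong_lo, very_lo = STRENGTH_THRESHOLDS
    if value < weak_hi:
        return StrengthClass.WEAK_OR_NON
    if value < strong_lo:
        return StrengthClass.MODERATE
    if value < very_lo:
        return StrengthClass.STRONG
    return StrengthClass.VERY_STRONG


def classify_nusg_dependency(
    nusg_fcs: Sequence[FoldChange | float],
    rho_fc: FoldChange | float,
    min_mutants: int = 3,
) -> NusGClass:
    """Classify NusG dependency from the NusG-mutant / Rho-mutant FC ratio.

    The ratio averages the NusG-mutant fold changes and divides by the Rho
    N340S fold change; [0.2, 0.5] is closed for the moderate class.
    ``min_mutants`` relaxes the three-mutant requirement when fewer strains
    were assayed.
    """
    values = [f.mean_fc if isinstance(f, FoldChange) else float(f) for f in nusg_fcs]
    if len(values) < min_mutants:
        raise InsufficientDataError(
            f"need >= {min_mutants} NusG-mutant fold changes, got {len(values)}"
        )
    rho = rho_fc.mean_fc if isinstance(rho_fc, FoldChange) else float(rho_fc)
    if rho <= 0:
        raise ValidationError(f"Rho-mutant fold change must be > 0, got {rho}")
    gene = rho_fc.gene if isinstance(rho_fc, FoldChange) else ""
    ratio = float(np.mean(values)) / rho
    lo, hi = NUSG_THRESHOLDS
    if ratio > hi:
        label = NusGLabel.HIGHLY_DEPENDENT
    elif ratio >= lo:
        label = NusGLabel.MODERATELY_DEPENDENT
    else:
        label = NusGLabel.INDEPENDENT
    return NusGClass(gene=gene, ratio=ratio, label=label)
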