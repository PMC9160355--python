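"""Seeded generators for synthetic study inputs with known ground truth.

Every downstream stage assumes inputs with a specific statistical
structure: terminator-zone sequences whose windowed %C exceeds %G inside
rut-site bubbles, Ct tables whose mutant/WT difference encodes a true fold
change, descriptor–response scatters with a chosen population r², and
kinetic series following exact decay/binding models plus multiplicative
noise.  These generators produce exactly those structures from explicit
parameters and emit the planted truth beside every dataset, so recovery
tests consume only (data, truth) pairs and need no external download.

Background sequence is i.i.d. with P(A)=P(C)=P(G)=P(T)=0.25 by default —
a symmetric null that makes bubble false-positive analysis clean.  Bubble
planting perturbs the per-base sampling probabilities (C up, G down by the
target amplitude) rather than splicing homopolymers, so realized window
amplitudes carry sampling noise like real sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import _PAUSE_TEMPLATE
from .errors import ValidationError
from .qpcr import CtRecord, WT_STRAIN
from .sequence_model import SequenceRecord

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BubbleSpec:
    """A planted C>G bubble: C enriched / G depleted over [start, start+length)."""

    start: int
    length: int
    amplitude: float  # target E[%C - %G] inside the bubble, percent


@dataclass(frozen=True)
class MotifChainSpec:
    """A planted YC chain: ``order`` dimers spliced with the given gaps."""

    start: int
    order: int
    gaps: tuple[int, ...] = ()  # length order-1, each in [9, 13]
    dimer: str = "CC"


@dataclass
class PlantedTruth:
    """Ground truth emitted beside every generated dataset."""

    bubbles: list[BubbleSpec] = field(default_factory=list)
    motif_chains: list[MotifChainSpec] = field(default_factory=list)
    pause_offsets: list[int] = field(default_factory=list)
    true_fc: dict[str, float] = field(default_factory=dict)
    decay_params: Optional[tuple[float, float]] = None  # (A, lam)
    binding_params: Optional[tuple[float, float, float]] = None  # (bmax, kd, n)
    true_r2: Optional[float] = None


def _spliced_span(m: MotifChainSpec) -> int:
    return 2 * m.order + sum(m.gaps)


def gen_sequence_with_planted_features(
    length: int,
    bubbles: Sequence[BubbleSpec] = (),
    motifs: Sequence[MotifChainSpec] = (),
    pauses: Sequence[int] = (),
    seed: int = 0,
    background_gc: float = 0.5,
) -> tuple[SequenceRecord, PlantedTruth]:
    """Generate a sequence with planted bubbles, YC chains and pause sites.

    ``pauses`` lists offsets at which the literal pause consensus (C
    variant) is spliced.  Features must fit inside ``length`` and must not
    overlap one another.  Same seed, same arguments -> identical output.
    """
    rng = np.random.default_rng(seed)
    occupied: list[tuple[int, int]] = []

    def claim(start: int, end: int, what: str) -> None:
        if start < 0 or end > length:
            raise ValidationError(f"{what} [{start},{end}) outside sequence of {length} nt")
        for s, e in occupied:
            if start < e and s < end:
                raise ValidationError(f"{what} [{start},{end}) overlaps another feature")
        occupied.append((start, end))

    for b in bubbles:
        claim(b.start, b.start + b.length, "bubble")
    for m in motifs:
        claim(m.start, m.start + _spliced_span(m), "motif chain")
    pause_site = _PAUSE_TEMPLATE.replace("*", "C").upper()
    for p in pauses:
        claim(p, p + len(pause_site), "pause site")

    half_gc = background_gc / 2.0
    half_at = (1.0 - background_gc) / 2.0
    probs = np.tile([half_at, half_gc, half_gc, half_at], (length, 1))  # A C G T
    for b in bubbles:
        delta = b.amplitude / 200.0  # percent -> per-base probability shift
        if not 0 < delta <= half_gc:
            raise ValidationError(
                f"bubble amplitude {b.amplitude}% infeasible at GC {background_gc}"
            )
        probs[b.start : b.start + b.length, 1] += delta
        probs[b.start : b.start + b.length, 2] -= delta

    cum = probs.cumsum(axis=1)
    draws = rng.random(length)
    idx = (draws[:, None] > cum).sum(axis=1)
    seq = list(BASES[idx])

    for m in motifs:
        pos = m.start
        for k in range(m.order):
            seq[pos : pos + 2] = list(m.dimer)
            if k < m.order - 1:
                pos += 2 + m.gaps[k]
    for p in pauses:
        seq[p : p + len(pause_site)] = list(pause_site)

    truth = PlantedTruth(
        bubbles=list(bubbles),
        motif_chains=list(motifs),
        pause_offsets=list(pauses),
    )
    return SequenceRecord(id=f"synthetic_seed{seed}", residues="".join(seq)), truth


def gen_ct_table(
    true_fc: dict[str, float],
    strain: str = "rho_N340S",
    replicates: int = 4,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    reference_ct: float = 15.0,
    wt_delta_ct: Optional[dict[str, float]] = None,
) -> tuple[list[CtRecord], PlantedTruth]:
    """Generate a Ct table encoding known fold changes against a WT baseline.

    Each gene's WT ΔCt is drawn once (uniform on [3, 8] cycles) unless
    pinned via ``wt_delta_ct`` — pass the same mapping to every strain's
    table when tables are later pooled, so all strains share one baseline.
    The mutant ΔCt is WT ΔCt − log2(true_fc), so the noiseless 2^-ΔΔCt
    recovers ``true_fc`` exactly.  Gaussian noise of sd ``ct_noise_sd`` cycles is
    added to each replicate's target Ct; the reference (rpoC-like) Ct is
    held invariant across strains and replicates.
    """
    if replicates < 1:
        raise ValidationError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for gene in sorted(true_fc):
        fc = true_fc[gene]
        if fc <= 0:
            raise ValidationError(f"gene {gene!r}: true fold change must be > 0")
        if wt_delta_ct is not None:
            wt_dct = float(wt_delta_ct[gene])
        else:
            wt_dct = float(rng.uniform(3.0, 8.0))
        mut_dct = wt_dct - float(np.log2(fc))
        for strain_name, dct in ((WT_STRAIN, wt_dct), (strain, mut_dct)):
            noise = rng.normal(0.0, ct_noise_sd, size=replicates) if ct_noise_sd > 0 else np.zeros(replicates)
            for rep in range(replicates):
                records.append(
                    CtRecord(
                        gene=gene,
                        strain=strain_name,
                        replicate=rep,
                        ct_target=reference_ct + dct + float(noise[rep]),
                        ct_reference=reference_ct,
                    )
                )
    return records, PlantedTruth(true_fc=dict(true_fc))


def gen_correlated_pairs(
    n: int,
    true_r2: float,
    x_range: tuple[float, float] = (0.0, 10.0),
    slope: float = 1.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], PlantedTruth]:
    """Generate (x, y) pairs whose population r² equals ``true_r2``.

    x is uniform on ``x_range``; y = slope*x + Gaussian noise with variance
    chosen so slope²·Var(x) / (slope²·Var(x) + Var(noise)) = true_r2.  At
    ``true_r2 = 0`` the slope is 0 and y is pure noise (the null for
    p-value calibration).
    """
    if not 0 <= true_r2 < 1:
        raise ValidationError("true_r2 must be in [0, 1)")
    if n < 3:
        raise ValidationError("need n >= 3")
    rng = np.random.default_rng(seed)
    lo, hi = x_range
    x = rng.uniform(lo, hi, size=n)
    var_x = (hi - lo) ** 2 / 12.0
    if true_r2 == 0:
        y = rng.normal(0.0, 1.0, size=n)
    else:
        signal_var = slope**2 * var_x
        noise_sd = float(np.sqrt(signal_var * (1.0 - true_r2) / true_r2))
        y = slope * x + rng.normal(0.0, noise_sd, size=n)
    truth = PlantedTruth(true_r2=true_r2)
    return list(zip(x.tolist(), y.tolist())), truth


def gen_kinetic_series(
    kind: str,
    params: dict,
    design: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a decay time course or binding titration with known truth.

    ``kind='decay'``: params {A, lam}, design = times (min), columns
    (t_min, signal).  ``kind='binding'``: params {bmax, kd, n}, design =
    concentrations (nM), columns (conc_nM, frac_bound).  Noise is
    multiplicative Gaussian with the given relative sd.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(design, dtype=float)
    if kind == "decay":
        A, lam = float(params["A"]), float(params["lam"])
        if lam <= 0:
            raise ValidationError("decay rate lam must be > 0")
        y = A * np.exp(-lam * x)
        cols = ("t_min", "signal")
        truth = PlantedTruth(decay_params=(A, lam))
    elif kind == "binding":
        bmax = float(params.get("bmax", 1.0))
        kd = float(params["kd"])
        hn = float(params.get("n", 1.0))
        if kd <= 0:
            raise ValidationError("kd must be > 0")
        y = bmax * x**hn / (kd**hn + x**hn)
        cols = ("conc_nM", "frac_bound")
        truth = PlantedTruth(binding_params=(bmax, kd, hn))
    else:
        raise ValidationError(f"unknown kinetic series kind {kind!r}")
    if noise > 0:
        y = y * (1.0 + rng.normal(0.0, noise, size=len(x)))
        y = np.clip(y, 1e-9, None)
    return pd.DataFrame({cols[0]: x, cols[1]: y}), truth
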