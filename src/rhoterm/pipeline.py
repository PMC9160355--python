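"""End-to-end orchestration: config, fixture study, and the full analysis.

``run_full_analysis`` chains the stages — terminator-zone extraction,
bubble scanning, descriptor calculation, pause scan, ΔΔCt quantification,
strength/NusG classification, gated correlations with box summaries, and
kinetic fits — writing one TSV per stage plus a run log into an output
directory.  Outputs are deterministic: rerunning with the same inputs and
config produces byte-identical files.

``make_fixture_study`` bundles a complete miniature study (12 genes, 5
strains: WT, Rho N340S, three NusG mutants) generated from a seed, in the
same FASTA/TSV dialects the analysis stages read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import gated_correlation, group_box_summary
from .bubble_scan import bubble_table, detect_bubbles, window_profile
from .descriptors import DescriptorSet, compute_descriptors, scan_pause_sites
from .errors import ConfigurationError, InsufficientDataError
from .kinetics import fit_binding_isotherm, fit_exponential_decay
from .qpcr import (
    CtRecord,
    NUSG_MUTANTS,
    RHO_MUTANT,
    WT_STRAIN,
    classify_nusg_dependency,
    classify_strength,
    fold_change_from_ct,
)
from .sequence_model import (
    SequenceRecord,
    extract_region,
    read_annotations,
    read_fasta,
    select_analysis_interval,
    write_fasta,
)
from .synthetic import (
    BubbleSpec,
    MotifChainSpec,
    gen_ct_table,
    gen_kinetic_series,
    gen_sequence_with_planted_features,
)

BOX_DESCRIPTORS = (
    "cum_area_all_bubbles",
    "S1_longest_bubble_area",
    "cum_len_all_bubbles",
    "density_area",
)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults are the study values."""

    genome_fasta: Optional[str] = None
    annotation_tsv: Optional[str] = None
    zones_fasta: Optional[str] = None  # pre-extracted zones bypass extraction
    ct_tsv: Optional[str] = None
    decay_tsv: Optional[str] = None
    isotherm_tsv: Optional[str] = None

    scan_window: int = 70
    descriptor_window: int = 78
    step: int = 10
    strength_thresholds: tuple = (2.0, 10.0, 30.0)
    nusg_thresholds: tuple = (0.2, 0.5)
    fc_gate: float = 10.0
    fc_upper_gate: float = 40.0
    atpase_gate: float = 50.0
    motif_gap: tuple = (9, 13)
    pause_policy: str = "strict"
    whisker_percentiles: tuple = (10.0, 90.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("strength_thresholds", "nusg_thresholds", "motif_gap",
                     "whisker_percentiles"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rhoterm {__version__}: {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_ct_tsv(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CtRecord(
            gene=str(r.gene), strain=str(r.strain), replicate=int(r.replicate),
            ct_target=float(r.ct_target), ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# fixture study

FIXTURE_GENES = [
    # (gene, rho_fc, nusg_ratio, zone_nt, bubble specs [(start, len, amp%)])
    ("genA", 0.7, 0.80, 600, [(150, 120, 10.0)]),
    ("genB", 1.2, 0.70, 700, [(200, 150, 12.0)]),
    ("genC", 2.5, 0.60, 800, [(180, 200, 15.0)]),
    ("genD", 4.0, 0.55, 900, [(200, 250, 18.0)]),
    ("genE", 6.0, 0.45, 1000, [(250, 280, 20.0)]),
    ("genF", 9.0, 0.40, 1000, [(200, 300, 22.0), (650, 150, 15.0)]),
    ("genG", 12.0, 0.30, 1100, [(250, 320, 24.0)]),
    ("genH", 15.0, 0.25, 1100, [(200, 350, 26.0), (700, 180, 18.0)]),
    ("genI", 25.0, 0.15, 1200, [(250, 380, 28.0)]),
    ("genJ", 35.0, 0.12, 1200, [(200, 400, 30.0), (750, 200, 20.0)]),
    ("genK", 50.0, 0.08, 1300, [(250, 420, 32.0)]),
    ("genL", 66.6, 0.05, 1400, [(200, 450, 34.0), (800, 220, 24.0)]),
]

_SPACER_NT = 200
_PROBE_NT = 20


def make_fixture_study(outdir: str | Path, seed: int = 0) -> Path:
    """Write a complete miniature study (12 genes, 5 strains) to ``outdir``.

    Produces genome.fasta, annotations.tsv, ct.tsv, decay.tsv,
    isotherms.tsv, truth.json and a ready-to-run config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seq_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(len(FIXTURE_GENES))]
    aux = root.spawn(8)

    genome_parts: list[str] = []
    ann_rows: list[dict] = []
    truth: dict = {"seed": seed, "genes": {}}
    rng_sp = np.random.default_rng(int(aux[0].generate_state(1)[0] % 2**31))
    offset = 0

    def spacer() -> str:
        nonlocal offset
        s = "".join(rng_sp.choice(list("ACGT"), size=_SPACER_NT))
        offset += _SPACER_NT
        return s

    for i, (gene, rho_fc, ratio, zone_nt, bspecs) in enumerate(FIXTURE_GENES):
        genome_parts.append(spacer())
        bubbles = [BubbleSpec(s, l, a) for s, l, a in bspecs]
        motifs, pauses = [], []
        if gene == "genL":  # one gene carries a planted chain and pause site
            motifs = [MotifChainSpec(start=60, order=3, gaps=(9, 11))]
            pauses = [zone_nt - 60]
        rec, _ = gen_sequence_with_planted_features(
            zone_nt, bubbles, motifs, pauses, seed=seq_seeds[i]
        )
        strand = "-" if i % 3 == 2 else "+"
        first = i % 4 != 3
        zstart, zend = offset, offset + zone_nt
        genome_parts.append(
            rec.residues if strand == "+" else _revcomp(rec.residues)
        )
        offset = zend
        row = {
            "gene": gene, "contig": "synthetic_contig", "strand": strand,
            "tss": "", "fp_start": "", "fp_end": "",
            "rp_start": "", "rp_end": "", "first_in_operon": first,
            "upstream_rp_start": "", "upstream_rp_end": "",
        }
        if first:
            if strand == "+":
                row.update(tss=zstart + 1, rp_start=zend - _PROBE_NT + 1, rp_end=zend)
            else:
                row.update(tss=zend, rp_start=zstart + 1, rp_end=zstart + _PROBE_NT)
        else:  # downstream-gene rule: the zone lies between the two RP probes
            left = {"start": zstart - _PROBE_NT + 1, "end": zstart}
            right = {"start": zend + 1, "end": zend + _PROBE_NT}
            own, upstream = (right, left) if strand == "+" else (left, right)
            row.update(
                rp_start=own["start"], rp_end=own["end"],
                upstream_rp_start=upstream["start"], upstream_rp_end=upstream["end"],
            )
            genome_parts.append("".join(rng_sp.choice(list("ACGT"), size=_PROBE_NT)))
            offset += _PROBE_NT
        ann_rows.append(row)
        truth["genes"][gene] = {
            "rho_fc": rho_fc, "nusg_ratio": ratio, "zone_nt": zone_nt,
            "strand": strand, "bubbles": bspecs,
            "motif_chains": [(m.start, m.order, list(m.gaps)) for m in motifs],
            "pause_offsets": pauses,
        }
    genome_parts.append(spacer())
    genome = SequenceRecord("synthetic_contig", "".join(genome_parts))
    write_fasta([genome], outdir / "genome.fasta")
    pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    # Ct tables: Rho mutant carries rho_fc; each NusG mutant carries
    # ratio * rho_fc, so the recovered dependency ratio matches the truth.
    # All strains share one WT baseline ΔCt per gene.
    rng_wt = np.random.default_rng(int(aux[7].generate_state(1)[0] % 2**31))
    wt_dct = {g: float(rng_wt.uniform(3.0, 8.0)) for g, *_ in FIXTURE_GENES}
    rho_truth = {g: fc for g, fc, *_ in FIXTURE_GENES}
    ct_records, _ = gen_ct_table(
        rho_truth, strain=RHO_MUTANT, replicates=4, ct_noise_sd=0.2,
        seed=int(aux[1].generate_state(1)[0] % 2**31), wt_delta_ct=wt_dct,
    )
    for k, mut in enumerate(NUSG_MUTANTS):
        nusg_truth = {g: fc * ratio for g, fc, ratio, *_ in FIXTURE_GENES}
        recs, _ = gen_ct_table(
            nusg_truth, strain=mut, replicates=4, ct_noise_sd=0.2,
            seed=int(aux[2 + k].generate_state(1)[0] % 2**31), wt_delta_ct=wt_dct,
        )
        ct_records.extend(r for r in recs if r.strain == mut)
    pd.DataFrame([asdict(r) for r in ct_records]).to_csv(
        outdir / "ct.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # kinetics: four decay series and four titrations with known parameters
    decay_frames, iso_frames = [], []
    decay_truth, binding_truth = {}, {}
    t_design = [0, 2, 4, 6, 8, 10]
    c_design = [0.5, 1, 2, 5, 10, 20, 35, 50]
    for j, (gene, lam) in enumerate(
        [("genA", 0.08), ("genD", 0.14), ("genH", 0.23), ("genL", 0.35)]
    ):
        df, _ = gen_kinetic_series(
            "decay", {"A": 100.0, "lam": lam}, t_design, noise=0.05,
            seed=int(aux[5].generate_state(4)[j] % 2**31),
        )
        df.insert(0, "series_id", gene)
        decay_frames.append(df)
        decay_truth[gene] = {"A": 100.0, "lam": lam}
    for j, (gene, kd, hn) in enumerate(
        [("genC", 4.0, 1.0), ("genF", 8.0, 2.5), ("genI", 15.0, 2.0), ("genK", 25.0, 1.0)]
    ):
        df, _ = gen_kinetic_series(
            "binding", {"bmax": 1.0, "kd": kd, "n": hn}, c_design, noise=0.03,
            seed=int(aux[6].generate_state(4)[j] % 2**31),
        )
        df.insert(0, "series_id", gene)
        iso_frames.append(df)
        binding_truth[gene] = {"bmax": 1.0, "kd": kd, "n": hn}
    pd.concat(decay_frames).to_csv(
        outdir / "decay.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.concat(iso_frames).to_csv(
        outdir / "isotherms.tsv", sep="\t", index=False, float_format="%.10g"
    )
    truth["decay"] = decay_truth
    truth["binding"] = binding_truth
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    cfg = PipelineConfig(
        genome_fasta=str(outdir / "genome.fasta"),
        annotation_tsv=str(outdir / "annotations.tsv"),
        ct_tsv=str(outdir / "ct.tsv"),
        decay_tsv=str(outdir / "decay.tsv"),
        isotherm_tsv=str(outdir / "isotherms.tsv"),
        seed=seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return outdir


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# full analysis

def run_full_analysis(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage the config provides inputs for; write TSVs + run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"rhoterm {__version__}"]
    inputs: dict[str, str] = {}

    # -- sequences: extract zones from a genome, or read them pre-extracted
    zones: list[SequenceRecord] = []
    if config.genome_fasta and config.annotation_tsv:
        genome = read_fasta(config.genome_fasta)
        contigs = {g.id: g for g in genome}
        anns = read_annotations(config.annotation_tsv)
        region_rows = []
        for ann in anns:
            region = select_analysis_interval(ann, min_length=config.descriptor_window)
            zones.append(extract_region(contigs[region.contig], region))
            s1, e1 = region.to_report_coords()
            region_rows.append(
                {"gene": region.gene, "contig": region.contig, "start": s1,
                 "end": e1, "strand": region.strand,
                 "rule_applied": region.rule_applied.value, "L_t": len(region)}
            )
        _write_tsv(pd.DataFrame(region_rows), outdir / "regions.tsv",
                   "terminator-zone intervals (1-based inclusive)")
        write_fasta(zones, outdir / "zones.fasta")
        inputs["genome_fasta"] = _sha256(Path(config.genome_fasta))
        inputs["annotation_tsv"] = _sha256(Path(config.annotation_tsv))
    elif config.zones_fasta:
        zones = read_fasta(config.zones_fasta)
        inputs["zones_fasta"] = _sha256(Path(config.zones_fasta))

    # -- bubbles, descriptors, pause sites
    if zones:
        brows, drows, prows = [], [], []
        for z in zones:
            prof = window_profile(z, config.scan_window, config.step)
            brows.extend(bubble_table(z.id, detect_bubbles(prof)))
            drows.append(
                compute_descriptors(z, config.descriptor_window, config.step).as_row(z.id)
            )
            for hit in scan_pause_sites(z, policy=config.pause_policy):
                prows.append(
                    {"gene": z.id, "offset": hit.offset + 1,
                     "matched": hit.matched, "variant": hit.variant}
                )
        _write_tsv(pd.DataFrame(brows), outdir / "bubbles.tsv",
                   f"C>G bubbles, window {config.scan_window} step {config.step}")
        _write_tsv(pd.DataFrame(drows), outdir / "descriptors.tsv",
                   f"rut-site descriptors, window {config.descriptor_window}")
        _write_tsv(
            pd.DataFrame(prows, columns=["gene", "offset", "matched", "variant"]),
            outdir / "pause_hits.tsv",
            f"elemental pause consensus hits, policy {config.pause_policy}",
        )
        log.append(f"analyzed {len(zones)} terminator zones")

    # -- fold changes and classifications
    fold_changes: dict[tuple[str, str], float] = {}
    if config.ct_tsv:
        records = read_ct_tsv(config.ct_tsv)
        inputs["ct_tsv"] = _sha256(Path(config.ct_tsv))
        genes = sorted({r.gene for r in records})
        strains = sorted({r.strain for r in records} - {WT_STRAIN})
        fc_rows, cls_rows = [], []
        for gene in genes:
            per_strain = {}
            for strain in strains:
                try:
                    fc = fold_change_from_ct(records, gene, strain)
                except Exception:
                    continue
                per_strain[strain] = fc
                fc_rows.append(
                    {"gene": gene, "strain": strain, "mean_fc": fc.mean_fc,
                     "sd_fc": fc.sd_fc, "n": fc.n_replicates}
                )
            row = {"gene": gene, "strength_class": "", "nusg_ratio": "",
                   "nusg_class": ""}
            rho = per_strain.get(RHO_MUTANT)
            if rho is not None:
                row["strength_class"] = classify_strength(rho).value
                fold_changes[(gene, RHO_MUTANT)] = rho.mean_fc
                nusg = [per_strain[m] for m in NUSG_MUTANTS if m in per_strain]
                if len(nusg) == len(NUSG_MUTANTS):
                    nc = classify_nusg_dependency(nusg, rho)
                    row["nusg_ratio"] = nc.ratio
                    row["nusg_class"] = nc.label.value
            cls_rows.append(row)
        _write_tsv(pd.DataFrame(fc_rows), outdir / "fold_changes.tsv",
                   "2^-ddCt fold changes vs WT")
        _write_tsv(pd.DataFrame(cls_rows), outdir / "classifications.tsv",
                   "terminator strength and NusG-dependency classes")
        log.append(f"quantified {len(genes)} genes x {len(strains)} strains")

    # -- gated correlations and NusG-class box summaries
    if zones and fold_changes:
        desc_df = pd.read_csv(outdir / "descriptors.tsv", sep="\t", comment="#")
        desc_df = desc_df.set_index("gene")
        reg_rows, box_rows = [], []
        cls_df = pd.read_csv(outdir / "classifications.tsv", sep="\t", comment="#")
        for name in DescriptorSet.FIELDS:
            pairs = [
                (fold_changes[(g, RHO_MUTANT)], float(desc_df.loc[g, name]))
                for g in desc_df.index
                if (g, RHO_MUTANT) in fold_changes
            ]
            for gate in ("all", "fc_lt_10"):
                try:
                    r = gated_correlation(pairs, gate)
                except InsufficientDataError:
                    continue
                reg_rows.append(
                    {"descriptor": name, "gate": r.gate, "n": r.n,
                     "slope": r.slope, "intercept": r.intercept, "r2": r.r2,
                     "p": r.p}
                )
        dep = cls_df.loc[cls_df.nusg_class == "highly_dependent", "gene"]
        indep = cls_df.loc[cls_df.nusg_class == "independent", "gene"]
        for name in BOX_DESCRIPTORS:
            dep_v = [float(desc_df.loc[g, name]) for g in dep if g in desc_df.index]
            ind_v = [float(desc_df.loc[g, name]) for g in indep if g in desc_df.index]
            if not dep_v or not ind_v:
                continue
            bd, bi, red = group_box_summary(
                dep_v, ind_v, name, config.whisker_percentiles
            )
            for group, b in (("highly_dependent", bd), ("independent", bi)):
                box_rows.append(
                    {"descriptor": name, "group": group, "n": b.n,
                     "median": b.median, "q1": b.q1, "q3": b.q3,
                     "whisker_low": b.whisker_low, "whisker_high": b.whisker_high,
                     "median_reduction_pct": red if group == "highly_dependent" else ""}
                )
        _write_tsv(pd.DataFrame(reg_rows), outdir / "regressions.tsv",
                   "gated OLS fits: fold change (x) vs descriptors (y)")
        _write_tsv(pd.DataFrame(box_rows), outdir / "box_summaries.tsv",
                   "descriptor distributions by NusG class")

    # -- kinetics
    fit_rows = []
    if config.decay_tsv:
        df = pd.read_csv(config.decay_tsv, sep="\t", comment="#")
        inputs["decay_tsv"] = _sha256(Path(config.decay_tsv))
        for sid, grp in df.groupby("series_id", sort=True):
            f = fit_exponential_decay(grp["t_min"], grp["signal"])
            fit_rows.append(
                {"series_id": sid, "kind": "decay", "A": f.A, "lam": f.lam,
                 "half_life_min": f.half_life if f.half_life is not None else "",
                 "initial_rate": f.initial_rate if f.initial_rate is not None else "",
                 "kd_nM": "", "hill_n": "", "bmax": "", "rss": f.rss,
                 "n_points": f.n_points, "flags": ",".join(f.flags)}
            )
    if config.isotherm_tsv:
        df = pd.read_csv(config.isotherm_tsv, sep="\t", comment="#")
        inputs["isotherm_tsv"] = _sha256(Path(config.isotherm_tsv))
        for sid, grp in df.groupby("series_id", sort=True):
            f = fit_binding_isotherm(grp["conc_nM"], grp["frac_bound"])
            fit_rows.append(
                {"series_id": sid, "kind": f"binding_{f.model}", "A": "",
                 "lam": "", "half_life_min": "", "initial_rate": "",
                 "kd_nM": f.kd, "hill_n": f.hill_n, "bmax": f.bmax,
                 "rss": f.rss, "n_points": f.n_points, "flags": ",".join(f.flags)}
            )
    if fit_rows:
        _write_tsv(pd.DataFrame(fit_rows), outdir / "kinetic_fits.tsv",
                   "exponential-decay and binding-isotherm fits")
        log.append(f"fitted {len(fit_rows)} kinetic series")

    # -- run log and config echo (no timestamps: outputs stay reproducible)
    config.to_yaml(outdir / "config_used.yaml")
    cfg_hash = hashlib.sha256(
        (outdir / "config_used.yaml").read_bytes()
    ).hexdigest()
    log.append(f"config sha256 {cfg_hash}")
    log.extend(f"input {k} sha256 {v}" for k, v in sorted(inputs.items()))
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outdir
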