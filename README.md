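# rhoterm

Analysis pipeline for **in vivo Rho-dependent transcription termination** in
bacteria: scoring *rut* sites by their C>G sequence "bubbles", quantifying
terminator strength from RT-qPCR Ct tables, classifying NusG dependency,
and fitting the supporting kinetics (RNA half-lives, Rho ATPase time
courses, Rho–RNA binding isotherms).

## The science

Rho is a homo-hexameric, RNA-dependent ATPase that terminates bacterial
transcription by loading onto C-rich/G-poor, unstructured regions of the
nascent RNA (*rut* sites) and translocating 5′→3′ to catch the elongation
complex. A *rut* site's compositional signature is a **C>G bubble**: a
stretch where windowed %C exceeds %G. This package scans terminator-zone
sequences with a sliding window (70 nt scan / 78 nt descriptors, 10 nt
step) and summarizes the bubbles as 13 descriptors — longest-bubble length
L1 and area S1, cumulated length/area of all bubbles, their densities over
the zone length L_t (area S_i = Σ(%C−%G)·step over a bubble, in % × bp),
the longest bubble's max %C, max and mean %C−%G, and counts of YC-dimer
chains [(YC)N9→13]k (Y = pyrimidine, 9–13 nt between consecutive dimers),
which mark the primary RNA-binding site of Rho.

In vivo terminator strength is measured by read-through: in a strain whose
Rho (N340S) or NusG (G146D/V160N/L158Q, Rho-binding defective) is
compromised, transcription reads through the terminator and the downstream
gene is upregulated. From Ct tables, the fold change is 2^−ΔΔCt with
ΔCt = Ct(target) − Ct(*rpoC*) and ΔΔCt = ΔCt(mutant) − ΔCt(WT).
Classification: weak/non (<2-fold), moderate (2–10), strong (10–30), very
strong (>30). NusG dependency is the ratio of the average NusG-mutant fold
change to the Rho-mutant fold change: >0.5 highly dependent, 0.2–0.5
moderate, <0.2 independent. Associations are gated linear fits
(y = y0 + ax; e.g. fold changes <10 against descriptors), and group
contrasts are box summaries (linear-interpolation percentiles) with the
percent reduction of the median. Half-lives come from y = A·e^(−λt)
(t1/2 = ln2/λ); dissociation constants from hyperbolic or Hill isotherms.

A seeded synthetic-data module generates every input type with known
ground truth (planted bubbles/motifs/pause sites, true fold changes, true
λ and Kd, chosen population r²), so the whole pipeline is testable
end-to-end without any external data.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_scan_rut_sites.py
python analysis/03_quantify_terminators.py
python analysis/04_descriptor_correlations.py
python analysis/05_kinetics_fits.py
```

The first script writes a 12-gene, 5-strain synthetic study with planted
truth. The remaining steps print, for seed 1:

```
classified 12 terminators -> results/tables/qpcr
  strength strong: 4
  strength moderate: 3
  strength very_strong: 3
  strength weak_or_non: 2
  NusG highly_dependent: 4
  NusG moderately_dependent: 4
  NusG independent: 4
...
  cum_area_all_bubbles: median reduction 72% in NusG-dependent group
...
  genA: half-life 8.5 min
  genC: Kd 3.6 nM (hyperbolic, n=1.0)
```

i.e. the recovered strength classes, NusG classes, descriptor contrasts
and kinetic parameters track the values planted by the generator (the
study's truth.json records them). The same stages are available as a CLI
(`rhoterm scan|descriptors|pause|extract|quantify|fit|simulate|fixtures|run-all`)
and as library functions (`rhoterm.compute_descriptors`,
`rhoterm.fold_change_from_ct`, ...).

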