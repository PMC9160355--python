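# Methods

This note documents the models, conventions and numerical choices behind
the pipeline, what the synthetic generators do and do not emulate, and the
known limitations.

## Terminator-zone selection

The analyzed interval for a gene depends on where its qPCR reverse-primer
(RP) probe sits in the operon. For a first-in-operon gene the interval runs
from the transcription start site to the transcription-direction distal end
of the RP probe (the probe's far edge defines the assayed transcript
extent). For a downstream gene it is the interval strictly between the
gene's own RP probe and the upstream gene's RP probe; probe sequences are
excluded so primer-binding bases are not double-counted. Intervals shorter
than one descriptor window (78 nt) are rejected. Internally all coordinates
are 0-based half-open; files and reports use 1-based inclusive coordinates.
A minus-strand TSS in a file is the 1-based first transcribed base, which
numerically equals the interval's 0-based exclusive end. Extracted
sequences are the RNA-sense (non-template) strand, reverse-complemented
for minus-strand genes, normalized to the DNA alphabet (U→T, uppercase);
the pyrimidine set is Y = {C, T}.

## Bubble detection

The profile slides a window (70 nt for scanning, 78 nt for descriptors;
step 10 nt) along the sequence; %C and %G are 100·count/window, ambiguity
codes counting toward neither. Windows never wrap, and trailing residues
not covered by a final full window are ignored — consequences: a
homopolymer's reported bubble spans the last full window's end, so the
length-density of a poly-C sequence is exactly 1 only when full windows
tile the length ((L − window) divisible by the step).

A bubble is a maximal run of consecutive windows with %C − %G strictly
positive (a tie at 0 breaks the run); an optional `threshold` raises the
qualification bound. Its area is the step-weighted sum of the run's
%C − %G values, in % × bp — the step is the stretch of sequence each
sliding position uniquely represents, which keeps area additive across
windows.

Two boundary conventions are provided because no single one serves both
roles:

* **footprint** (default): first window start → last window start +
  window. Covers every base of every qualifying window, but systematically
  overstates a bubble's length by up to one window (and footprints of
  nearby bubbles may overlap, so summed lengths are not bounded by L_t).
* **center**: each window contributes the step-length segment centered in
  it; runs touching the profile's edge are clamped to the sequence
  boundary. Extents are disjoint, sum to ≤ L_t, and the length of a
  compositional feature is estimated without the one-window bias — this is
  the convention for quantitative length recovery.

On a composition-balanced background the bare %C > %G rule qualifies
roughly half of all windows by chance (the window statistic is a
zero-mean lattice variable), so featureless sequence yields several short
spurious bubbles per kilobase. This is inherent to the definition, not a
bug; the measured false-positive rates are asserted in the test suite
(~8/kb at threshold 0, ~1.5/kb at 15% threshold, ~0 at 30%). Recovery of
a planted bubble of amplitude a is therefore performed at threshold a/2 —
the decision boundary between background (0) and bubble (a) — with center
extents, and its accuracy is stated as a median over seeds because single
draws carry boundary-sampling noise of roughly ±2 windows.

## Descriptors

Thirteen per zone: longest-bubble length (L1), cumulated bubble length,
length density (cum/L_t), longest-bubble area (S1), cumulated area, area
density, and the longest bubble's max %C, max %C−%G and mean %C−%G; plus
YC-dimer chain counts of order 1/2/3 inside the longest bubble and the
whole-sequence YC-dimer density (count/L_t). The "longest" bubble is the
one maximizing length, ties broken by larger area then 5′-most position
(a deterministic rule is required; the choice is arbitrary but fixed).
All bubble-scoped descriptors are 0 when no window qualifies.

YC dimers overlap freely (CCC contains two). A chain of order k needs
k−1 qualifying spacings; the spacing is measured from the end of one dimer
to the start of the next (9–13 nt), with start-to-start measurement
available as an option since the informal "distance between motifs" is
ambiguous. Chains are counted by distinct start offset — a dimer begins at
most one counted chain of each order, however many downstream partners
qualify — which is the regex-occurrence reading of "occurrences of k
consecutive dimers" and guarantees yc3 ≤ yc2 ≤ yc1 on every sequence
(counting all ordered pairs would violate that wherever dimers overlap,
e.g. inside a CCC run). Whether the YC density's numerator should be
restricted to bubbles is unclear from its definition; the whole sequence
is used here.

The elemental pause consensus GGcataatTG(C/T)GGCcg (16 nt, one degenerate
position) is matched either strictly (every position literal) or
core-only (only the strongly conserved, uppercase positions constrained);
strict is the default, under which a hit in random sequence is a
~2·4⁻¹⁵ event. Overlapping hits are all reported.

A QC note rather than a filter: in the study system the 5′-most bubble is
expected ≥100 nt downstream of the TSS, so the descriptor table carries
the 5′-most bubble offset for inspection.

## qPCR quantification and classification

Per replicate, ΔCt = Ct(target) − Ct(reference); the reference transcript
(rpoC by convention) is assumed invariant across strains. Each mutant
replicate's ΔΔCt is taken against the **mean** WT ΔCt (replicate pairing
across strains is not meaningful for independently grown cultures), and
per-replicate fold changes 2^−ΔΔCt are aggregated by arithmetic mean with
sd; geometric aggregation is available since log-scale noise is the more
natural model. Adding a constant to both Ct values of a replicate cancels
exactly.

Strength classes use half-open-right intervals — <2 weak/non, [2, 10)
moderate, [10, 30) strong, ≥30 very strong — because the printed class
edges overlap and a deterministic convention is needed. The NusG ratio is
mean(NusG-mutant fold changes)/Rho-mutant fold change, three mutants by
default (relaxable); >0.5 high, [0.2, 0.5] (closed) moderate, <0.2
independent.

## Associations

Regressions are ordinary least squares y = y0 + ax with r² and the exact
two-sided t-test p-value of the slope. Gates (fold change <10, >10, ≤40;
ATPase rate <50; all; or a numeric threshold) filter on the x variable
before fitting, with ≥3 surviving points required. r² > 0.3 is carried as
the significance convention for this data regime; no multiple-testing
correction is applied across descriptors, matching the analysis this
pipeline reproduces. Box summaries use linear-interpolation percentiles;
whiskers default to the 10th/90th percentiles (the source convention for
outlier marks is internally inconsistent, so this is configurable), and
the group contrast is 100·(median_indep − median_dep)/median_indep.

## Kinetics

Decay series are fit to y = A·e^(−λt) by nonlinear least squares started
from the log-linear regression of ln y on t (requiring y > 0 and ≥3
distinct times). Fits with λ ≤ 0, or with negligible decay over the
observed span (λ·span ≤ 1e−9), are flagged non-decaying and report no
half-life; otherwise t1/2 = ln2/λ exactly. Both λ and the initial rate
A·λ are reported, since "the rate" of an assay depends on its calibration.

Isotherms are fit to the hyperbola bmax·x/(Kd + x) or the Hill sigmoid
bmax·xⁿ/(Kdⁿ + xⁿ) (the standard sigmoid form; n ∈ [1, 8],
bmax ∈ (0, 1.2] to absorb normalization error) with bounded least squares
from analytic start points (bmax from the max response, Kd from the
half-max crossing), so no random initialization is involved. `auto`
selects by small-sample-corrected AIC; fixing n = 1 reproduces the
hyperbolic fit identically. Titrations whose largest response stays below
half the fitted plateau are flagged wide-CI rather than rejected.

## Synthetic data

Backgrounds are i.i.d. with P(A)=P(C)=P(G)=P(T)=0.25 — a symmetric null
that makes bubble false-positive analysis clean (configurable GC). A
planted bubble of amplitude a% shifts per-base probabilities (C up, G down
by a/200 each) rather than splicing homopolymers, so realized window
amplitudes fluctuate like real sequence; motif chains and pause sites are
spliced literally. Ct tables draw one WT ΔCt per gene (uniform 3–8
cycles; pinnable so pooled multi-strain tables share a baseline), set the
mutant ΔCt to WT − log2(true fold change), and add Gaussian noise (default
sd 0.2 cycles, 3–4 replicates — typical qPCR replicate scatter) to target
Cts only. Correlated pairs fix the noise variance from the population
identity r² = a²Var(x)/(a²Var(x) + σ²). Kinetic series add multiplicative
Gaussian noise (5% default, typical of band/absorbance quantification).
Every generator emits its planted truth beside the data and is
byte-reproducible for a fixed seed.

What the generators do **not** emulate: real rut sites sit in sequence
with local composition structure, codon bias and secondary-structure
constraints, none of which the i.i.d. background has; qPCR efficiencies
are assumed exactly 2 (no standard-curve correction); kinetic noise is
homoscedastic on the log scale. Passing recovery tests therefore show the
estimators are correct under their stated models, not that the biological
conclusions transfer to any particular genome.

## Problem sizes and defaults

The bundled study is 12 genes × 5 strains with zones of 600–1400 nt, four
decay series and four titrations — large enough that every stage runs and
every class is populated, small enough that the full pipeline and its
tests complete in seconds. Monte-Carlo checks use 200–1000 replicates,
which bounds the standard error of the reported medians well below the
tolerances asserted. The scan window (70), descriptor window (78), step
(10), strength thresholds (2/10/30), NusG thresholds (0.2/0.5), gates
(10/40 fold, 50 pmol/min), and motif gap bounds (9–13) are the study's
stated values and are all overridable in `PipelineConfig`.

## Known limitations

* Bubble extents are quantized to the step, and the footprint convention
  is biased long by construction; comparisons across window sizes should
  use one convention throughout.
* Which window (70 vs 78 nt) produced which published figure is not
  recoverable, so both are exposed and the choice is recorded in every
  output's metadata.
* The p-values of the gated regressions assume i.i.d. Gaussian residuals;
  with n ≈ 5–12 points per gate they are indicative, not exact.
* The pipeline accepts a precomputed folding-ΔG column for correlation
  but does not compute RNA folding energies itself.
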