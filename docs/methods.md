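# Methods

This note documents the models and procedures implemented in `mirxplat`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Probe-target hybrid thermodynamics

Microarray detection probes are DNA oligonucleotides hybridizing mature miRNAs
(RNA), so duplex stability is governed by RNA/DNA *hybrid* nearest-neighbor
parameters, which differ substantially from both DNA/DNA and RNA/RNA sets. We
use the Sugimoto et al. (1995) hybrid parameter set, shipped as a plain-text
TSV (`src/mirxplat/data/sugimoto_rna_dna_nn.tsv`) so the engine is data-driven
and auditable. Steps are keyed by the RNA strand read 5'→3'; the DNA strand is
implied by complementarity. On load the table is checked for internal
consistency (ΔG°37 = ΔH° − 310.15·ΔS°/1000 within 0.1 kcal/mol per entry) and
for completeness (exactly 16 steps plus one initiation entry).

Free energy of a duplex is the sum of per-step ΔG°37 values plus the
initiation ΔG°37. Probes must be exact reverse complements of a 3'-anchored
(or full-length) segment of the miRNA — the geometry of both platforms'
designs — and any internal mismatch is an error naming the first mismatched
position. No dangling-end or mismatch corrections are applied. Probes written
with a parenthesized optional 3' residue (the hairpin-linker platform's
notation) are evaluated twice: tail-bearing species first, then the base
probe.

Melting temperature uses the two-state formula

```
Tm(°C) = 1000·ΔH° / (ΔS° + A + R·ln(Ct/4)) − 273.15
         + 16.6·log10([Na+]) − F·(% formamide)
```

with ΔH° (kcal/mol) and ΔS° (cal/(K·mol)) summed over steps **including** the
parameter table's initiation ΔH°/ΔS°, A = −10.8 cal/(K·mol) an additional
entropic helix-initiation factor, Ct/4 the standard non-self-complementary
two-state convention (natural log), the salt term in log10 (exactly zero at
the 1 M Na+ default), and F = 0.63 °C per percent formamide (35% default).
Default conditions are the reference panel's: 1 M Na+, Ct = 100 µM,
R = 1.987 cal/(K·mol).

**Initiation calibration.** Whether A replaces or supplements the parameter
set's own initiation entropy is ambiguous in the field's shorthand notation.
Both variants are implemented (`include_init_in_tm`); the supplementing
variant is the default because it reproduces the packaged reference panel: it
matches eight of the twelve assays' published Tm to 0.1 °C, whereas the
replacing variant matches none.

**Known inconsistency in the reference panel.** The published Tm values for
mmu-miR-15a (56.2), -34a (60.4), -146a (59.5) and -182 (62.9 °C) cannot be
reproduced by any convention we tested (either initiation variant,
DNA-strand-keyed steps, DNA/DNA unified parameters, reversed strand keying,
Ct with or without the /4 factor, µM-vs-M units), while the other eight
assays — and *all twelve* free energies, including both species of every
dual-variant probe — match exactly. Those four are precisely the assays added
to the panel as qPCR controls, suggesting they were computed separately and
erroneously. The acceptance tests assert the printed values verbatim and
therefore fail on those rows by design; the package reports its faithfully
computed values (e.g. 42.1 °C for the miR-15a duplex). Similarly, the printed
GC percent of mmu-miR-96 (40) corresponds to 9 G+C over 22 nt, but the
sequence is 23 nt long (9/23 = 39.1%); with the truncation rule that
reproduces the other eleven rows exactly we report 39.

**GC rounding.** The panel's integer GC column is reproduced by truncating
the percentage toward zero (12/22 = 54.55 → 54); round-half-up would give 55.
Truncation is therefore the default and only rule.

## Normalization

Two vendor-style arms are modeled, and the orchestrator enforces each arm's
order of operations:

* **Quantile normalization** (platform A): every sample is forced to the
  common distribution given by the row-wise mean of sorted columns; tied
  values receive the mean of their candidate values (average ranks with
  linear interpolation), which preserves idempotence. Normalization operates
  on raw intensities; log2 is taken downstream by the differential-expression
  stage, matching vendor QC-tool behavior.
* **75th-percentile scaling → clamping → median summarization** (platform B):
  each sample is divided by its 75th percentile (linear-interpolation
  percentile, the common "type 7" rule — the convention is configurable via
  `q`) and multiplied by the geometric mean of all samples' 75th percentiles,
  so the operation is idempotent and preserves the overall scale. Whether the
  vendor targets a fixed constant or a cross-array level is not public; the
  geometric-mean target is this package's choice. All values ≤ 0 are then
  replaced by 0.01 — zeros are clamped along with negatives because a zero
  would map to −∞ under log2 — and the 20 technical replicate spots per miRNA
  are collapsed to per-sample medians (mean-of-middle-two for even counts).

Every transform appends a provenance line (operation, parameters, shape) to
the matrix log; the pipeline writes the accumulated log next to its outputs.

## Detection calling and concordance

Vendor present/absent flags are produced by proprietary feature-extraction
software and are not reproducible from published descriptions. The package's
default rule is explicit instead: a miRNA is detected in a group when its
median normalized signal across the group's samples exceeds a threshold,
defaulting to the matrix-wide median. The rule and threshold are recorded in
every call. Published detection counts made with vendor flags are therefore
not comparison targets; what the package reproduces is the *shape* of the
concordance analysis: per-group detected counts, fractions of the shared
feature universe, the commonly detected fraction, and platform-exclusive
sets. The universe ("overlapping genes") is always supplied explicitly —
simulated runs use the simulated feature set, external runs a one-name-per-
line file — never inferred silently.

The GC discordance diagnostic reports, for each of the platform-A-exclusive,
platform-B-exclusive and shared sets, the member miRNAs with their GC
percent, range and mean. On the packaged panel it reproduces the published
observation that the GC-sensitive platform's exclusive calls sit at 54–59%
GC while the other platform's exclusive calls span 36–50%.

## Differential expression

Per-sex contrasts (transgenic vs wild-type within males, and within females)
use Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom, computed on log2 signals by default (configurable; signals are
clamped at 0.01 before the log). Zero pooled variance with equal means yields
t = 0, p = 1. Fold change is the signal logarithm ratio (SLR): log2 of the
ratio of group means of *linear* signals, not the mean of per-sample log
ratios.

The compound significance filter keeps features with p < 0.05, |SLR| ≥ 1.5,
and mean signal above the 50th percentile of all features' means. The
log2 threshold of 1.5 (fold change 2^1.5 ≈ 2.83) and a linear gate |FC| > 3
are both in circulation for this filter and are not equivalent; the log2
gate is the default because it is the one attached to the reported result
tables, and the linear gate is available via `min_linear_fc`. No
multiple-testing correction gates by default — matching the filter as
published — but a Benjamini–Hochberg q column is always emitted for modern
use.

qPCR quantification uses ddCt: ΔCt = Ct_target − Ct_U6 per sample,
ΔΔCt = mean ΔCt(case) − mean ΔCt(control), log2 fold change = −ΔΔCt, with
Welch's t on the per-sample ΔCt values. The reference assay's fold change is
identically 1.

## Hierarchical clustering

Agglomerative clustering on the distance 1 − r (Pearson correlation) over
log2-ratio profiles, average linkage by default (the cited clustering
software's default; complete and single are available). Ties merge the
lexicographically smallest eligible pair (clusters keyed by their smallest
leaf name), making trees deterministic and testable against an exhaustive
O(n³) reference agglomerator. Heights are monotone non-decreasing under
average linkage. Trees export to Newick with ultrametric branch lengths (a
pair merging at height h places each leaf at depth h/2); names containing
metacharacters are quoted. The clustering is axis-agnostic — the caller
chooses what the rows are; the pipeline clusters the per-platform, per-sex
SLR profiles of significant miRNAs.

## Synthetic data generator

The generator emulates the study design the analysis chain assumes: four
groups (M/F × WT/transgenic), n = 6 per group, two platforms measuring one
shared miRNA universe, and a qPCR arm. Defaults: 200 miRNAs, baseline log2
signal ~ N(8, 1.5), per-observation noise SD 0.3, GC percent ~ N(45, 10)
clipped to [15, 80] (the GC range of mature mouse miRNAs), platform A
detectability logistic in GC with midpoint 45% and slope 0.25 (the GC-biased
platform), platform B midpoint 25% and slope 0.15 (broadly sensitive),
20 replicate spots with 5% negative background-corrected values on platform
B, Ct intercept 30 with U6 at Ct 20 and qPCR noise SD 0.2. The noise
magnitudes and logistic parameters are free parameters of the simulation —
the source study publishes none — chosen to give realistic array-like
signal-to-noise; they are documented in the config schema, not claims about
any real dataset.

Planted effects are (log2FC, sex-restriction) pairs applied in the transgenic
groups, implemented as interaction terms so per-sex contrasts are meaningful.
Undetectable miRNAs (per the platform's logistic draw) fall to a constant
background level and lose their effect, coupling detection bias to
differential-expression discordance the way probe chemistry does on real
arrays. Negative platform-B spots are produced by subtracting a simulated
background exceeding the signal, not by sign-flipping. One biological signal
matrix underlies both platforms (same RNA extracts); platform B adds
spot-level technical noise (SD 0.1 log2 by default).

What the generator does **not** emulate: image-level artifacts, probe-level
cross-hybridization, pre-miRNA vs mature-miRNA confusion, sequence-isoform
effects, and correlated (batch) noise. Passing tests therefore demonstrate
that the statistical machinery is correct and calibrated under the assumed
model, not that any given real two-platform experiment will agree.

Randomness: a single seed is split per stage via NumPy `SeedSequence.spawn`,
so identical configurations are bit-identical and stages are independently
reproducible.

## Problem sizes and numerical choices

Monte-Carlo checks run at 1000 features with n = 6 vs 6 (type-I error within
the binomial band [0.035, 0.065] at α = 0.05; ≥ 80% of 100 planted
log2FC = 2 effects pass the compound filter with ≤ 10% of nulls), the
normalization property checks at 100 random matrices up to 30 × 8, and the
clustering oracle at 50 random instances of up to 6 leaves — sizes at which
the closed-form and brute-force oracles are exact and fast. Degenerate
inputs are errors rather than silent defaults: empty sequences, T in
RNA-declared input, probes with internal mismatches, constant profiles under
Pearson distance, contrast groups with fewer than two samples, missing
reference Ct values, and non-positive percentiles all raise with a message
naming the offending item.

## Known limitations

* The detection rule is a reproducible stand-in, not the vendors' flags;
  absolute detected counts from vendor software are not comparable.
* No moderated-variance (limma-style) statistics and no paired designs; with
  n = 6 per group Welch's test is what the modeled analysis used.
* Thermodynamics cover Watson–Crick RNA/DNA duplexes only: no mismatches,
  dangling ends, hairpin linkers, or DNA/DNA / RNA/RNA parameter sets.
* The four melting temperatures and one GC value noted above are faithfully
  computed and deliberately disagree with the inconsistent published figures.
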