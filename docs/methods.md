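# Methods

This note documents the models implemented in `arraycnv`, the defaults
they ship with and why, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter when reading
results.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model

A SNP-array sample is summarised per marker by the Log R Ratio (LRR;
log2 of observed over expected total intensity, 0 at two copies) and
the B Allele Frequency (BAF; estimated B-allele fraction in [0, 1]).
Markers are either polymorphic SNPs, with a population B-allele
frequency (PFB) in [0, 1], or monomorphic copy-number probes, marked by
the PFB sentinel value 2 and carrying LRR information only.
Coordinates are 1-based inclusive everywhere inside the package; BED
export/import converts to 0-based half-open at the file boundary, and
CNV length in bp is `end − start + 1`.

## HMM caller

Five hidden states, copy numbers 0–4.  Emissions factorise into an LRR
and a BAF term:

* LRR ~ Normal(μ_c, σ_LRR) with state means μ = (−3.5, −0.66, 0.0,
  0.40, 0.68) for CN 0–4.  These means are config-exposed; they are the
  working values at which deletions and duplications are separable at
  realistic noise, and the simulator emits the same means so that
  caller tests never depend on hidden constants.
* BAF at copy number c ≥ 1 is a Binomial(c, PFB)-weighted mixture of
  Normals centred at b/c (b = 0..c) with width σ_BAF, censored at the
  [0, 1] boundary: an observation at exactly 0 or 1 is scored with the
  component tail mass beyond the boundary rather than a density.  CN 0
  emits uniform BAF with a small boundary atom (10⁻³) so that clipped
  values cannot produce −∞.  Monomorphic probes and missing values
  contribute a neutral BAF term.

Transitions decay with inter-marker distance d: the total probability
of leaving a state is λ(d) = λ_max(1 − e^(−d/D)), split equally among
the other four states, with D = 100 kb.  The initial distribution
anchors the chain in the diploid state.  Maximal Viterbi runs of
non-diploid state become calls; a call's confidence is the summed
per-marker emission log-likelihood advantage of the called state over
diploid (transition terms approximately cancel over a run and are
excluded).  Calls need ≥ 5 markers and confidence ≥ 10.

Defaults: σ_LRR = 0.2, σ_BAF = 0.03, D = 100 kb; λ_max = 10⁻³ with
confidence gate 10 (`strict`) or λ_max = 10⁻² with gate 5 (`lenient`).
The two presets emulate a conservative versus a permissive caller; on
marginal events the lenient preset calls at least as many and at least
as long, which is the direction of documented caller discordance.  The
caller can optionally re-estimate per-sample noise (scaled MAD of LRR)
and drop samples above a cut (`max_lrr_sd`), mirroring the practice of
removing samples with unacceptably high LRR dispersion.

The confidence scale is this caller's own log-likelihood scale; the
value 10 is a gate in those units, not a claim of equivalence to any
other caller's confidence units.

## Marker QC

Markers inside user-supplied unstable regions (telomeres, centromeres,
immunoglobulin loci) are flagged and excluded before calling.

Sex-cross-hybridizing markers are found with three logistic regressions
of sex, each on two predictors: (X, Y) raw allele intensities, (R, Θ)
with R = X + Y and Θ = (2/π)·atan2(Y, X), and (BAF, LRR).  Two-predictor
models catch diagonal separation that single-variable screens miss.  A
marker is removed when the minimum of the six per-coefficient two-sided
Wald p-values is below 0.05 / (n_markers × n_variables) — recomputed
from the actual panel rather than hard-coded, since the threshold
derives from the marker count (at 370,404 markers and 6 variables it is
2.2×10⁻⁸).  Fits that separate the sexes perfectly (every sample
classified correctly at probability 10⁻⁶, or a runaway standardized
coefficient) receive a sentinel p of 0 and are always removed.  When
raw X/Y are absent only the (BAF, LRR) model runs and the Bonferroni
denominator uses 2 variables.

The fits are maximum-likelihood Newton iterations batched across
markers (all markers advanced simultaneously with einsum-built
Hessians), which screens 10⁴ markers in seconds; the unit tests verify
per-coefficient agreement with a reference per-marker GLM fit.  One
caveat inherent to the Wald statistic: near-separated fits at small
sample size suffer the Hauck–Donner effect (inflated standard errors,
p-values drifting toward 1).  The separation sentinel catches the fully
separated case; in the intermediate regime the test regains power with
cohort size, and the power property is therefore stated for ≥ 200
samples per sex.

## Mosaicism screening

For every sample-arm, all BAF values strictly inside (0.15, 0.85) are
collected; arms with fewer than 30 such values are classed `unknown`.
The standard deviation (population form, so the two-point band
distribution has sd exactly 1/6 at bands 1/3 and 2/3) and the
interquartile range of the mid-band are the two screening statistics.
An arm is flagged when the robust z-score (median/MAD across all arms,
MAD floored at 0.005) of either statistic exceeds 6 — an automated
stand-in for visual outlier inspection; the OR rule keeps faint
(IQR-driven) and strong (sd-driven) signatures both detectable.  The
z > 6 cut is a calibration choice, config-exposed: on null cohorts the
false-flag rate is ≤ 0.5% while arms at fraction ≥ 0.3 are flagged
essentially always (both measured by the acceptance suite).

For a flagged arm the band separation d (difference of upper and lower
band means, split at 0.5) inverts to the cell fraction: f = 2d/(1+d)
for a loss, 2d/(1−d) for a gain, direction read from mean LRR.  Band
means use a wider (0.05, 0.95) window when the screening mid-band holds
too few values, because at f ≳ 0.85 the split bands migrate past
0.15/0.85; the narrow window is preferred otherwise since homozygote
cluster tails contaminate the wide one at low fractions.

Flagged arms mostly covered (≥ 50% of the arm span, config-exposed) by
the sample's CNV calls are classed `mosaic_called_cnv` and excluded:
their calls are dropped and the arm is masked for that sample in
association.  Two or more disjoint overlapping calls give
`multi_event`, also excluded.  Flagged arms without such calls are
retained (`mosaic_uncalled` or `faint` below f = 0.15); arms whose LRR
noise exceeds 0.35 are `noisy`.  Exclusion is arm-scoped
(sample × arm); both arm and sample counts can be reported.

## Filter sets

* Conservative: length ≥ 100 kb and ≥ 20 markers.  (The size rule is
  implemented as ≥, matching the tabulated "≥100 kb" reading.)
* Common: ≥ 5 markers and covering at least one probe observed deleted
  or duplicated ≥ 3 times across the cohort's calls.  Deletion and
  duplication counts are pooled by default ("deleted or duplicated"
  read as a disjunctive event count); a direction-specific mode is
  available behind a flag.
* Union = Conservative ∪ Common; Gene-centric = the union members
  overlapping ≥ 1 bp of any annotated gene (deliberately not
  exon-restricted: sparse marker maps misplace breakpoints, so an
  exonic event can be called with intronic boundaries).

The accounting report gives counts, percentages, the inclusion-
exclusion identity, and a marker-count histogram (5–9, 10–14, 15–19,
≥ 20) of calls failing both filters.

## Association

A sample carries a locus when ≥ 1 retained call overlaps it.  Loci are
marker positions (`position` mode) or ±200 kb windows around each
marker (`window` mode); adjacent loci with identical carrier sets are
collapsed, which changes nothing statistically but keeps permutation
cost proportional to the number of distinct loci.  The per-locus
statistic is the one-sided Fisher exact p for case excess
(hypergeometric tail), with the odds ratio ad/bc (∞ sentinel on a zero
denominator).  The window statistic is carrier-based; an event-count
reading of "number of CNVs within a window" is representable via the
per-sample overlap counts the engine already computes, but the carrier
test is the one wired to the permutation machinery.

Genome-wide significance is empirical max-T: B phenotype permutations
preserving group sizes, each re-scanning all loci and recording the
genome-wide minimum nominal p; a locus's empirical p is
(1 + #{min_b ≤ p_obs}) / (B + 1), bounded below by 1/(B+1).  An
exhaustive mode enumerates all case-position assignments for tiny
cohorts and is tested against brute-force enumeration.  Study-wide
correction across k analysis approaches flags empirical p strictly
below 0.05/k (0.0125 at the canonical four approaches).

Discreteness caveat: with sparse singleton carriers the exact test's
attainable p-values are few and large, and the max-T empirical p is
super-uniform (conservative).  The calibration study therefore uses
recurrent loci at 25% carrier frequency in 100-sample cohorts, where
the attainable p-range is dense; there the fraction of null replicates
with empirical p ≤ 0.05 sits inside the binomial 99% band around 0.05.

Candidate-locus replication uses the gene-overlap carrier definition
with compound-heterozygote exclusion: samples with ≥ 2 distinct calls
over the gene are removed from both margins (they already carry two
hits and are uninformative for a single-dosage-mutation risk model).

## Artifact diagnostics

**Low-MAF LOH block.**  A run of SNPs whose minor alleles ride one rare
haplotype leaves almost every sample homozygous across the run — BAF
only near 0/1 — which a BAF-aware caller can read as support for a
deletion.  `loh_check` first selects the qualifying panel: SNPs with
sample MAF < 0.05 whose pairwise composite (genotype-correlation) r²
exceeds 0.75, taking the largest connected group; composite r² stands
in for haplotype r² because phase is unavailable.  The frequency of the
all-minor haplotype is then estimated separately in deletion-call
carriers and in the rest by a two-class EM over unphased genotypes:
each chromosome is either the all-minor haplotype H (frequency h) or
some other haplotype, with residual per-SNP minor alleles off H
estimated jointly.  The artifact signature is h ≈ 0 in carriers with
zero carrier heterozygosity while the background h is clearly positive.
The diagnostic reports frequencies; it asserts no particular
significance test for the carrier/non-carrier difference.

**VNTR probe group.**  Monomorphic probes tagging a variable-number
tandem repeat track repeat length, not a deletion/duplication, and are
sensitive to DNA-source batch effects (blood vs lymphoblast cell
lines).  `vntr_check` (i) tests call-carrier status at the probe group
against DNA source (two-sided Fisher), (ii) re-calls the chromosome
with the group masked and reports the fraction of region calls lost,
and (iii) regresses per-sample mean probe LRR on true summed repeat
count when a truth panel is available.  The flag requires both a
source association (p < 0.05) and a masked-recall loss ≥ 50%.

**Validation calculators.**  qPCR: each sample quantity is divided by
the mean of the two control quantities, replicate proportions are
averaged, and the thresholds are exclusive — < 0.80 deletion, > 1.20
duplication.  MLPA: inclusive bounds, [0.8, 1.2] normal.  The bounds
differ deliberately, following each assay's stated rule.  Gel sizing
interpolates linearly between the two nearest ladder bands only (no
global standard curve) and converts to repeat units as
(size − flank)/32, reported unrounded and rounded.  `repeat_decompose`
tiles a sequence into consecutive 32-mers from an anchor, clusters
identical units, and reports variants, counts, differing positions and
any trailing partial unit.  The summed-allele comparison is an
equal-variance two-sample Student t-test.

## Synthetic cohorts

`simdata` emulates, per sample: Hardy-Weinberg genotypes at each SNP's
PFB with BAF clusters of width σ_BAF = 0.03; LRR noise of width 0.2
(optionally inflated for cell-line DNA); germline CNVs (explicit specs,
a shared case/control carrier locus, or Poisson background events)
shifting LRR to the state means and BAF to Binomial(c, PFB)/c genotype
fractions (uniform at CN 0); mosaic arms as a linear signal mixture
(LRR shift f·μ_c — an acknowledged approximation to the log-domain
mixture, monotone in f and adequate for detection) with the band
geometry above; and three artifact structures:

* sex-cross-hybridizing markers in the three observed patterns —
  complete co-hybridization (sexes in disjoint BAF clusters), a
  monomorphic probe separating the sexes in Θ only (equal mean LRR),
  and partial hybridization with sex-shifted clusters;
* a monomorphic VNTR probe group: per-allele repeat counts uniform
  within ±6 of the 28-unit reference, probe LRR =
  slope·(summed − 56)/56 + shift·1[cell line] + noise.  The source
  shift is not re-centred because array normalisation anchored to
  reference clusters does not re-centre batch offsets;
* a low-MAF LOH block of 9 strictly adjacent SNPs whose minor alleles
  ride a haplotype of frequency 0.041 by default, with residual
  off-haplotype minor alleles at 0.002 — small enough that the block's
  expected composite r², (h/(h+(1−h)ε))², stays clearly above the 0.75
  tight-LD premise while LD remains imperfect.  The PFB written to the
  marker map for the block is a config value (default 0.5, an
  uninformed prior) while the generative frequency is recorded in the
  truth set: the gap between the two is precisely the caller
  misspecification the artifact demonstrates.  The block also carries a
  configurable LRR bias (default −0.3), chosen from the emission
  arithmetic so that the block sits in the regime where the
  misspecified-PFB BAF term tips the decoder over the call threshold
  while the LRR evidence alone does not.

Randomness is a per-sample stream split from the master seed, so adding
a sample never perturbs existing ones; the seed fixes the full output
bit for bit.  With the DNA-source confound enabled (the default) every case's DNA
source is blood and every control's is a cell line.

Not emulated: GC waves, plate/batch structure beyond the DNA-source
shift, genotype-calling chemistry, real array manifests, X-chromosome
dosage.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated signal model, not robustness to
every real-data failure mode.

### Scenario sizes

The seeded studies are scaled to run comfortably on one CPU: caller
recovery uses 200 samples × 5,000 markers with ~2 background CNVs per
sample; mosaic studies use 40-sample cohorts with fraction grids
0.2–0.8 plus 400 null arms; marker-QC null calibration uses 10⁴
markers at 200 samples; permutation calibration uses 100 replicates of
B = 500 permutations.  The LOH diagnostic scenarios use haplotype
frequency 0.03 in 300-sample cohorts: at the default 0.041 the sample
MAF of a few-hundred-sample cohort exceeds the 0.05 screening cut in a
substantial fraction of draws (the binomial sd of the MAF estimate is
~0.008 at that size), voiding the scenario's low-MAF premise, and
homozygous rare-haplotype samples — which look deletion-like under any
per-marker PFB because the HMM cannot represent LD — stay rare.

## Known limitations

* No copy-neutral-LOH state: a germline homozygous stretch and a true
  deletion are distinguished only through LRR and population frequency,
  which is exactly why the low-MAF artifact exists and is diagnosable.
* The HMM treats markers as independent given the state; LD is not
  modelled, so a sample homozygous for a rare haplotype across a block
  is indistinguishable from a deletion carrier at the emission level.
* Wald-based marker QC loses power in the near-separated small-sample
  regime (Hauck–Donner); the separation sentinel covers the fully
  separated case.
* The mosaic screen is whole-arm; sub-arm mosaics dilute the mid-band
  statistics in proportion to their span.
* X-chromosome calling, trio designs and covariate-adjusted association
  models are out of scope.
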