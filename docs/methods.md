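# Methods

This note records the models, numerical choices, and design decisions
behind the package, and what the synthetic experiments do and do not show.

## Coalescent model and simulator

Demography is a set of demes with diploid effective sizes N and a
time-ordered event list: backward-in-time splits (all lineages of a
derived deme merge into an ancestral deme, optionally resetting its size)
and instantaneous size changes. Within a deme, each lineage pair coalesces
at rate 1/(2N) per generation (continuous-time approximation); time is
kept in generations and converted to years only at reporting boundaries
(2 years per generation throughout). Mutation is infinite-sites with rate
μ = 1.23 × 10⁻⁸ per site per generation by default. Recombination is not
simulated: unlinked loci stand in for independent windows, consistent with
the site-independence assumption of SFS-based inference; linkage structure
for LD tests is produced by the generator's copy-with-mutation site
chaining instead.

Model configs require explicit `ne_units` (diploid/haploid) and
`time_units` (generations/years) tags because SFS-inference tools differ
silently in both conventions; everything internal is diploid N and
generations. The published sizes are treated as diploid N_e.

Two engines share the event semantics. The Python engine returns full
genealogies (branches as leaf bitmasks) and feeds the data generator; a
numba kernel accumulates branch lengths directly into joint-SFS cells over
thousands of replicates for likelihood evaluation. Their agreement, plus
agreement with msprime on split models and with E[T₂] = 2N,
E[L] = 4N·Σ1/k, and ξ_i ∝ 1/i identities, is enforced by tests. For a
single population with piecewise-constant size the expected spectrum is
computed exactly via the lineage-count death chain (matrix exponentials
per epoch, closed form in the open-ended epoch) — no Monte Carlo error —
and this closed form doubles as the oracle for the Monte-Carlo kernel.

Diploids are formed by pairing consecutive haplotypes; with inbreeding
coefficient F an individual's two haplotypes are identical copies with
probability F. This is a pragmatic stand-in for partial selfing that
reproduces the heterozygosity deficit of homostyle demes, not a full
selfing coalescent (no correlated ancestry across loci).

## Filtering cascade

Site-level thresholds mirror common GATK hard filtering: QD > 2.0,
MQ > 40.0, FS < 60.0, MQRankSum > −12.5, ReadPosRankSum > −8.0, site depth
within [½×, 3×] of the dataset mean (the mean is an explicit argument),
InbreedingCoeff ≥ −0.99. A record missing an annotation passes that single
criterion, as in standard VCF practice for hom-only sites lacking
rank-sum annotations. Genotypes with total allelic depth < 6 or > 60 are
set missing; any site with a heterozygous call whose allele balance
AD_alt/AD_total falls outside the closed interval [0.30, 0.70] is removed
entirely (the published expression "0.30 ≤ AB ≥ 0.70" is typographically
garbled; we read "outside [0.30, 0.70] fails"). Final callsets keep
biallelic SNPs on whitelisted chromosomes with missingness strictly
below 20%. All internal coordinates are 0-based half-open; VCF (1-based)
and BED/GFF conversions happen at the format boundary.

Degeneracy annotation walks CDS codons per transcript (phase- and
strand-aware, standard nuclear code): a codon position is 4-fold when all
three substitutions are synonymous, 0-fold when none is; stop codons,
ambiguous bases, trailing sub-codon bases and positions where overlapping
transcripts disagree are "other-coding". The neutral accessibility mask
excludes gene bodies, 2,000 bp flanks, and repeat/centromere intervals.

## Diversity statistics

θ_W = S/(a_{n−1}·L) and π are reported per accessible site: windows tile
each chromosome in units of 50,000 *accessible* sites (a bp-window mode
exists for sensitivity analysis). Reading "windows of 50,000 sites" as
accessible sites makes the missing-data correction exact and windows
comparable across masks; this is a documented package choice where the
source protocol is ambiguous. Tajima's D uses the standard a₁,a₂,b₁,b₂,
c₁,c₂,e₁,e₂ constants; within windows with missing data, sites at the
modal call count form the spectrum. π computed from the SFS and from
average pairwise differences agree identically by construction and are
cross-checked on random fixtures.

LD is the squared Pearson correlation of unphased diploid dosages
(composite r²), since real genotypes are unphased. LD-decay curves exclude
singletons via maf_min = 1.5/(2n) by default — the smallest cutoff that
removes singletons at every sample size — and pruning follows the
plink-style greedy rule (windows 50 kb, step 10 kb, remove the later site
of any pair with r² > 0.1), audited against an exhaustive oracle. PCA
mean-imputes missing dosages, centers, scales, and uses a full SVD.

## Demographic inference

The composite likelihood treats polymorphic joint-SFS cells as
independent. Cells with observed count below a minimum entry (default 10)
are pooled into one lumped cell, as in the source protocol. Two
likelihood forms exist:

* multinomial (default): the SNP total is fixed; only the relative
  spectrum matters. A joint rescaling of all sizes and times then leaves
  the likelihood invariant, so at least one absolute quantity must be
  fixed externally.
* Poisson: expected cell counts are μ·L·W with W the expected branch
  lengths; the expected SNP total anchors the absolute scale. The
  recovery experiments use this form with μ and L known to the
  experiment, mirroring the way the source fixes the mutation rate and
  monitored sequence externally.

Optimization approximates the ECM-style protocol with a multi-run cyclic
coordinate search on log parameters: random starts within bounds
(log-uniform), multiplicative steps with a directional line search,
geometric step shrinkage across cycles, common random numbers within a run
(each run's Monte-Carlo likelihood surface is deterministic), and a final
cross-run comparison at a shared seed with a four-fold simulation count.
Event-ordering constraints are enforced by the model builder (invalid
parameter combinations score −∞) rather than by reparameterization.
Parametric-bootstrap CIs re-simulate from the fitted model and refit
starting near the fitted values (the initial-values protocol), reporting
empirical 2.5/97.5 percentiles.

The encoded four-population family fixes the published point values:
splits TR/Europe 79,000 y, CH/EN 65,500 y, EN1/EN6 24,000 y; CH
contraction/recovery 64,000/62,300 y; EN contraction/recovery
48,000/31,000 y; EN6 contraction 100 y; N_e(TR) = 95,627 and ancestral
N_e = 13,419. Sizes the source does not print (current CH/EN1/EN6,
bottleneck and pre-contraction sizes, the CH–EN ancestor) are package
choices of plausible magnitude, declining westward, and are declared in
`MODEL5_UNPUBLISHED`. In the recovery experiment the five printed
parameters are free; bottleneck/recovery times ride along as fixed
fractions of their lineage's split time so ordering is preserved
everywhere in the search region, and the unprinted sizes stay fixed —
at desk scale (~10,000 SNPs, 8 haploid genomes per deme, thousands of
simulations per evaluation instead of 200,000) freeing all nuisance sizes
would mostly add variance without informing the printed quantities. Two
simplified alternates (no bottlenecks; single EN bottleneck) complete a
testable AIC family; the full six-model set of the source lives in
supplementary material that prints no parameter values, so the alternates
are labeled stand-ins.

The multi-epoch single-population fit (the stand-in for the model-free
stairway analysis) maximizes the same lumped composite likelihood over
piecewise-constant histories using the exact death-chain spectrum, with
Nelder-Mead on log sizes/durations and AIC over k = 1..4 epochs. Because
the relative 1D spectrum identifies only shape functionals (size ratios,
durations in coalescent units), the CI-calibration experiment measures
coverage of the recent/ancient size ratio.

## DFE estimation

The sojourn density of a new semidominant deleterious mutation with
γ = 4N_e·s is H(γ,x) = 2(e^{γ(1−x)}−1)/((e^{γ}−1)·x(1−x)), the
negative-selection branch of the standard diffusion result; the expected
unfolded spectrum is E[ξ_i] = (θ/2)∫ H(γ,x)·C(n,i)xⁱ(1−x)^{n−i} dx,
evaluated by 400-node Gauss–Legendre quadrature with expm1-stable
arithmetic (continuous at γ = 0, neutral limit θ/i; for large γ the mass
collapses onto singletons). A small-population Wright–Fisher
transition-matrix oracle (haploid size M, fitness 1−s, γ = 2Ms) validates
the spectrum to the O(1/M) discretization. The gamma DFE over N_e·s
(shape β, mean) is integrated by 200-point quantile discretization;
reported bin masses are exact gamma CDF differences over [0,1), [1,10),
[10,100), [100,∞).

Fitting is two-stage: distortion factors r_i = ξ_i^neutral/(θ̂/i) absorb
demography and ascertainment (empty classes get r_i = 1 with a warning),
then (β, mean) maximize the Poisson likelihood of the selected spectrum
with expectation θ_sel·r_i·Ē_i. The mass at N_e·s ≥ 100 is carried
almost entirely by the *deficit* of selected SNPs relative to mutational
opportunity — mutations that never segregate leave no SFS shape signal —
so θ_sel should be tied to the neutral rate through the
`mutational_target_ratio` (selected/neutral mutational opportunity, known
in all synthetic experiments and computable from site counts in real
data). Without it θ_sel is profiled and the strongest bin is only weakly
identified. The bootstrap resamples the selected spectrum multinomially
(neutral fixed) and refits. Scaled selection is γ = 4N_e·s internally;
bins are labeled in N_e·s (= γ/4), and bin edges are configurable because
tools differ in the 2N_e·s vs 4N_e·s convention.

## TE content statistic

Input is a per-individual × superfamily table of mean TE-consensus depth,
genome-wide depth, and consensus coverage (depth computation from BAMs is
out of scope; the generator and a trivial TSV schema stand in). Normalized
content = TE depth / genome depth, which is invariant to sequencing
effort. The ≥ 80% coverage filter is applied per superfamily on the mean
coverage across individuals (the source does not define the denominator;
threshold and reading are configurable and logged). The "Gaussian GLM" is
ordinary least squares on norm_depth ~ population * superfamily with
treatment coding; the reference population is a parameter (TR-D for the
expansion contrast, EN1-D for the homostyly contrast), and releveling is
verified to leave fitted values unchanged. Pairwise Wilcoxon rank-sum
tests against the reference are Bonferroni-corrected over the populations
actually compared (logged per superfamily).

## Synthetic-data generator

The default design mirrors the study layout: nine demes east to west
(TR-D, SK-D, CH-D, EN1-D, EN2-D, EN3-D, EN4-T, EN5-T, EN6-M), 105
diploids (12 per deme, 9 in EN6-M), 11 chromosomes. Each western deme is
founded by a split from its eastern neighbour with a founder bottleneck
(size 300 for 200 generations), split times 8,000 → 1,000 generations ago,
current sizes declining 12,000 → 1,500: scaled-down sizes in the thousands
keep full-pipeline runs fast while preserving the east-to-west diversity
and LD gradients the analysis tests for. Inbreeding F is 0.45 in
trimorphic and 0.90 in monomorphic demes (free knobs: the source cites no
usable selfing-rate estimates). Genes (3 kb single-exon CDS every 15 kb,
alternating strand) define 0-fold/4-fold sites by reading frame; 0-fold
variants are thinned with probability proportional to H(γ,x)/H(0,x) with
γ drawn from the gamma DFE (shape 0.3, mean N_e·s 300), imprinting
purifying selection on the selected spectrum. A central 10% block per
chromosome acts as the repeat/centromere mask. VCF quality annotations
(QD, MQ, FS, rank sums, DP, InbreedingCoeff, per-genotype AD) are drawn
from simple calibrated distributions solely to exercise the filter
cascade — they carry no read-level realism, so passing filters here says
nothing about behaviour on pathological real alignments. TE tables are
Gaussian around population × superfamily means with injectable effects.
The truth record (JSON) stores every generating parameter.

What the synthetic experiments show: estimator identities, calibration
under the package's own model assumptions, and end-to-end parameter
recovery at reduced scale. What they do not show: robustness to real
read-level artifacts, reference bias in polarization (the
reference-equals-ancestral convention conflates reference and ancestral
state wherever the outgroup carries the derived allele), linked selection,
or a mechanistically correct selfing coalescent.

## Problem sizes and numerical settings

Recovery and calibration experiments run at desk scale as a package
choice: joint-SFS fits use ~10,000 SNPs, 8 haploid genomes per deme,
3,000 coalescent simulations per likelihood evaluation, 12–14 runs × 12
cycles; DFE recovery uses spectra of ~10⁵ selected SNPs at n = 20; the
CI-calibration experiment uses 20 datasets × 50 bootstraps at S = 3,000.
Likelihood floors (p ≥ 1e−300), the minimum-entry lump (10), quadrature
node counts (400 in x, 200 in γ), and optimizer steps (initial factor
1.6, shrink 0.88, floor 0.01 on the log scale) are all explicit arguments.
Known limitations: no recombination in the simulator, no positive
selection or divergence-based α in the DFE, no F_ST/haplotype scans, and
the six-model demographic family is representative rather than complete.
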