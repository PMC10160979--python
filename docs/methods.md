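# Methods

This note documents the models and procedures implemented in `rohload`, the
assumptions behind them, the numerical choices, and what the synthetic-data
validation does and does not establish.

## Genotype representation and site filters

Genotypes are dense int8 codes (0 = hom-ref, 1 = het, 2 = hom-alt, −1 =
missing) over a coordinate-sorted biallelic SNP table; coordinates are
1-based inclusive internally and 0-based half-open only in BED output. The
hard site filters (QUAL ≥ 30; mean depth in [5, 20]; call rate ≥ 0.95; minor
allele count ≥ 1, computed over non-missing genotypes only; autosome
allowlist) are conjunctive, so the retained set is independent of evaluation
order; the removal report attributes each dropped site to the first failing
criterion in a fixed order (qual, depth, call rate, MAC, chromosome) purely
for deterministic reporting. Per-site mean depth prefers the across-sample
mean of FORMAT `DP`; our own VCF writer additionally stores it losslessly in
INFO `MDP` while emitting a conventional integer INFO `DP` total.

## ROH calling

The caller reproduces the PLINK `--homozyg` window heuristic in SNP-index
space: a window of `window_snp` = 50 consecutive SNPs is "homozygous" when it
holds ≤ 3 heterozygous and ≤ 5 missing calls; each SNP's hit fraction is the
proportion of homozygous windows among those covering it, and the SNP is
eligible at threshold 0.05 (the tool default inherited by unmodified command
lines). Maximal runs of eligible SNPs are split where consecutive SNPs are
> 1 Mb apart and emitted if they hold ≥ 50 SNPs, span ≥ 500 kb and stay under
50 kb/SNP. Two defined-behavior choices where the reference tool is
version-dependent or undefined at toy scale: chromosomes with fewer SNPs than
one window are scanned with a single window spanning all SNPs, and no
segment-level heterozygote cap is applied (the corresponding option is
unlimited by default). Segment length is `end_bp − start_bp + 1` over the
first/last SNP of the run. Correctness is pinned by exact equivalence with a
brute-force oracle (direct enumeration of every window, hit fraction, run
assembly and constraint check) on 1,000 random instances.

`F_ROH` is the summed segment length over the autosomal genome length
(default 2.44 Gb, configurable).

## Length classes and Nₑ

Under a uniform map of 1 cM/Mb (physical length used for genetic length —
appropriate when no linkage map exists), the expected length of a tract whose
haplotypes coalesce *g* generations ago is `L = 100/(2g)` Mb. Dyadic windows
(1,2] … (64,128] generations give the class bounds 25, 12.5, 6.25, 3.125,
1.5625, 0.78125 and 0.390625 Mb. Classes are half-open `[lower, upper)` with
the youngest class `[25, ∞)`, so every segment ≥ 0.390625 Mb is assigned
exactly once; the smallest class is truncated in practice by the 500 kb
calling floor (documented, not corrected — shorter segments are counted in a
report). Per population and window the mean per-individual class fraction
`F_ROH,t` is inverted through

  F_ROH,t = 1 − (1 − 1/(2Nₑ))^t,  Nₑ = 1 / (2(1 − (1 − F)^(1/t))),

with *t* the window's upper bound. `F = 0` returns a `+inf` sentinel with a
warning (no inbreeding observed in that window bounds Nₑ only from below);
`F ≥ 1` is an error. CIs are a percentile bootstrap (2.5/97.5, nearest-rank so
infinite replicates are handled exactly) over individuals resampled within
each population, 100 replicates by default; the point estimate uses the
unresampled mean.

Interpretation caveats, verified analytically and by simulation during
development:

* The expression is a cumulative-inbreeding form applied to per-class
  (non-cumulative) fractions, exactly as the procedure is defined. For dyadic
  windows this is internally consistent: under a *constant* size N the class
  mass integrates to ≈ (g_high − g_low)/N across all coalescence times, and
  the inversion returns ≈ N (our recovery experiment: N = 150 constant,
  (8,16] class, mean estimate ≈ 107–130 across seeds after ROH calling, within
  ±30%).
* The length-class kernel is wide: most of a class's mass comes from
  coalescences *outside* its nominal window. A sharp one-window size change
  (e.g. 150 diploids only 8–16 generations ago against a background of 1,000)
  is therefore smeared toward the background value (analytically ≈ 580 for
  that scenario; the acceptance script reports the simulated value as a
  diagnostic). The estimator tracks smooth trajectories, not step changes.
* ROH calling itself biases class masses upward (window-edge extension into
  homozygous-by-state flanks, merging across short gaps), inflating F_ROH,t
  and deflating Nₑ. The effect shrinks with SNP density; the recovery
  experiment therefore uses a WGS-scale panel (4×10⁻³ SNPs/bp before
  filtering) and runs the full filter chain first, since the MAC ≥ 1 filter
  removes sample-monomorphic sites and is part of the procedure the estimator
  is defined on.

## Polarization

The outgroup consensus is consumed as a FASTA aligned to the same
coordinates; its construction from outgroup reads is out of scope. Rules per
SNP: consensus base absent/`N`/ambiguity code → drop; equal to neither
allele → drop; equal to alt → rotate (swap ref/alt, flip homozygote codes;
heterozygous and missing calls are orientation-free). Soft-masked bases are
uppercased; IUPAC ambiguity codes are treated as `N` because a majority-base
consensus that reports ambiguity is unusable at that site. Rotation conserves
allele counts (derived frequency = 1 − previous alt frequency at rotated
sites), and polarizing an already-polarized dataset is the identity; both are
asserted as properties.

## Mutation load, π, Rxy, contrasts

Loads require a polarized dataset (alt = derived) and exclude missing
genotypes: heterozygous load = #het (masked load under recessivity),
homozygous load = #derived homozygotes (expressed load), total derived
= 2·hom + het (additive load; the identity is asserted globally).
Heterozygotes are counted at all retained annotated sites, not only at sites
polymorphic within the focal population; output metadata records this choice.
Fixed-allele attribution marks a site fixed within a population when every
non-missing genotype there is derived-homozygous; 0/0 percentages are
reported as 0 with a flag.

Nucleotide diversity uses the genotype-based estimator
`π_site = 2d(n−d)/(n(n−1))` (n non-missing alleles, d derived), summed and
divided by a supplied callable-site count when available, else by the number
of usable sites (flagged `polymorphic_only`). It is labelled an
*approximation*: it assumes called genotypes rather than genotype
likelihoods, so at low coverage it inherits genotype-calling bias. The
estimator is symmetric in d ↔ n−d, hence orientation-invariant.

Rxy uses the frequency-product form
`L_{X∉Y}(S) = Σᵢ fᵢˣ(1−fᵢʸ)` with per-group frequencies over non-missing
alleles, standardized by the intergenic site set; swapping groups maps the
statistic to its exact reciprocal (asserted). Bootstrap CIs resample the
focal-class and intergenic site sets independently with replacement (100
replicates by default); a replicate whose resample carries no exclusive
derived alleles yields 0/∞ as the ratio limits dictate (NaN-dropping only
when the neutral term vanishes), while a zero term in the *point* estimate is
an error with a diagnostic. Management contrasts are plain OLS on a 0/1
indicator (UNMANAGED = 0) with t-based CIs — deliberately the simple linear
model even for count responses, matching how such contrasts are convention-
ally reported; zero-residual fits are flagged degenerate instead of inventing
a p-value.

## Synthetic data

`simulate_population` runs a forward diploid Wright–Fisher simulation over a
piecewise-constant size trajectory (oldest block first; sampling from the
final generation). Haplotypes are lists of founder segments, so autozygosity
— both haplotypes descending from the same founder haplotype — is read off
exactly and emitted as truth tracts; adjacent tracts tracing to different
founders merge, as a caller would see them. Recombination is Poisson with
uniform crossover placement (default 1e-8/bp/generation = 1 cM/Mb).
All polymorphism is founder standing variation: per-site derived frequencies
are drawn from class-specific Beta spectra (defaults: LoF mean 0.05 <
missense 0.15 < intergenic/other 0.30), and founder haplotypes draw alleles
independently at those frequencies. Multiple populations share the same
founder frequency pool (allowing "shared founders, divergent management"
designs) but evolve independently; a founder-duplication knob can add
baseline relatedness. Post-founding mutation is omitted — on the ≤ 128-
generation timescales relevant to ROH length classes its contribution to
tract structure is negligible, but the simulator is therefore *not* suitable
for mutation-rate-sensitive quantities.

Default SNP density is 1×10⁻³/bp, the same order as filtered mammalian WGS
panels scaled to desk size; QUAL and depth are uniform draws within passing
ranges, with configurable fractions of sites violating each filter so the
filter stage has real work; genotype and site-level missingness are
configurable. The consensus "ancestral" sequence is the founder-pool major
allele per site (so sites with derived frequency > ½ genuinely require
rotation), stored sparsely for large genomes; `perturb_ancestral` injects
exact, ledgered fractions of `N` and both-allele-mismatch defects (counts are
floored). `paint_roh` builds fully deterministic ROH fixtures: homozygous
intervals painted onto a heterozygous background, truth = the layout
verbatim.

What passing the synthetic suite shows: the window caller implements its
specification exactly; the estimator chain recovers known simulated
quantities under the stated conditions; every bookkeeping identity holds.
What it does not show: robustness to genotyping error models, linkage-map
heterogeneity, reference bias, population structure within groups, or
selection during the simulated epoch — none of which the generator emulates.

## Problem sizes and determinism

Test and acceptance experiments use genomes of 60–200 Mb across 4–10
chromosomes, 25–30 sampled individuals and up to 128 simulated generations —
sizes chosen so the full suite and the acceptance script each complete in
minutes on one CPU while keeping per-class ROH counts informative. Every
stochastic component takes an explicit seed; the pipeline fans a single
global seed out to stages via a fixed counter scheme recorded in each stage
manifest, and identical configuration + seed reproduces every output
bit-for-bit.
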