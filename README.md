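# rohload

Runs-of-homozygosity (ROH), ROH-based demographic inference, and mutation-load
analysis for conservation genomics — with a fully specified synthetic-data
generator so the whole chain can be validated against known ground truth.

The package is aimed at population/conservation geneticists comparing
inbreeding and deleterious variation between groups of individuals (for
example, captive populations under contrasting management regimes) from a
jointly genotyped SNP panel.

## What it computes

Starting from a multi-sample VCF of biallelic SNPs, a sample→population→
management table, an outgroup-consensus FASTA and a site impact-class
annotation table:

1. **Site filtering** — hard filters: QUAL ≥ 30, per-site mean depth within
   [5, 20], genotyping rate ≥ 95%, minor allele count ≥ 1, autosome allowlist.
2. **Polarization** — each SNP is oriented to ancestral/derived against the
   outgroup consensus: sites absent from the consensus (or `N`) are dropped;
   sites where the consensus matches neither allele are dropped; where it
   matches the alternate allele, ref/alt are rotated so that *alt = derived*.
3. **ROH calling** — PLINK-`--homozyg`-style sliding window (50-SNP windows,
   ≤ 3 heterozygotes, ≤ 5 missing per window, 5% hit-fraction threshold), with
   minimum segment size 500 kb / 50 SNPs, 1 Mb maximum gap and 50 kb/SNP
   maximum density. Per individual, `F_ROH = Σ ROH length / L_auto` with
   `L_auto` = 2.44 Gb by default.
4. **Demography** — ROH are binned into seven length classes derived from
   `L = 100 / (2g)` Mb (expected tract length for coalescence *g* generations
   ago at 1 cM/Mb): ≥ 25, 12.5–25, …, 0.39–0.78 Mb, mapping to time windows
   (1,2], (2,4], …, (64,128] generations. Per population and window,
   `F_ROH,t = 1 − (1 − 1/(2Nₑ))^t` is inverted at *t* = the window's upper
   bound, giving an Nₑ trajectory with percentile-bootstrap CIs over
   individuals.
5. **Mutation load** — per individual and impact class (LoF, missense,
   intergenic): heterozygous load (count of heterozygotes), homozygous load
   (count of derived homozygotes), and total derived alleles
   (= 2·hom + het); attribution of homozygous load to alleles fixed within
   each population; genotype-based nucleotide diversity
   `π_site = 2d(n−d)/(n(n−1))`.
6. **Rxy** — relative derived-allele burden of a class in group X over group
   Y, standardized by intergenic SNPs:
   `Rxy = [L_{X∉Y}(class)/L_{X∉Y}(intergenic)] / [L_{Y∉X}(class)/L_{Y∉X}(intergenic)]`
   with `L_{X∉Y}(S) = Σᵢ fᵢˣ(1−fᵢʸ)`, and a percentile bootstrap over sites.
7. **Group contrasts** — OLS of any per-individual response on a binary
   management indicator (UNMANAGED = 0, MANAGED = 1) with t-based 95% CIs.

The synthetic-data module (`rohload.synthetic`) generates all of these inputs
from a forward Wright–Fisher simulation with founder-segment haplotype
tracking, so true autozygous tracts, true ancestral states and the true Nₑ
trajectory are known exactly.

## Worked example

```python
import numpy as np
from rohload import (SimConfig, simulate_population, apply_site_filters,
                     FilterConfig, polarize, call_roh, ROHConfig, compute_froh,
                     froh_by_class, LengthClassSpec, estimate_ne,
                     compute_loads, group_contrast)

cfg = SimConfig(
    chromosome_lengths=(15_000_000,) * 4,
    ne_trajectory=((40, 400),),                       # 40 generations at N=400
    population_trajectories={"UNMGD": ((30, 400), (10, 15))},  # recent crash
    n_sample_per_population={"UNMGD": 15, "MGD": 15},
    population_management={"UNMGD": "UNMANAGED", "MGD": "MANAGED"},
    seed=20020,
)
dataset, ancestral, truth = simulate_population(cfg)
filtered, report = apply_site_filters(dataset, FilterConfig())
polarized, _ = polarize(filtered, ancestral)

segments = call_roh(polarized, ROHConfig())
genome = sum(cfg.chromosome_lengths)
froh = compute_froh(segments, genome, sample_ids=polarized.sample_ids)
mgmt = polarized.samples["management"]
print("mean F_ROH managed   :", round(froh["froh"][(mgmt == "MANAGED").to_numpy()].mean(), 3))
print("mean F_ROH unmanaged :", round(froh["froh"][(mgmt == "UNMANAGED").to_numpy()].mean(), 3))
beta = group_contrast(froh["froh"], mgmt, response="froh")
print("management effect on F_ROH: beta =", round(beta.beta, 3))
```

prints (seed 20020):

```
mean F_ROH managed   : 0.044
mean F_ROH unmanaged : 0.245
management effect on F_ROH: beta = -0.202
```

i.e. the genome fraction in ROH is ~20 percentage points lower in the managed
group — the managed/unmanaged inbreeding contrast the pipeline is built to
quantify. Continuing with `froh_by_class` + `estimate_ne` turns the same
segments into a per-window Nₑ trajectory, and `compute_loads` yields the
heterozygous/homozygous/total-derived load table for the management contrast.

The same pipeline is available from the shell:

```bash
rohload all --config pipeline.yaml     # simulate → filter → polarize → roh →
                                       # demography → load → rxy, with manifests
rohload roh --vcf polarized.vcf --samples samples.tsv --out roh.bed \
            --froh-out froh.tsv --genome-length 2440000000
```

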