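"""Synthetic genotype data with known ground truth.

A forward-in-time diploid Wright–Fisher simulator over a piecewise-constant
population-size trajectory. Haplotypes are tracked as lists of founder
segments (breakpoint arrays), so autozygous tracts — intervals where an
individual's two haplotypes descend from the same founder haplotype — are
read off exactly and emitted as truth. All polymorphism is founder standing
variation: each site is assigned an impact class and a founder derived-allele
frequency drawn from a class-specific Beta spectrum (loss-of-function rarer
than missense rarer than intergenic by default), and founder haplotypes draw
alleles independently at that frequency. New mutation after founding is
omitted; on the tens-of-generations timescale relevant to ROH structure its
contribution is negligible.

Recombination is uniform at a configurable rate (default 1e-8 crossovers/bp/
generation, i.e. 1 cM/Mb): each gamete receives Poisson(rate x length)
crossovers at uniform positions per chromosome.

Per-site QUAL and depth fields are drawn from configured ranges, with
configurable fractions of sites violating each hard filter, so the filter
stage has realistic work. The outgroup-consensus ("ancestral") sequence is
the founder-pool major allele at each SNP and can be perturbed with missing
(N) and both-allele-mismatch defects, returning an exact ledger of perturbed
positions for downstream cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polarize import AncestralFasta
from .roh import ROHSegment
from .variant_io import HET, MISSING, GenotypeDataset

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

DEFAULT_CLASS_FRACTIONS = {"LOF": 0.02, "MISSENSE": 0.15, "INTERGENIC": 0.60, "OTHER": 0.23}
# Beta(a, b) parameters of the founder derived-allele frequency per class;
# means 0.05 (LoF) < 0.15 (missense) < 0.30 (intergenic/other).
DEFAULT_CLASS_SPECTRA = {
    "LOF": (0.25, 4.75),
    "MISSENSE": (0.45, 2.55),
    "INTERGENIC": (0.9, 2.1),
    "OTHER": (0.9, 2.1),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``ne_trajectory`` is ordered oldest-to-newest: the simulation founds the
    population at the first entry's size and runs forward through each
    (generation_span, diploid_size) block; sampling happens in the final
    generation. Populations listed in ``n_sample_per_population`` are
    simulated as independent Wright–Fisher replicates sharing the same
    per-site founder allele-frequency pool (``population_trajectories`` can
    override the trajectory per population, e.g. to bottleneck one group).
    """

    chromosome_lengths: tuple = (25_000_000, 25_000_000)
    snp_density: float = 1e-3  # ~1 SNP/kb, same order as dense mammalian WGS panels
    ne_trajectory: tuple = ((50, 500),)
    n_sample_per_population: dict = field(default_factory=lambda: {"POP1": 25})
    population_trajectories: dict = field(default_factory=dict)
    population_management: dict = field(default_factory=dict)
    recombination_rate: float = 1e-8
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    class_maf_spectra: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SPECTRA))
    qual_range: tuple = (30.0, 60.0)
    depth_range: tuple = (6.0, 18.0)
    frac_low_qual: float = 0.02
    frac_bad_depth: float = 0.02
    frac_high_missing: float = 0.01
    base_missing_rate: float = 0.002
    founder_duplication: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        for traj in [self.ne_trajectory, *self.population_trajectories.values()]:
            for span, size in traj:
                if size < 2:
                    raise ValueError("trajectory sizes must be >= 2 (need two parents)")
                if span < 1:
                    raise ValueError("trajectory spans must be >= 1")

    def trajectory_for(self, pop: str) -> tuple:
        return tuple(self.population_trajectories.get(pop, self.ne_trajectory))


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated cohort."""

    true_roh: list                      # ROHSegment per sampled individual
    true_ancestral: np.ndarray          # S1 base per retained site
    true_ne: dict                       # population -> trajectory used
    ledger: dict = field(default_factory=dict)  # e.g. ancestral perturbations


# ---------------------------------------------------------------------------
# haplotype machinery: a haplotype on one chromosome is (breaks, ids) where
# breaks are segment end positions (bp, ascending, last == chrom length) and
# ids the founder-haplotype id of each segment.
# ---------------------------------------------------------------------------

def _recombine(hap_a, hap_b, length, rate, rng):
    """One gamete from a parent's two haplotypes on one chromosome."""
    k = rng.poisson(rate * length)
    start_with = rng.integers(2)
    if k == 0:
        breaks, ids = (hap_a if start_with == 0 else hap_b)
        return breaks.copy(), ids.copy()
    cuts = np.sort(rng.integers(1, length, size=k)).astype(np.int64)
    haps = (hap_a, hap_b) if start_with == 0 else (hap_b, hap_a)
    out_breaks: list = []
    out_ids: list = []
    prev = 0
    bounds = np.concatenate([cuts, [length]])
    for phase, bound in enumerate(bounds):
        if bound <= prev:
            continue
        breaks, ids = haps[phase % 2]
        i = np.searchsorted(breaks, prev, side="right")
        while prev < bound:
            seg_end = min(int(breaks[i]), int(bound))
            if out_ids and out_ids[-1] == ids[i]:
                out_breaks[-1] = seg_end
            else:
                out_breaks.append(seg_end)
                out_ids.append(int(ids[i]))
            prev = seg_end
            if seg_end == breaks[i]:
                i += 1
        prev = int(bound)
    return np.array(out_breaks, dtype=np.int64), np.array(out_ids, dtype=np.int64)


def _wright_fisher(trajectory, chrom_lengths, rate, rng, founder_duplication=0.0,
                   first_founder_id=0):
    """Run the trajectory forward; return final-generation individuals as
    [(hap1, hap2)] with hap = tuple over chromosomes of (breaks, ids), plus
    the number of founder haplotype ids consumed."""
    n0 = trajectory[0][1]
    next_id = first_founder_id
    founders = []
    created: list = []
    for _ in range(2 * n0):
        if created and rng.random() < founder_duplication:
            fid = created[rng.integers(len(created))]
        else:
            fid = next_id
            next_id += 1
            created.append(fid)
        founders.append(fid)
    pop = []
    for ind in range(n0):
        haps = []
        for which in range(2):
            fid = founders[2 * ind + which]
            haps.append(tuple(
                (np.array([L], dtype=np.int64), np.array([fid], dtype=np.int64))
                for L in chrom_lengths
            ))
        pop.append((haps[0], haps[1]))
    # founder generation counts as the first generation of the first block
    blocks = list(trajectory)
    spans = [(span - 1 if bi == 0 else span, size) for bi, (span, size) in enumerate(blocks)]
    for span, size in spans:
        for _ in range(span):
            parents = rng.integers(len(pop), size=(size, 2))
            new_pop = []
            for pa, pb in parents:
                gametes = []
                for parent in (pop[pa], pop[pb]):
                    gametes.append(tuple(
                        _recombine(parent[0][c], parent[1][c], chrom_lengths[c], rate, rng)
                        for c in range(len(chrom_lengths))
                    ))
                new_pop.append((gametes[0], gametes[1]))
            pop = new_pop
    return pop, next_id


def _autozygous_tracts(hap1, hap2, length):
    """Intervals (start_bp, end_bp), 1-based inclusive, where the two
    haplotypes carry the same founder id."""
    b1, i1 = hap1
    b2, i2 = hap2
    tracts = []
    prev = 0
    a = b = 0
    cur_start = None
    while prev < length:
        end = min(int(b1[a]), int(b2[b]))
        same = i1[a] == i2[b]
        if same and cur_start is None:
            cur_start = prev
        if not same and cur_start is not None:
            tracts.append((cur_start + 1, prev))
            cur_start = None
        prev = end
        if b1[a] == end:
            a += 1
        if b2[b] == end:
            b += 1
    if cur_start is not None:
        tracts.append((cur_start + 1, length))
    return tracts


def simulate_population(cfg: SimConfig) -> tuple[GenotypeDataset, AncestralFasta, TruthSet]:
    """Simulate a multi-population diploid cohort with known autozygosity.

    Returns the genotype dataset (QUAL/depth/impact-class metadata filled,
    including deliberately filter-violating sites), the outgroup-consensus
    sequence (sparse backing, founder-pool major allele at every SNP), and
    the :class:`TruthSet` (exact autozygous tracts, ancestral bases, input
    trajectories).
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(len(cfg.chromosome_lengths))]
    contig_lengths = dict(zip(chroms, cfg.chromosome_lengths))

    # --- sites ------------------------------------------------------------
    pos_per_chrom = {}
    for c, L in contig_lengths.items():
        n = int(round(L * cfg.snp_density))
        raw = rng.integers(1, L + 1, size=int(n * 1.3) + 8)
        uniq = np.unique(raw)
        if uniq.size > n:  # thin uniformly, never positionally
            uniq = rng.choice(uniq, size=n, replace=False)
        pos_per_chrom[c] = np.sort(uniq)
    chrom_col = np.concatenate([[c] * len(pos_per_chrom[c]) for c in chroms])
    pos_col = np.concatenate([pos_per_chrom[c] for c in chroms])
    n_sites = pos_col.size

    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[k] for k in classes])
    site_class = rng.choice(classes, size=n_sites, p=probs / probs.sum())
    founder_freq = np.empty(n_sites)
    for k in classes:
        a, b = cfg.class_maf_spectra[k]
        m = site_class == k
        founder_freq[m] = rng.beta(a, b, size=int(m.sum()))

    ref_idx = rng.integers(4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    # --- populations --------------------------------------------------------
    pops = list(cfg.n_sample_per_population)
    samples_rows = []
    geno_blocks = []
    true_roh: list = []
    true_ne = {}

    default_mgmt = {p: ("MANAGED" if i % 2 == 0 else "UNMANAGED") for i, p in enumerate(pops)}
    for pop in pops:
        traj = cfg.trajectory_for(pop)
        true_ne[pop] = traj
        final, _ = _wright_fisher(
            traj, cfg.chromosome_lengths, cfg.recombination_rate, rng,
            founder_duplication=cfg.founder_duplication,
        )
        n_take = cfg.n_sample_per_population[pop]
        if n_take > len(final):
            raise ValueError(f"cannot sample {n_take} from final size {len(final)} in {pop}")
        take = rng.choice(len(final), size=n_take, replace=False)
        sampled = [final[i] for i in take]
        del final
        # founder alleles are iid Bernoulli(freq) per founder haplotype; only
        # haplotypes surviving into the sample ever need alleles drawn
        needed: list = []
        seen: dict = {}
        for hap1, hap2 in sampled:
            for hap in (hap1, hap2):
                for _, ids in hap:
                    for fid in ids:
                        if int(fid) not in seen:
                            seen[int(fid)] = len(needed)
                            needed.append(int(fid))
        founder_alleles = (rng.random((len(needed), n_sites)) < founder_freq).astype(np.int8)
        mgmt = cfg.population_management.get(pop, default_mgmt[pop])
        for j, (hap1, hap2) in enumerate(sampled):
            sid = f"{pop}_{j:03d}"
            samples_rows.append((sid, pop, mgmt))
            geno = np.empty(n_sites, dtype=np.int8)
            off = 0
            for c_i, c in enumerate(chroms):
                p = pos_per_chrom[c]
                cols = np.arange(off, off + p.size)
                rows1 = np.array([seen[int(f)] for f in
                                  hap1[c_i][1][np.searchsorted(hap1[c_i][0], p - 1, side="right")]])
                rows2 = np.array([seen[int(f)] for f in
                                  hap2[c_i][1][np.searchsorted(hap2[c_i][0], p - 1, side="right")]])
                geno[cols] = founder_alleles[rows1, cols] + founder_alleles[rows2, cols]
                for start, end in _autozygous_tracts(hap1[c_i], hap2[c_i], contig_lengths[c]):
                    inside = p[(p >= start) & (p <= end)]
                    true_roh.append(ROHSegment(
                        sample_id=sid, chromosome=c, start_bp=start, end_bp=end,
                        n_snps=int(inside.size), n_het=0, n_missing=0,
                    ))
                off += p.size
            geno_blocks.append(geno)

    genotypes = np.stack(geno_blocks) if geno_blocks else np.zeros((0, n_sites), dtype=np.int8)

    # --- genotype missingness ----------------------------------------------
    n_samples = genotypes.shape[0]
    if n_samples and cfg.base_missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.base_missing_rate
        genotypes[miss] = MISSING
    if n_samples and cfg.frac_high_missing > 0:
        n_bad = int(n_sites * cfg.frac_high_missing)
        bad_sites = rng.choice(n_sites, size=n_bad, replace=False)
        for s in bad_sites:
            k = max(1, int(np.ceil(n_samples * 0.1)))
            rows = rng.choice(n_samples, size=k, replace=False)
            genotypes[rows, s] = MISSING

    # --- QUAL / depth --------------------------------------------------------
    qual = rng.uniform(*cfg.qual_range, size=n_sites)
    lowq = rng.random(n_sites) < cfg.frac_low_qual
    qual[lowq] = rng.uniform(5.0, 29.5, size=int(lowq.sum()))
    depth = rng.uniform(*cfg.depth_range, size=n_sites)
    badd = rng.random(n_sites) < cfg.frac_bad_depth
    half = rng.random(int(badd.sum())) < 0.5
    bd = np.flatnonzero(badd)
    depth[bd[half]] = rng.uniform(0.5, 4.5, size=int(half.sum()))
    depth[bd[~half]] = rng.uniform(21.0, 40.0, size=int((~half).sum()))

    # --- ancestral = founder-pool major allele ------------------------------
    # the consensus converges to the majority allele of the founder pool,
    # i.e. alt exactly where the founder derived frequency exceeds 1/2
    anc_is_alt = founder_freq > 0.5
    anc_base = np.where(anc_is_alt, alt, ref)
    anc = AncestralFasta.from_sparse(
        contig_lengths,
        {c: pos_per_chrom[c] for c in chroms},
        {c: anc_base[chrom_col == c] for c in chroms},
    )

    sites = pd.DataFrame({
        "chrom": chrom_col,
        "pos": pos_col.astype(np.int64),
        "ref": ref.astype("U1"),
        "alt": alt.astype("U1"),
        "qual": qual,
        "mean_depth": depth,
        "impact_class": site_class,
        "polarized": False,
    })
    samples = pd.DataFrame(samples_rows, columns=["sample_id", "population_id", "management"])
    dataset = GenotypeDataset(sites, samples, genotypes, contig_lengths=contig_lengths)
    truth = TruthSet(true_roh=true_roh, true_ancestral=anc_base, true_ne=true_ne)
    return dataset, anc, truth


# ---------------------------------------------------------------------------
# deterministic ROH paint fixture
# ---------------------------------------------------------------------------

def paint_roh(layout, snp_positions: dict, background_het_rate: float, seed: int = 0,
              chromosome_lengths: dict | None = None) -> tuple[GenotypeDataset, TruthSet]:
    """Paint explicit homozygous intervals onto a heterozygous background.

    ``layout``: iterable of (sample_id, chrom, start_bp, end_bp), 1-based
    inclusive, disjoint per sample. Inside painted intervals genotypes are
    homozygous (HOM_REF/HOM_ALT, never HET); outside, each SNP is HET with
    probability ``background_het_rate``, else homozygous. Truth is the layout
    verbatim.
    """
    if not 0.0 <= background_het_rate <= 1.0:
        raise ValueError("background_het_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = list(snp_positions)
    contig_lengths = dict(chromosome_lengths) if chromosome_lengths else {
        c: int(np.max(snp_positions[c])) for c in chroms
    }
    layout = [tuple(iv) for iv in layout]
    by_sample: dict = {}
    for sid, chrom, start, end in layout:
        if chrom not in contig_lengths:
            raise KeyError(f"unknown chromosome {chrom!r} in layout")
        if not 1 <= start <= end <= contig_lengths[chrom]:
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome bounds")
        by_sample.setdefault(sid, []).append((chrom, start, end))
    for sid, ivs in by_sample.items():
        ivs = sorted(ivs)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 <= e1:
                raise ValueError(f"overlapping painted intervals for sample {sid}")

    chrom_col = np.concatenate([[c] * len(snp_positions[c]) for c in chroms])
    pos_col = np.concatenate([np.sort(np.asarray(snp_positions[c])) for c in chroms])
    n_sites = pos_col.size
    sample_ids = sorted(by_sample)
    genotypes = np.empty((len(sample_ids), n_sites), dtype=np.int8)
    for s, sid in enumerate(sample_ids):
        is_het = rng.random(n_sites) < background_het_rate
        hom_kind = rng.integers(2, size=n_sites).astype(np.int8) * 2  # 0 or 2
        g = np.where(is_het, HET, hom_kind).astype(np.int8)
        for chrom, start, end in by_sample[sid]:
            inside = (chrom_col == chrom) & (pos_col >= start) & (pos_col <= end)
            g[inside] = hom_kind[inside]
        genotypes[s] = g

    ref_idx = rng.integers(4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({
        "chrom": chrom_col, "pos": pos_col.astype(np.int64),
        "ref": _BASES[ref_idx].astype("U1"), "alt": _BASES[alt_idx].astype("U1"),
        "qual": 50.0, "mean_depth": 10.0, "impact_class": "OTHER", "polarized": False,
    })
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "population_id": "PAINT",
        "management": "MANAGED",
    })
    dataset = GenotypeDataset(sites, samples, genotypes, contig_lengths=contig_lengths)
    true_roh = []
    for sid, chrom, start, end in layout:
        inside = (chrom_col == chrom) & (pos_col >= start) & (pos_col <= end)
        true_roh.append(ROHSegment(sample_id=sid, chromosome=chrom, start_bp=start,
                                   end_bp=end, n_snps=int(inside.sum()), n_het=0, n_missing=0))
    truth = TruthSet(true_roh=true_roh, true_ancestral=sites["ref"].to_numpy().astype("S1"),
                     true_ne={})
    return dataset, truth


# ---------------------------------------------------------------------------
# ancestral-sequence defects
# ---------------------------------------------------------------------------

def perturb_ancestral(anc: AncestralFasta, dataset: GenotypeDataset,
                      frac_missing: float, frac_mismatch: float,
                      seed: int = 0) -> tuple[AncestralFasta, dict]:
    """Inject defects into the outgroup consensus at SNP positions.

    ``floor(n_sites * frac_missing)`` positions become N; a disjoint
    ``floor(n_sites * frac_mismatch)`` positions become a base equal to
    neither ref nor alt. Returns the perturbed copy and a ledger dict with
    the exact (chrom, pos) sets, for downstream cross-checks.
    """
    if not (0 <= frac_missing <= 1 and 0 <= frac_mismatch <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if frac_missing + frac_mismatch > 1:
        raise ValueError("frac_missing + frac_mismatch must be <= 1")
    rng = np.random.default_rng(seed)
    n = dataset.n_sites
    n_miss = int(np.floor(n * frac_missing))
    n_mis = int(np.floor(n * frac_mismatch))
    chosen = rng.choice(n, size=n_miss + n_mis, replace=False) if n_miss + n_mis else np.array([], dtype=int)
    miss_idx = np.sort(chosen[:n_miss])
    mis_idx = np.sort(chosen[n_miss:])
    out = anc.copy()
    chroms = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    ref = dataset.sites["ref"].to_numpy()
    alt = dataset.sites["alt"].to_numpy()
    for i in miss_idx:
        out.set_base(chroms[i], int(pos[i]), "N")
    all_bases = ["A", "C", "G", "T"]
    for i in mis_idx:
        options = [b for b in all_bases if b not in (ref[i], alt[i])]
        out.set_base(chroms[i], int(pos[i]), options[rng.integers(len(options))])
    ledger = {
        "missing": {(chroms[i], int(pos[i])) for i in miss_idx},
        "mismatch": {(chroms[i], int(pos[i])) for i in mis_idx},
    }
    return out, ledger


def write_truth_bed(truth: TruthSet, path) -> None:
    """Truth autozygosity tracts as BED (0-based half-open)."""
    rows = sorted(((s.chromosome, s.start_bp - 1, s.end_bp, s.sample_id, s.n_snps)
                   for s in truth.true_roh), key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
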