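"""Genotype container, VCF/BED/table I/O, and hard site filters.

The in-memory representation used by every downstream stage is a
:class:`GenotypeDataset`: a site table (pandas), a sample table (pandas) and a
dense ``(n_samples, n_sites)`` int8 genotype-code matrix. Genotype codes follow
the usual 0/1/2 dosage convention with ``-1`` for missing:

========  =====  =========================
constant  value  meaning
========  =====  =========================
HOM_REF   0      homozygous reference
HET       1      heterozygous
HOM_ALT   2      homozygous alternate
MISSING   -1     no call (``./.``)
========  =====  =========================

Coordinates are 1-based inclusive internally (VCF convention); BED output is
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("rohload")

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

IMPACT_CLASSES = ("LOF", "MISSENSE", "INTERGENIC", "OTHER")
MANAGEMENT_VALUES = ("MANAGED", "UNMANAGED")

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "mean_depth", "impact_class", "polarized"]
SAMPLE_COLUMNS = ["sample_id", "population_id", "management"]

_BASES = frozenset("ACGT")


class GenotypeDataset:
    """Samples x biallelic-SNP sites with genotype codes and site metadata.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, qual,
        mean_depth, impact_class, polarized`` (missing metadata columns are
        filled with defaults). Sites must be coordinate-sorted: chromosomes in
        contiguous blocks, positions strictly increasing within each block.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id, population_id,
        management``.
    genotypes : numpy.ndarray
        int8 matrix of shape ``(n_samples, n_sites)`` with values in
        {0, 1, 2, -1}.
    contig_lengths : dict, optional
        Chromosome name -> length in bp, when known (used for VCF/FASTA
        headers and bounds checks).
    """

    def __init__(self, sites, samples, genotypes, contig_lengths=None, validate=True):
        sites = sites.reset_index(drop=True).copy()
        if "qual" not in sites:
            sites["qual"] = 0.0
        if "mean_depth" not in sites:
            sites["mean_depth"] = np.nan
        if "impact_class" not in sites:
            sites["impact_class"] = "OTHER"
        if "polarized" not in sites:
            sites["polarized"] = False
        self.sites = sites[SITE_COLUMNS]
        self.samples = samples.reset_index(drop=True).copy()
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.contig_lengths = dict(contig_lengths) if contig_lengths else None
        if validate:
            self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list:
        return list(self.samples["sample_id"])

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.genotypes.shape != (self.n_samples, self.n_sites):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({self.n_samples}, {self.n_sites})"
            )
        bad = ~np.isin(self.genotypes, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("genotype matrix contains codes outside {0,1,2,-1}")
        if self.n_sites:
            chrom = self.sites["chrom"].to_numpy()
            pos = self.sites["pos"].to_numpy()
            # chromosomes must form contiguous blocks
            change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
            blocks = np.concatenate([[0], change])
            names = chrom[blocks]
            if len(set(names)) != len(names):
                raise ValueError("unsorted sites: chromosome blocks are interleaved")
            same = chrom[1:] == chrom[:-1]
            if np.any(same & (pos[1:] <= pos[:-1])):
                raise ValueError("unsorted or duplicate positions within a chromosome")
            for col in ("ref", "alt"):
                vals = self.sites[col]
                if not vals.isin(list(_BASES)).all():
                    raise ValueError(f"non-SNP allele in column {col!r}")
            if (self.sites["ref"] == self.sites["alt"]).any():
                raise ValueError("ref allele equals alt allele at some site")
        if self.n_samples:
            pops = self.samples.groupby("population_id")["management"].nunique()
            if (pops > 1).any():
                bad_pops = list(pops[pops > 1].index)
                raise ValueError(f"population(s) {bad_pops} mapped to >1 management value")
            if not self.samples["management"].isin(MANAGEMENT_VALUES).all():
                raise ValueError("management must be MANAGED or UNMANAGED")

    def subset_sites(self, mask) -> "GenotypeDataset":
        """Return a new dataset restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.sites[mask],
            self.samples,
            self.genotypes[:, mask],
            contig_lengths=self.contig_lengths,
            validate=False,
        )

    def sample_indices(self, sample_ids) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.samples["sample_id"])}
        missing = [s for s in sample_ids if s not in order]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return np.array([order[s] for s in sample_ids], dtype=int)

    def equal_content(self, other: "GenotypeDataset") -> bool:
        """Site coordinates/alleles and genotype codes identical."""
        a = self.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
        b = other.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
        return a.equals(b) and np.array_equal(self.genotypes, other.genotypes)


# ---------------------------------------------------------------------------
# sample / annotation tables
# ---------------------------------------------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    """Read the tab-separated sample table (sample_id, population_id, management)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in tab.columns]
    if missing_cols:
        raise ValueError(f"sample table {path} lacks column(s) {missing_cols}")
    tab["management"] = tab["management"].str.upper()
    bad = ~tab["management"].isin(MANAGEMENT_VALUES)
    if bad.any():
        raise ValueError(f"invalid management value(s): {sorted(set(tab['management'][bad]))}")
    return tab[SAMPLE_COLUMNS]


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read the tab-separated site annotation table (chrom, pos, class)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "class": str})
    for col in ("chrom", "pos", "class"):
        if col not in ann.columns:
            raise ValueError(f"annotation table {path} lacks column {col!r}")
    bad = ~ann["class"].isin(IMPACT_CLASSES)
    if bad.any():
        raise ValueError(f"invalid impact class(es): {sorted(set(ann['class'][bad]))}")
    return ann


def write_annotations(dataset: GenotypeDataset, path) -> None:
    out = dataset.sites[["chrom", "pos", "impact_class"]].rename(columns={"impact_class": "class"})
    out.to_csv(path, sep="\t", index=False)


def attach_annotations(dataset: GenotypeDataset, annotations: pd.DataFrame) -> GenotypeDataset:
    """Return a copy of ``dataset`` with impact classes set from the table.

    Sites absent from the table keep class OTHER.
    """
    key = pd.MultiIndex.from_frame(dataset.sites[["chrom", "pos"]])
    ann_key = pd.MultiIndex.from_frame(annotations[["chrom", "pos"]])
    mapping = pd.Series(annotations["class"].to_numpy(), index=ann_key)
    mapping = mapping[~mapping.index.duplicated()]
    new_sites = dataset.sites.copy()
    matched = mapping.reindex(key)
    new_sites["impact_class"] = matched.fillna("OTHER").to_numpy()
    return GenotypeDataset(
        new_sites, dataset.samples, dataset.genotypes,
        contig_lengths=dataset.contig_lengths, validate=False,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_table_path) -> GenotypeDataset:
    """Read a VCF 4.x file of biallelic SNPs into a :class:`GenotypeDataset`.

    Multiallelic and non-SNP records are skipped and counted in a log summary.
    Per-site mean depth is the across-sample mean of FORMAT DP when present,
    else INFO DP divided by the sample count, else NaN.

    Raises
    ------
    KeyError
        If a VCF sample is absent from the sample table.
    ValueError
        If the VCF is not coordinate-sorted.
    """
    from cyvcf2 import VCF

    table = read_sample_table(sample_table_path)
    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    known = set(table["sample_id"])
    absent = [s for s in vcf_samples if s not in known]
    if absent:
        raise KeyError(f"VCF sample(s) missing from sample table: {absent}")
    table = table.set_index("sample_id").loc[vcf_samples].reset_index()

    contig_lengths = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            contig_lengths[name] = int(length)
    except Exception:
        contig_lengths = {}

    rows, geno_cols = [], []
    n_skipped = 0
    n = len(vcf_samples)
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = var.gt_types.astype(np.int8)  # gts012: 0,1,2 and 3=unknown
        gt[gt == 3] = MISSING
        fmt_dp = None
        try:
            fmt_dp = var.format("DP")
        except Exception:
            fmt_dp = None
        if fmt_dp is not None:
            dp = np.asarray(fmt_dp, dtype=float)
            dp[dp < 0] = np.nan
            mean_depth = float(np.nanmean(dp)) if np.isfinite(dp).any() else np.nan
        elif var.INFO.get("MDP") is not None:
            mean_depth = float(var.INFO.get("MDP"))
        elif var.INFO.get("DP") is not None:
            mean_depth = float(var.INFO.get("DP")) / n
        else:
            mean_depth = np.nan
        rows.append(
            (var.CHROM, var.POS, var.REF, var.ALT[0],
             float(var.QUAL) if var.QUAL is not None else 0.0,
             mean_depth, "OTHER", bool(var.INFO.get("POLARIZED") is not None))
        )
        geno_cols.append(gt)
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP record(s)", n_skipped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.zeros((n, 0), dtype=np.int8)
    )
    ds = GenotypeDataset(sites, table, genotypes, contig_lengths=contig_lengths or None)
    ds.n_skipped_records = n_skipped
    return ds


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 file.

    QUAL goes to the QUAL column; mean depth to INFO ``MDP`` (per-site mean,
    lossless) and conventionally to integer INFO ``DP`` (total over samples);
    the ``POLARIZED`` INFO flag marks sites already oriented
    ancestral/derived.
    """
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    n = dataset.n_samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth across samples">\n')
        fh.write('##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean depth per sample">\n')
        fh.write('##INFO=<ID=POLARIZED,Number=0,Type=Flag,Description="REF is the ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(dataset.sites["chrom"]))
        for c in chroms:
            if dataset.contig_lengths and c in dataset.contig_lengths:
                fh.write(f"##contig=<ID={c},length={dataset.contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples["sample_id"]) + "\n")
        sites = dataset.sites
        for j in range(dataset.n_sites):
            row = sites.iloc[j]
            info = []
            if np.isfinite(row["mean_depth"]):
                info.append(f"DP={int(round(row['mean_depth'] * n))}")
                info.append(f"MDP={_fmt_float(row['mean_depth'])}")
            if row["polarized"]:
                info.append("POLARIZED")
            gts = "\t".join(gt_str[int(g)] for g in dataset.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{_fmt_float(row['qual'])}\t.\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Hard site-filter thresholds.

    Defaults reproduce a conventional high-quality SNP set: QUAL >= 30,
    per-site mean depth within [5, 20], genotyping rate >= 95%, minor allele
    count >= 1, and autosomes only (when an allowlist is given).
    """

    min_qual: float = 30.0
    min_mean_depth: float = 5.0
    max_mean_depth: float = 20.0
    min_call_rate: float = 0.95
    min_minor_allele_count: int = 1
    autosome_allowlist: frozenset | None = None  # None = all chromosomes pass

    def __post_init__(self):
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not self.min_mean_depth < self.max_mean_depth:
            raise ValueError("min_mean_depth must be < max_mean_depth")
        if self.autosome_allowlist is not None:
            if len(self.autosome_allowlist) == 0:
                raise ValueError("autosome_allowlist is empty: no site could pass")
            self.autosome_allowlist = frozenset(self.autosome_allowlist)


# attribution order is fixed so reports are deterministic
FILTER_CRITERIA = ("qual", "depth", "call_rate", "mac", "chromosome")


@dataclass
class FilterReport:
    """Per-criterion removal counts; a site failing several criteria is counted
    once, under the first failing criterion (order: qual, depth, call_rate,
    mac, chromosome)."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed": dict(self.removed)}


def minor_allele_counts(dataset: GenotypeDataset) -> np.ndarray:
    """Per-site minor allele count over non-missing genotypes."""
    g = dataset.genotypes
    called = g != MISSING
    alt = np.where(g == HET, 1, 0) + np.where(g == HOM_ALT, 2, 0)
    alt_count = alt.sum(axis=0)
    total = 2 * called.sum(axis=0)
    return np.minimum(alt_count, total - alt_count)


def apply_site_filters(dataset: GenotypeDataset, cfg: FilterConfig) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the hard site filters; returns the filtered dataset and a report.

    The retained set is independent of criterion order (all criteria are
    conjunctive); only the report's attribution depends on the fixed order.
    """
    sites = dataset.sites
    qual_ok = sites["qual"].to_numpy() >= cfg.min_qual
    depth = sites["mean_depth"].to_numpy(dtype=float)
    depth_ok = (depth >= cfg.min_mean_depth) & (depth <= cfg.max_mean_depth)
    called = dataset.genotypes != MISSING
    call_rate = called.mean(axis=0) if dataset.n_samples else np.ones(dataset.n_sites)
    rate_ok = call_rate >= cfg.min_call_rate
    mac_ok = minor_allele_counts(dataset) >= cfg.min_minor_allele_count
    if cfg.autosome_allowlist is None:
        chrom_ok = np.ones(dataset.n_sites, dtype=bool)
    else:
        chrom_ok = sites["chrom"].isin(cfg.autosome_allowlist).to_numpy()

    checks = {"qual": qual_ok, "depth": depth_ok, "call_rate": rate_ok,
              "mac": mac_ok, "chromosome": chrom_ok}
    keep = np.ones(dataset.n_sites, dtype=bool)
    attributed = np.zeros(dataset.n_sites, dtype=bool)
    report = FilterReport(n_input=dataset.n_sites, removed={k: 0 for k in FILTER_CRITERIA})
    for name in FILTER_CRITERIA:
        fail = ~checks[name]
        newly = fail & ~attributed
        report.removed[name] = int(newly.sum())
        attributed |= fail
        keep &= ~fail
    report.n_retained = int(keep.sum())
    return dataset.subset_sites(keep), report


# ---------------------------------------------------------------------------
# BED output for ROH segments
# ---------------------------------------------------------------------------

def write_roh_bed(segments, path) -> None:
    """Write ROH segments as sorted BED (0-based half-open).

    Columns: chrom, start, end, sample, n_snps, n_het. Overlapping segments
    for the same sample are a caller error and raise ValueError.
    """
    rows = sorted(
        ((s.chromosome, s.start_bp - 1, s.end_bp, s.sample_id, s.n_snps, s.n_het)
         for s in segments),
        key=lambda r: (r[0], r[1], r[3]),
    )
    last_end: dict = {}
    for chrom, start, end, sample, _, _ in rows:
        key = (sample, chrom)
        if key in last_end and start < last_end[key]:
            raise ValueError(f"overlapping ROH segments for sample {sample} on {chrom}")
        last_end[key] = max(end, last_end.get(key, 0))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_roh_bed(path):
    """Read a BED written by :func:`write_roh_bed` back into segments."""
    from .roh import ROHSegment

    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, sample, n_snps, n_het = line.rstrip("\n").split("\t")
            segs.append(ROHSegment(
                sample_id=sample, chromosome=chrom,
                start_bp=int(start) + 1, end_bp=int(end),
                n_snps=int(n_snps), n_het=int(n_het), n_missing=0,
            ))
    return segs
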