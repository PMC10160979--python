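"""Sliding-window runs-of-homozygosity (ROH) caller and F_ROH.

The caller reproduces the PLINK ``--homozyg`` window heuristic: a window of a
fixed number of consecutive SNPs slides along each chromosome; a window is
"homozygous" when it holds at most ``window_het`` heterozygous and at most
``window_missing`` missing calls; a SNP is eligible when at least
``window_threshold`` of the windows covering it are homozygous; maximal runs
of eligible SNPs, split at large physical gaps, become segments subject to
minimum-SNP, minimum-length and maximum-density constraints.

Defaults match a conservative mammalian whole-genome configuration:
50-SNP windows (<=3 het, <=5 missing), 5% hit-fraction threshold, minimum
segment size 500 kb and 50 SNPs, 1 Mb maximum gap, 50 kb/SNP maximum density.

F_ROH for an individual is the summed segment length divided by the autosomal
genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import HET, MISSING, GenotypeDataset


@dataclass
class ROHConfig:
    window_snp: int = 50
    window_het: int = 3
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 500.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self):
        for name in ("window_snp", "window_het", "window_missing", "min_snp",
                     "min_kb", "max_gap_kb", "max_density_kb_per_snp"):
            if getattr(self, name) <= 0 and name not in ("window_het", "window_missing"):
                raise ValueError(f"{name} must be positive")
        if getattr(self, "window_het") < 0 or getattr(self, "window_missing") < 0:
            raise ValueError("window_het/window_missing must be >= 0")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run for one sample; coordinates of the first and last
    SNP in the run, 1-based inclusive."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def scan_sample_chromosome(genotypes, positions, cfg: ROHConfig) -> np.ndarray:
    """Per-SNP eligibility for one sample on one chromosome.

    Parameters
    ----------
    genotypes : array of genotype codes for the chromosome's SNPs, in order.
    positions : strictly increasing 1-based bp positions (same length).
    cfg : ROHConfig.

    Returns
    -------
    boolean array: SNP is covered by a fraction >= ``cfg.window_threshold``
    of homozygous windows among the windows covering it. Chromosomes with
    fewer SNPs than ``window_snp`` are scanned with a single window spanning
    all SNPs.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    pos = np.asarray(positions)
    n = g.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if pos.size != n or (n > 1 and np.any(np.diff(pos) <= 0)):
        raise ValueError("positions must be strictly increasing and match genotypes")
    w = min(cfg.window_snp, n)
    het = (g == HET).astype(np.int64)
    miss = (g == MISSING).astype(np.int64)
    # sliding sums over windows of w consecutive SNPs
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    nw = n - w + 1
    het_in_win = chet[w:] - chet[:-w]
    miss_in_win = cmiss[w:] - cmiss[:-w]
    hom_win = ((het_in_win <= cfg.window_het) & (miss_in_win <= cfg.window_missing))
    # window j covers SNPs j..j+w-1; SNP i covered by windows max(0,i-w+1)..min(nw-1,i)
    chom = np.concatenate([[0], np.cumsum(hom_win.astype(np.int64))])
    i = np.arange(n)
    j1 = np.maximum(0, i - w + 1)
    j2 = np.minimum(nw - 1, i)
    hits = chom[j2 + 1] - chom[j1]
    cov = j2 - j1 + 1
    return hits / cov >= cfg.window_threshold


def _assemble_segments(eligible, genotypes, positions, cfg, sample_id, chrom):
    """Maximal eligible runs -> gap splitting -> size/density constraints."""
    segs = []
    n = eligible.size
    i = 0
    g = np.asarray(genotypes, dtype=np.int8)
    pos = np.asarray(positions)
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        # split run [i, j] at gaps larger than max_gap_kb
        max_gap = cfg.max_gap_kb * 1000.0
        start = i
        for k in range(i, j + 1):
            end_here = (k == j) or (pos[k + 1] - pos[k] > max_gap)
            if end_here:
                seg = _finalize(g, pos, start, k, cfg, sample_id, chrom)
                if seg is not None:
                    segs.append(seg)
                start = k + 1
        i = j + 1
    return segs


def _finalize(g, pos, a, b, cfg, sample_id, chrom):
    n_snps = b - a + 1
    length = int(pos[b] - pos[a] + 1)
    if n_snps < cfg.min_snp:
        return None
    if length < cfg.min_kb * 1000.0:
        return None
    if length / n_snps > cfg.max_density_kb_per_snp * 1000.0:
        return None
    run = g[a:b + 1]
    return ROHSegment(
        sample_id=sample_id, chromosome=chrom,
        start_bp=int(pos[a]), end_bp=int(pos[b]), n_snps=n_snps,
        n_het=int(np.count_nonzero(run == HET)),
        n_missing=int(np.count_nonzero(run == MISSING)),
    )


def call_roh(dataset: GenotypeDataset, cfg: ROHConfig | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample of the dataset.

    Heterozygous SNPs inside an emitted segment are permitted (the window
    heuristic tolerates them) and reported in ``n_het``; no segment-level
    heterozygote cap is applied.
    """
    cfg = cfg or ROHConfig()
    dataset.validate()  # unsorted input is fatal
    segments: list[ROHSegment] = []
    chroms = dataset.sites["chrom"].to_numpy()
    pos_all = dataset.sites["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        for s, sample_id in enumerate(dataset.samples["sample_id"]):
            g = dataset.genotypes[s, idx]
            eligible = scan_sample_chromosome(g, pos, cfg)
            segments.extend(_assemble_segments(eligible, g, pos, cfg, sample_id, chrom))
    return segments


def compute_froh(segments, genome_length_bp: float, sample_ids=None) -> pd.DataFrame:
    """Per-individual inbreeding coefficient F_ROH.

    F_ROH = (sum of the individual's ROH segment lengths) / genome_length_bp.
    ``sample_ids`` fixes the output rows (individuals with no segments get 0);
    when omitted, only samples with segments appear.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    totals: dict = {}
    for seg in segments:
        totals[seg.sample_id] = totals.get(seg.sample_id, 0) + seg.length_bp
    if sample_ids is None:
        sample_ids = sorted(totals)
    rows = [(s, totals.get(s, 0) / genome_length_bp, genome_length_bp) for s in sample_ids]
    return pd.DataFrame(rows, columns=["sample_id", "froh", "genome_length_bp"])
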