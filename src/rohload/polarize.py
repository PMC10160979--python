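"""Ancestral/derived polarization against an outgroup consensus sequence.

A SNP is usable only when the outgroup consensus carries one of its two
alleles at that position. Three rules, applied per site:

1. consensus base is N, an ambiguity code, or the position lies outside the
   consensus -> site dropped ("absent");
2. consensus base equals neither ref nor alt -> site dropped ("mismatch");
3. consensus base equals alt -> ref/alt are swapped and homozygous genotype
   codes are flipped (HOM_REF <-> HOM_ALT), so that after the operation the
   reference allele is ancestral and the alternate allele is derived at every
   retained site.

Soft-masked (lower-case) consensus bases are uppercased before comparison;
IUPAC ambiguity codes other than ACGT are treated as N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variant_io import HOM_ALT, HOM_REF, GenotypeDataset


class AncestralFasta:
    """Outgroup-consensus bases addressable by (chromosome, 1-based position).

    Backed either densely (full per-contig base strings, as read from a FASTA
    file) or sparsely (bases known at listed positions only, everything else
    implicitly N) — the sparse form is what the simulator emits for large
    genomes where only SNP positions matter.
    """

    def __init__(self, contig_lengths: dict):
        self.contig_lengths = dict(contig_lengths)
        self._dense: dict = {}
        self._sparse_pos: dict = {}
        self._sparse_base: dict = {}

    # -- construction -------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "AncestralFasta":
        """Read a FASTA file; sequences are uppercased, non-ACGT becomes N."""
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
        anc = cls({name: len(fa[name]) for name in fa.keys()})
        for name in fa.keys():
            seq = np.frombuffer(str(fa[name][:]).encode(), dtype="S1").copy()
            seq[~np.isin(seq, [b"A", b"C", b"G", b"T"])] = b"N"
            anc._dense[name] = seq
        return anc

    @classmethod
    def from_dense(cls, sequences: dict) -> "AncestralFasta":
        anc = cls({c: len(s) for c, s in sequences.items()})
        for c, s in sequences.items():
            seq = np.frombuffer(s.upper().encode(), dtype="S1").copy()
            seq[~np.isin(seq, [b"A", b"C", b"G", b"T"])] = b"N"
            anc._dense[c] = seq
        return anc

    @classmethod
    def from_sparse(cls, contig_lengths: dict, positions: dict, bases: dict) -> "AncestralFasta":
        """``positions[chrom]``: sorted 1-based positions; ``bases[chrom]``:
        matching bases (array of single-character bytes or str)."""
        anc = cls(contig_lengths)
        for c in positions:
            pos = np.asarray(positions[c], dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"sparse positions for {c} must be strictly increasing")
            b = np.asarray(bases[c], dtype="S1")
            anc._sparse_pos[c] = pos
            anc._sparse_base[c] = b
        return anc

    # -- lookup --------------------------------------------------------------
    def bases_at(self, chrom: str, positions) -> np.ndarray:
        """Bases (bytes, S1) at 1-based positions; b'N' for unknown, b'' for
        positions beyond the contig end (absent)."""
        if chrom not in self.contig_lengths:
            raise KeyError(f"contig {chrom!r} absent from ancestral sequence")
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(pos.shape, b"N", dtype="S1")
        inside = (pos >= 1) & (pos <= self.contig_lengths[chrom])
        out[~inside] = b""
        if chrom in self._dense:
            out[inside] = self._dense[chrom][pos[inside] - 1]
        elif chrom in self._sparse_pos:
            sp = self._sparse_pos[chrom]
            sb = self._sparse_base[chrom]
            j = np.searchsorted(sp, pos)
            hit = inside & (j < sp.size)
            hit[hit] &= sp[j[hit]] == pos[hit]
            out[hit] = sb[j[hit]]
        return out

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        if chrom in self._dense:
            self._dense[chrom][pos - 1] = base.encode()
        elif chrom in self._sparse_pos:
            j = np.searchsorted(self._sparse_pos[chrom], pos)
            if j >= self._sparse_pos[chrom].size or self._sparse_pos[chrom][j] != pos:
                raise KeyError(f"position {chrom}:{pos} not tracked in sparse ancestral sequence")
            self._sparse_base[chrom][j] = base.encode()
        else:
            raise KeyError(f"contig {chrom!r} has no backing sequence")

    def copy(self) -> "AncestralFasta":
        new = AncestralFasta(self.contig_lengths)
        new._dense = {c: s.copy() for c, s in self._dense.items()}
        new._sparse_pos = {c: p.copy() for c, p in self._sparse_pos.items()}
        new._sparse_base = {c: b.copy() for c, b in self._sparse_base.items()}
        return new

    def to_fasta(self, path, fill: str = "N", width: int = 70) -> None:
        """Write a full-length FASTA; sparse contigs are filled with ``fill``
        outside tracked positions."""
        with open(path, "w") as fh:
            for chrom, length in self.contig_lengths.items():
                if chrom in self._dense:
                    seq = self._dense[chrom].tobytes().decode()
                else:
                    arr = np.full(length, fill.encode(), dtype="S1")
                    if chrom in self._sparse_pos:
                        arr[self._sparse_pos[chrom] - 1] = self._sparse_base[chrom]
                    seq = arr.tobytes().decode()
                fh.write(f">{chrom}\n")
                for i in range(0, length, width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass
class PolarizationReport:
    """Counts per polarization outcome; dropped/rotated position lists are kept
    for exact cross-checks against simulated-defect ledgers."""

    n_input: int = 0
    n_dropped_absent: int = 0
    n_dropped_mismatch: int = 0
    n_rotated: int = 0
    n_unchanged: int = 0
    dropped_absent: list = field(default_factory=list)    # (chrom, pos)
    dropped_mismatch: list = field(default_factory=list)  # (chrom, pos)
    rotated: list = field(default_factory=list)           # (chrom, pos)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_absent": self.n_dropped_absent,
            "n_dropped_mismatch": self.n_dropped_mismatch,
            "n_rotated": self.n_rotated,
            "n_unchanged": self.n_unchanged,
        }


def polarize(dataset: GenotypeDataset, anc: AncestralFasta) -> tuple[GenotypeDataset, PolarizationReport]:
    """Orient every site to ancestral (ref) / derived (alt) state.

    Returns the polarized dataset (dropped sites removed, rotated sites with
    ref/alt swapped and homozygote codes flipped, ``polarized`` flag set) and
    a :class:`PolarizationReport`. Unknown contigs are fatal.
    """
    report = PolarizationReport(n_input=dataset.n_sites)
    chroms = dataset.sites["chrom"].to_numpy()
    missing_contigs = sorted(set(chroms) - set(anc.contig_lengths))
    if missing_contigs:
        raise KeyError(f"contig(s) {missing_contigs} absent from ancestral sequence")

    pos_all = dataset.sites["pos"].to_numpy()
    anc_base = np.empty(dataset.n_sites, dtype="S1")
    for chrom in dict.fromkeys(chroms):
        m = chroms == chrom
        anc_base[m] = anc.bases_at(chrom, pos_all[m])

    ref = dataset.sites["ref"].to_numpy().astype("S1")
    alt = dataset.sites["alt"].to_numpy().astype("S1")
    absent = (anc_base == b"N") | (anc_base == b"")
    is_ref = ~absent & (anc_base == ref)
    is_alt = ~absent & (anc_base == alt)
    mismatch = ~absent & ~is_ref & ~is_alt

    keep = is_ref | is_alt
    report.n_dropped_absent = int(absent.sum())
    report.n_dropped_mismatch = int(mismatch.sum())
    report.n_rotated = int(is_alt.sum())
    report.n_unchanged = int(is_ref.sum())
    report.dropped_absent = [(c, int(p)) for c, p in zip(chroms[absent], pos_all[absent])]
    report.dropped_mismatch = [(c, int(p)) for c, p in zip(chroms[mismatch], pos_all[mismatch])]
    report.rotated = [(c, int(p)) for c, p in zip(chroms[is_alt], pos_all[is_alt])]

    sites = dataset.sites.copy()
    genotypes = dataset.genotypes.copy()
    rot = np.flatnonzero(is_alt)
    if rot.size:
        r = sites.loc[rot, "ref"].to_numpy()
        sites.loc[rot, "ref"] = sites.loc[rot, "alt"].to_numpy()
        sites.loc[rot, "alt"] = r
        col = genotypes[:, rot]
        flipped = col.copy()
        flipped[col == HOM_REF] = HOM_ALT
        flipped[col == HOM_ALT] = HOM_REF
        genotypes[:, rot] = flipped
    sites["polarized"] = True
    out = GenotypeDataset(sites, dataset.samples, genotypes,
                          contig_lengths=dataset.contig_lengths, validate=False)
    return out.subset_sites(keep), report
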