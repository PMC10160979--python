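"""Window ROH caller: brute-force oracle equivalence, constraint arithmetic,
painted-fixture recovery, F_ROH."""

import numpy as np
import pytest

from rohload import (HET, HOM_ALT, HOM_REF, MISSING, ROHConfig, ROHSegment,
                     call_roh, compute_froh, paint_roh, scan_sample_chromosome)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracle: direct enumeration of every window, hit fractions, run
# assembly and constraint checks, all in plain Python
# ---------------------------------------------------------------------------

def oracle_eligibility(genos, cfg):
    n = len(genos)
    w = min(cfg.window_snp, n)
    windows = []
    for start in range(n - w + 1):
        chunk = genos[start:start + w]
        n_het = sum(1 for g in chunk if g == HET)
        n_miss = sum(1 for g in chunk if g == MISSING)
        windows.append(n_het <= cfg.window_het and n_miss <= cfg.window_missing)
    eligible = []
    for i in range(n):
        covering = [windows[j] for j in range(len(windows)) if j <= i <= j + w - 1]
        frac = sum(covering) / len(covering)
        eligible.append(frac >= cfg.window_threshold)
    return eligible


def oracle_segments(genos, positions, cfg, sample_id="S0", chrom="chr1"):
    eligible = oracle_eligibility(genos, cfg)
    n = len(genos)
    runs, cur = [], []
    for i in range(n):
        if eligible[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    # split at large physical gaps
    pieces = []
    for run in runs:
        piece = [run[0]]
        for prev_i, i in zip(run, run[1:]):
            if positions[i] - positions[prev_i] > cfg.max_gap_kb * 1000:
                pieces.append(piece)
                piece = []
            piece.append(i)
        pieces.append(piece)
    segs = []
    for piece in pieces:
        a, b = piece[0], piece[-1]
        n_snps = b - a + 1
        length = positions[b] - positions[a] + 1
        if n_snps < cfg.min_snp or length < cfg.min_kb * 1000:
            continue
        if length / n_snps > cfg.max_density_kb_per_snp * 1000:
            continue
        segs.append(ROHSegment(
            sample_id=sample_id, chromosome=chrom,
            start_bp=int(positions[a]), end_bp=int(positions[b]), n_snps=n_snps,
            n_het=sum(1 for g in genos[a:b + 1] if g == HET),
            n_missing=sum(1 for g in genos[a:b + 1] if g == MISSING),
        ))
    return segs


def random_instance(rng, max_snps=200):
    n = rng.integers(5, max_snps + 1)
    positions = np.sort(rng.choice(np.arange(1, 8_000_000), size=n, replace=False))
    p_het = rng.uniform(0, 0.3)
    p_miss = rng.uniform(0, 0.15)
    u = rng.random(n)
    genos = np.where(u < p_het, HET,
                     np.where(u < p_het + p_miss, MISSING,
                              np.where(rng.random(n) < 0.5, HOM_REF, HOM_ALT))).astype(np.int8)
    # occasionally paint a clean homozygous stretch so segments actually occur
    if rng.random() < 0.7 and n > 60:
        a = rng.integers(0, n - 60)
        genos[a:a + 60] = HOM_REF
    cfg = ROHConfig(
        window_snp=int(rng.integers(5, 60)),
        window_het=int(rng.integers(0, 4)),
        window_missing=int(rng.integers(0, 6)),
        window_threshold=float(rng.choice([0.05, 0.2, 0.5, 1.0])),
        min_snp=int(rng.integers(10, 60)),
        min_kb=float(rng.choice([100, 300, 500])),
        max_gap_kb=float(rng.choice([200, 500, 1000])),
        max_density_kb_per_snp=float(rng.choice([50, 200])),
    )
    return genos, positions, cfg


def test_all_homozygous_all_eligible():
    genos = np.zeros(60, dtype=np.int8)
    pos = np.arange(1, 61) * 10_000
    eligible = scan_sample_chromosome(genos, pos, ROHConfig())
    assert eligible.all()


def test_het_cluster_matches_window_enumeration():
    # 4 heterozygotes at consecutive indices exceed the 3-het window budget
    genos = np.zeros(60, dtype=np.int8)
    genos[10:14] = HET
    pos = np.arange(1, 61) * 10_000
    cfg = ROHConfig()
    got = scan_sample_chromosome(genos, pos, cfg)
    assert list(got) == oracle_eligibility(list(genos), cfg)


def test_strict_threshold_single_het_blocks_window_span():
    genos = np.zeros(150, dtype=np.int8)
    genos[30] = HET
    pos = np.arange(1, 151) * 10_000
    cfg = ROHConfig(window_threshold=1.0, window_het=0)
    got = scan_sample_chromosome(genos, pos, cfg)
    expected = oracle_eligibility(list(genos), cfg)
    assert list(got) == expected
    assert not got[30]
    # every SNP whose covering windows all contain the het is blocked;
    # SNPs beyond that reach stay eligible
    assert not got[0]       # its single covering window holds the het
    assert got[-1]          # far from the het: all covering windows clean


def test_short_chromosome_single_window():
    genos = np.zeros(10, dtype=np.int8)
    genos[3] = HET
    pos = np.arange(1, 11) * 1000
    cfg = ROHConfig(window_snp=50, window_het=0)
    eligible = scan_sample_chromosome(genos, pos, cfg)
    assert not eligible.any()  # the one spanning window holds a het


@pytest.mark.parametrize("seed", range(6))
def test_oracle_equivalence_random_instances(seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        genos, pos, cfg = random_instance(rng)
        ds = make_dataset(genos[None, :], positions=pos)
        got = call_roh(ds, cfg)
        want = oracle_segments(list(genos), list(pos), cfg)
        assert got == want


@pytest.mark.parametrize(
    "n_snps,span_bp,expect",
    [
        (80, 400_000, 0),   # fails the 500 kb minimum length
        (49, 600_000, 0),   # fails the 50 SNP minimum
        (80, 600_000, 1),   # passes everything
    ],
)
def test_minimum_constraints(n_snps, span_bp, expect):
    positions = np.linspace(1, span_bp, n_snps).astype(np.int64)
    positions = np.unique(positions)
    genos = np.zeros((1, len(positions)), dtype=np.int8)
    ds = make_dataset(genos, positions=positions)
    assert len(call_roh(ds, ROHConfig())) == expect


def test_gap_splitting():
    # 120 homozygous SNPs with a 2 Mb hole in the middle -> two segments
    left = np.arange(1, 61) * 10_000
    right = left[-1] + 2_000_000 + np.arange(1, 61) * 10_000
    pos = np.concatenate([left, right])
    ds = make_dataset(np.zeros((1, 120), dtype=np.int8), positions=pos)
    segs = call_roh(ds, ROHConfig())
    assert len(segs) == 2
    assert segs[0].end_bp == left[-1] and segs[1].start_bp == right[0]


def test_painted_interval_recovery():
    rng_positions = np.sort(np.random.default_rng(7).choice(
        np.arange(1, 10_000_000), size=2000, replace=False))
    layout = [("S0", "chr1", 3_000_000, 5_000_000)]
    ds, truth = paint_roh(layout, {"chr1": rng_positions}, background_het_rate=0.3, seed=1)
    segs = call_roh(ds, ROHConfig())
    assert len(segs) == 1
    seg = segs[0]
    w = ROHConfig().window_snp
    inside = (rng_positions >= 3_000_000) & (rng_positions <= 5_000_000)
    painted_idx = np.flatnonzero(inside)
    start_idx = int(np.searchsorted(rng_positions, seg.start_bp))
    end_idx = int(np.searchsorted(rng_positions, seg.end_bp))
    assert abs(start_idx - painted_idx[0]) <= w - 1
    assert abs(end_idx - painted_idx[-1]) <= w - 1


def test_het_monotonicity_on_froh():
    """Converting a homozygous call to HET never lengthens ROH coverage."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        genos, pos, cfg = random_instance(rng)
        ds = make_dataset(genos[None, :], positions=pos)
        before = sum(s.length_bp for s in call_roh(ds, cfg))
        hom_idx = np.flatnonzero((genos == HOM_REF) | (genos == HOM_ALT))
        if hom_idx.size == 0:
            continue
        flip = genos.copy()
        flip[hom_idx[rng.integers(hom_idx.size)]] = HET
        ds2 = make_dataset(flip[None, :], positions=pos)
        after = sum(s.length_bp for s in call_roh(ds2, cfg))
        assert after <= before


def test_segments_satisfy_invariants(small_cohort):
    cfg, (ds, _, _) = small_cohort
    roh_cfg = ROHConfig()
    segs = call_roh(ds, roh_cfg)
    by_key = {}
    for s in segs:
        assert s.end_bp >= s.start_bp
        assert s.length_bp >= roh_cfg.min_kb * 1000
        assert s.n_snps >= roh_cfg.min_snp
        assert s.length_bp / s.n_snps <= roh_cfg.max_density_kb_per_snp * 1000
        by_key.setdefault((s.sample_id, s.chromosome), []).append(s)
    for segs_k in by_key.values():
        segs_k.sort(key=lambda s: s.start_bp)
        for s1, s2 in zip(segs_k, segs_k[1:]):
            assert s2.start_bp > s1.end_bp  # disjoint


def test_true_tract_recall(small_cohort):
    """Called ROH recover >= 80% of the base pairs of true autozygous
    tracts longer than 1 Mb."""
    cfg, (ds, _, truth) = small_cohort
    segs = call_roh(ds, ROHConfig())
    called = {}
    for s in segs:
        called.setdefault((s.sample_id, s.chromosome), []).append((s.start_bp, s.end_bp))
    covered = total = 0
    for t in truth.true_roh:
        if t.length_bp < 1_000_000:
            continue
        total += t.length_bp
        for (a, b) in called.get((t.sample_id, t.chromosome), []):
            lo, hi = max(a, t.start_bp), min(b, t.end_bp)
            if hi >= lo:
                covered += hi - lo + 1
    assert total > 0, "fixture must contain tracts >= 1 Mb"
    assert covered / total >= 0.8


def test_compute_froh_arithmetic():
    seg = ROHSegment("S0", "chr1", 1, 2_440_000, 100, 0, 0)
    tab = compute_froh([seg], 2_440_000_000)
    assert tab.loc[0, "froh"] == pytest.approx(0.001)
    empty = compute_froh([], 2_440_000_000, sample_ids=["S0"])
    assert empty.loc[0, "froh"] == 0.0
    full = compute_froh([ROHSegment("S0", "chr1", 1, 1000, 10, 0, 0)], 1000)
    assert full.loc[0, "froh"] == 1.0
    with pytest.raises(ValueError):
        compute_froh([], 0)
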