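"""Load components, fixed-allele attribution, nucleotide diversity, Rxy,
management contrasts."""

import numpy as np
import pytest
from scipy import stats

from rohload import (HET, HOM_ALT, HOM_REF, MISSING, compute_loads,
                     fixed_attribution, group_contrast, nucleotide_diversity, rxy)
from conftest import make_dataset


def test_compute_loads_counting_example():
    g = np.array([[HET, HET, HOM_ALT, HOM_REF, MISSING]], dtype=np.int8)
    ds = make_dataset(g, impact_class="LOF", polarized=True)
    row = compute_loads(ds).set_index("impact_class").loc["LOF"]
    assert (row["het_load"], row["hom_load"], row["total_derived"]) == (2, 1, 4)


def test_compute_loads_requires_polarized():
    ds = make_dataset(np.zeros((1, 3), dtype=np.int8), polarized=False)
    with pytest.raises(ValueError, match="polarized"):
        compute_loads(ds)


def test_load_identity_holds_everywhere(small_cohort):
    from rohload import polarize
    _, (ds, anc, _) = small_cohort
    ds_pol, _ = polarize(ds, anc)
    loads = compute_loads(ds_pol)
    assert (loads["total_derived"] == 2 * loads["hom_load"] + loads["het_load"]).all()
    all_ref = make_dataset(np.zeros((1, 4), dtype=np.int8), polarized=True)
    row = compute_loads(all_ref).iloc[0]
    assert row["het_load"] == row["hom_load"] == row["total_derived"] == 0


def test_fixed_attribution_example():
    # 3 individuals, 2 sites: site0 fixed derived-homozygous; site1 segregating
    # with one extra derived homozygote
    g = np.array([[HOM_ALT, HOM_ALT],
                  [HOM_ALT, HOM_REF],
                  [HOM_ALT, HET]], dtype=np.int8)
    ds = make_dataset(g, impact_class="LOF", polarized=True,
                      populations=["P1"] * 3)
    out = fixed_attribution(ds).set_index("impact_class").loc["LOF"]
    assert out["n_hom_genotypes_total"] == 4
    assert out["n_hom_from_fixed"] == 3
    assert out["pct_from_fixed"] == pytest.approx(75.0)


def test_fixed_attribution_no_homozygotes_flagged():
    g = np.array([[HET, HOM_REF], [HOM_REF, HET], [HET, HET]], dtype=np.int8)
    ds = make_dataset(g, impact_class="MISSENSE", polarized=True, populations=["P1"] * 3)
    out = fixed_attribution(ds).set_index("impact_class").loc["MISSENSE"]
    assert out["flag_no_homozygotes"]
    assert out["pct_from_fixed"] == 0.0


def test_fixed_attribution_brute_force():
    rng = np.random.default_rng(8)
    g = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(6, 20),
                   p=[0.3, 0.25, 0.4, 0.05]).astype(np.int8)
    cls = rng.choice(["LOF", "MISSENSE", "INTERGENIC"], size=20)
    ds = make_dataset(g, impact_class=list(cls), polarized=True, populations=["P1"] * 6)
    out = fixed_attribution(ds)
    for c in ("LOF", "MISSENSE", "INTERGENIC"):
        total = fixed = 0
        for j in range(20):
            if cls[j] != c:
                continue
            col = g[:, j]
            called = col[col != MISSING]
            is_fixed = called.size > 0 and (called == HOM_ALT).all()
            n_hom = int((col == HOM_ALT).sum())
            total += n_hom
            if is_fixed:
                fixed += n_hom
        row = out.set_index("impact_class").loc[c]
        assert (row["n_hom_genotypes_total"], row["n_hom_from_fixed"]) == (total, fixed)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def test_pi_single_site_example():
    # 2 diploids, genotypes HOM_REF/HOM_ALT: alleles (0,0,1,1); 4 of the 6
    # allele pairs differ -> pi = 2*2*2/(4*3) = 2/3
    g = np.array([[HOM_REF], [HOM_ALT]], dtype=np.int8)
    ds = make_dataset(g)
    res = nucleotide_diversity(ds)
    assert res["pi"] == pytest.approx(2 / 3)


def test_pi_monomorphic_zero_and_callable_denominator():
    g = np.zeros((3, 4), dtype=np.int8)
    g[0, 0] = HET
    ds = make_dataset(g)
    res = nucleotide_diversity(ds, callable_sites=100)
    assert res["pi"] == pytest.approx((2 * 1 * 5 / (6 * 5)) / 100)
    assert not res["polymorphic_only"]


def test_pi_matches_pairwise_difference_oracle():
    rng = np.random.default_rng(12)
    g = rng.choice([HOM_REF, HET, HOM_ALT], size=(5, 10)).astype(np.int8)
    ds = make_dataset(g)
    res = nucleotide_diversity(ds)
    # oracle: mean pairwise allele differences over all 2n*(2n-1)/2 allele pairs
    total = 0.0
    for j in range(10):
        alleles = []
        for i in range(5):
            alleles += {HOM_REF: [0, 0], HET: [0, 1], HOM_ALT: [1, 1]}[int(g[i, j])]
        n = len(alleles)
        diff = sum(a != b for i, a in enumerate(alleles) for b in alleles[i + 1:])
        total += diff / (n * (n - 1) / 2)
    assert res["sum_pi_sites"] == pytest.approx(total)


def test_pi_orientation_invariant():
    g = np.array([[HOM_REF, HOM_ALT], [HOM_ALT, HOM_REF], [HET, HET]], dtype=np.int8)
    flipped = g.copy()
    flipped[g == HOM_REF] = HOM_ALT
    flipped[g == HOM_ALT] = HOM_REF
    a = nucleotide_diversity(make_dataset(g))
    b = nucleotide_diversity(make_dataset(flipped))
    assert a["pi"] == pytest.approx(b["pi"])


# ---------------------------------------------------------------------------
# Rxy
# ---------------------------------------------------------------------------

def rxy_fixture(fx_class, fy_class, n_intergenic=4):
    """Two groups of 2 diploids each; class-site frequencies set exactly via
    genotypes (frequencies in quarters); intergenic sites identical across
    groups."""
    def geno_for_freq(f):
        # 4 alleles per group; f in {0, .25, .5, .75, 1}
        counts = int(round(f * 4))
        g = [HOM_REF, HOM_REF]
        if counts == 1:
            g = [HET, HOM_REF]
        elif counts == 2:
            g = [HOM_ALT, HOM_REF]
        elif counts == 3:
            g = [HOM_ALT, HET]
        elif counts == 4:
            g = [HOM_ALT, HOM_ALT]
        return g
    n_class = len(fx_class)
    gx = np.array([geno_for_freq(f) for f in fx_class]).T
    gy = np.array([geno_for_freq(f) for f in fy_class]).T
    inter = np.tile([HET, HOM_ALT], (n_intergenic, 1)).T
    g = np.concatenate([np.vstack([gx, gy]),
                        np.vstack([inter, inter])], axis=1).astype(np.int8)
    classes = ["LOF"] * n_class + ["INTERGENIC"] * n_intergenic
    ds = make_dataset(g, impact_class=classes, polarized=True,
                      populations=["PX", "PX", "PY", "PY"],
                      management=["MANAGED", "MANAGED", "UNMANAGED", "UNMANAGED"])
    x = ["S0", "S1"]
    y = ["S2", "S3"]
    return ds, x, y


def test_rxy_identical_groups_is_one():
    ds, x, y = rxy_fixture([0.5, 0.25], [0.5, 0.25])
    res = rxy(ds, x, y, "LOF", n_boot=50, seed=0)
    assert res.rxy == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)


def test_rxy_hand_computed_two_site_example():
    # symmetric case first
    ds, x, y = rxy_fixture([0.5, 0.0], [0.0, 0.5])
    assert rxy(ds, x, y, "LOF", n_boot=10, seed=0).rxy == pytest.approx(1.0)
    # perturb the first site to fixation in X: L_XnotY = 1.0, L_YnotX = 0.5
    ds2, x, y = rxy_fixture([1.0, 0.0], [0.0, 0.5])
    assert rxy(ds2, x, y, "LOF", n_boot=10, seed=0).rxy == pytest.approx(2.0)


def test_rxy_group_swap_reciprocal():
    ds, x, y = rxy_fixture([0.75, 0.25, 0.5], [0.25, 0.5, 0.25])
    a = rxy(ds, x, y, "LOF", n_boot=10, seed=0).rxy
    b = rxy(ds, y, x, "LOF", n_boot=10, seed=0).rxy
    assert a == pytest.approx(1 / b)


def test_rxy_deterministic_bootstrap():
    ds, x, y = rxy_fixture([0.75, 0.25, 0.5], [0.25, 0.5, 0.25])
    a = rxy(ds, x, y, "LOF", n_boot=100, seed=5)
    b = rxy(ds, x, y, "LOF", n_boot=100, seed=5)
    assert (a.rxy, a.ci_low, a.ci_high) == (b.rxy, b.ci_low, b.ci_high)


def test_rxy_zero_denominator_fatal():
    ds, x, y = rxy_fixture([0.0], [0.0])
    with pytest.raises(ValueError, match="Rxy undefined"):
        rxy(ds, x, y, "LOF", n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def test_group_contrast_matches_t_test():
    values = [1.0, 2.0, 3.0, 4.0]
    mgmt = ["UNMANAGED", "UNMANAGED", "MANAGED", "MANAGED"]
    res = group_contrast(values, mgmt)
    assert res.beta == pytest.approx(2.0)
    t, p = stats.ttest_ind([3.0, 4.0], [1.0, 2.0], equal_var=True)
    assert res.p_value == pytest.approx(p)
    assert res.p_value == pytest.approx(0.10557, rel=1e-3)
    assert res.ci_low < res.beta < res.ci_high


def test_group_contrast_degenerate_flagged():
    res = group_contrast([1.0, 1.0, 3.0, 3.0],
                         ["UNMANAGED", "UNMANAGED", "MANAGED", "MANAGED"])
    assert res.beta == pytest.approx(2.0)
    assert res.degenerate and np.isnan(res.p_value)


def test_group_contrast_all_equal_zero_beta():
    res = group_contrast([2.0] * 6, ["UNMANAGED"] * 3 + ["MANAGED"] * 3)
    assert res.beta == pytest.approx(0.0)
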