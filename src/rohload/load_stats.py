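"""Mutation-load statistics, nucleotide diversity, Rxy, and group contrasts.

All operations here require a polarized dataset (alternate allele = derived
allele) except :func:`nucleotide_diversity` and :func:`group_contrast`, which
are polarization-invariant.

Load components per individual and impact class:

* heterozygous load — number of heterozygous genotypes (masked load under
  recessivity: the potential for future inbreeding to expose variants);
* homozygous load — number of derived-homozygous genotypes (realized load
  under recessivity);
* total derived alleles — 2 x hom + het (the additive-load measure).

Rxy compares the derived-allele burden of a variant class between two groups
X and Y, standardized by a neutral (intergenic) SNP set:

    L_{X notin Y}(S) = sum_i f_i^X (1 - f_i^Y)   over sites i in S
    Rxy = [L_XnotY(class) / L_XnotY(intergenic)] /
          [L_YnotX(class) / L_YnotX(intergenic)]

Rxy > 1: excess derived alleles of the class in X relative to Y; the
intergenic standardization cancels group-specific branch length / reference
bias. CIs are a percentile bootstrap over sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import HET, HOM_ALT, MISSING, GenotypeDataset

LOAD_CLASSES = ("LOF", "MISSENSE", "INTERGENIC")


def _require_polarized(dataset: GenotypeDataset) -> None:
    if dataset.n_sites and not dataset.sites["polarized"].all():
        raise ValueError("dataset must be polarized (alt = derived) for load statistics")


# ---------------------------------------------------------------------------
# load components
# ---------------------------------------------------------------------------

def compute_loads(dataset: GenotypeDataset, classes=LOAD_CLASSES) -> pd.DataFrame:
    """Per-(sample, impact class) load components.

    Returns columns sample_id, impact_class, het_load, hom_load,
    total_derived. Missing genotypes are excluded from every count.
    """
    _require_polarized(dataset)
    g = dataset.genotypes
    site_class = dataset.sites["impact_class"].to_numpy()
    rows = []
    for cls in classes:
        m = site_class == cls
        het = (g[:, m] == HET).sum(axis=1)
        hom = (g[:, m] == HOM_ALT).sum(axis=1)
        for s, sid in enumerate(dataset.samples["sample_id"]):
            rows.append((sid, cls, int(het[s]), int(hom[s]), int(2 * hom[s] + het[s])))
    return pd.DataFrame(rows, columns=["sample_id", "impact_class",
                                       "het_load", "hom_load", "total_derived"])


def fixed_attribution(dataset: GenotypeDataset, classes=LOAD_CLASSES) -> pd.DataFrame:
    """Fraction of derived-homozygous genotypes attributable to alleles fixed
    within each population.

    A site is "fixed" in a population when every non-missing genotype of that
    population's members is derived-homozygous. Columns: population,
    impact_class, n_hom_genotypes_total, n_hom_from_fixed, pct_from_fixed,
    flag_no_homozygotes.
    """
    _require_polarized(dataset)
    g = dataset.genotypes
    site_class = dataset.sites["impact_class"].to_numpy()
    rows = []
    for pop, grp in dataset.samples.groupby("population_id", sort=True):
        sidx = grp.index.to_numpy()
        sub = g[sidx]
        called = sub != MISSING
        hom = sub == HOM_ALT
        # fixed: every non-missing genotype is derived-homozygous (all-missing sites excluded)
        fixed = (hom | ~called).all(axis=0) & called.any(axis=0)
        for cls in classes:
            m = site_class == cls
            total = int(hom[:, m].sum())
            from_fixed = int(hom[:, m & fixed].sum())
            flag = total == 0
            pct = 0.0 if flag else 100.0 * from_fixed / total
            rows.append((pop, cls, total, from_fixed, pct, flag))
    return pd.DataFrame(rows, columns=["population", "impact_class",
                                       "n_hom_genotypes_total", "n_hom_from_fixed",
                                       "pct_from_fixed", "flag_no_homozygotes"])


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(dataset: GenotypeDataset, sample_ids=None,
                         callable_sites: int | None = None) -> dict:
    """Genotype-based per-site pairwise nucleotide diversity (approximation).

    Per site, with n non-missing alleles of which d carry the alternate:
    pi_site = 2 d (n - d) / (n (n - 1)). The reported value is the sum over
    sites divided by ``callable_sites`` when supplied (monomorphic sites in
    the denominator), else by the number of usable polymorphic-table sites
    (flagged ``polymorphic_only``). The estimator is symmetric in d and n-d,
    so it is invariant to allele orientation.
    """
    if sample_ids is None:
        sample_ids = dataset.sample_ids
    if len(sample_ids) < 2:
        raise ValueError("nucleotide diversity needs >= 2 individuals")
    g = dataset.genotypes[dataset.sample_indices(sample_ids)]
    called = g != MISSING
    n = 2 * called.sum(axis=0)
    d = np.where(g == HET, 1, 0).sum(axis=0) + 2 * np.where(g == HOM_ALT, 1, 0).sum(axis=0)
    usable = n >= 2
    n_skipped = int((~usable).sum())
    nn = n[usable].astype(float)
    dd = d[usable].astype(float)
    pi_sites = 2.0 * dd * (nn - dd) / (nn * (nn - 1.0))
    total = float(pi_sites.sum())
    if callable_sites is not None:
        if callable_sites <= 0:
            raise ValueError("callable_sites must be positive")
        denom = callable_sites
        polymorphic_only = False
    else:
        denom = int(usable.sum())
        polymorphic_only = True
    return {
        "pi": total / denom if denom else float("nan"),
        "sum_pi_sites": total,
        "n_sites_used": int(usable.sum()),
        "n_sites_skipped": n_skipped,
        "denominator": denom,
        "polymorphic_only": polymorphic_only,
    }


# ---------------------------------------------------------------------------
# Rxy
# ---------------------------------------------------------------------------

@dataclass
class RxyResult:
    impact_class: str
    rxy: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_class_sites: int
    n_intergenic_sites: int


def _derived_freqs(dataset: GenotypeDataset, sample_ids, site_mask):
    g = dataset.genotypes[dataset.sample_indices(sample_ids)][:, site_mask]
    called = g != MISSING
    n = 2 * called.sum(axis=0)
    d = np.where(g == HET, 1, 0).sum(axis=0) + 2 * np.where(g == HOM_ALT, 1, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    return f


def _l_terms(fx, fy):
    ok = np.isfinite(fx) & np.isfinite(fy)
    return float(np.sum(fx[ok] * (1 - fy[ok]))), float(np.sum(fy[ok] * (1 - fx[ok])))


def rxy(dataset: GenotypeDataset, group_x, group_y, impact_class: str,
        n_boot: int = 100, seed: int = 0,
        neutral_class: str = "INTERGENIC") -> RxyResult:
    """Rxy of ``impact_class`` in group X over group Y, standardized by the
    neutral class, with a percentile bootstrap CI over sites.

    Both the focal-class and the neutral-class site sets are resampled with
    replacement in each bootstrap replicate. Swapping X and Y maps the
    statistic to its exact reciprocal. A zero numerator/denominator term (no
    derived alleles exclusive to one group in one of the site sets) is fatal
    with a diagnostic.
    """
    _require_polarized(dataset)
    group_x, group_y = list(group_x), list(group_y)
    if not group_x or not group_y:
        raise ValueError("both groups must be non-empty")
    site_class = dataset.sites["impact_class"].to_numpy()
    m_class = site_class == impact_class
    m_neut = site_class == neutral_class
    if not m_neut.any():
        raise ValueError(f"no {neutral_class} sites available for standardization")
    if not m_class.any():
        raise ValueError(f"no sites of class {impact_class!r}")

    fx_c = _derived_freqs(dataset, group_x, m_class)
    fy_c = _derived_freqs(dataset, group_y, m_class)
    fx_n = _derived_freqs(dataset, group_x, m_neut)
    fy_n = _derived_freqs(dataset, group_y, m_neut)

    def statistic(ci, ni, strict):
        lxy_c, lyx_c = _l_terms(fx_c[ci], fy_c[ci])
        lxy_n, lyx_n = _l_terms(fx_n[ni], fy_n[ni])
        if strict:
            for name, v in (("L_XnotY(class)", lxy_c), ("L_XnotY(neutral)", lxy_n),
                            ("L_YnotX(class)", lyx_c), ("L_YnotX(neutral)", lyx_n)):
                if v == 0.0:
                    raise ValueError(f"Rxy undefined: {name} is zero "
                                     f"(class={impact_class}, neutral={neutral_class})")
        if lxy_n == 0.0 or lyx_n == 0.0:
            return float("nan")  # neutral resample carries no information
        num, den = lxy_c / lxy_n, lyx_c / lyx_n
        if den == 0.0:
            return float("inf") if num > 0 else float("nan")
        return num / den

    all_c = np.arange(fx_c.size)
    all_n = np.arange(fx_n.size)
    point = statistic(all_c, all_n, strict=True)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.integers(0, fx_c.size, size=fx_c.size)
        ni = rng.integers(0, fx_n.size, size=fx_n.size)
        reps[b] = statistic(ci, ni, strict=False)
    reps = reps[~np.isnan(reps)]
    # nearest-rank percentiles stay finite/exact when replicates include inf
    lo, hi = np.percentile(reps, [2.5, 97.5], method="nearest")
    return RxyResult(impact_class=impact_class, rxy=point, ci_low=float(lo),
                     ci_high=float(hi), n_boot=n_boot, seed=seed,
                     n_class_sites=int(m_class.sum()),
                     n_intergenic_sites=int(m_neut.sum()))


# ---------------------------------------------------------------------------
# management contrasts
# ---------------------------------------------------------------------------

@dataclass
class GroupContrast:
    response: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    degenerate: bool = False


def group_contrast(values, management, response: str = "value") -> GroupContrast:
    """OLS of a per-individual response on a binary management indicator
    (UNMANAGED = 0, MANAGED = 1).

    beta is the MANAGED minus UNMANAGED effect; the 95% CI uses the t
    distribution with n - 2 df. Zero residual variance (each group internally
    constant) leaves p undefined and sets the degenerate flag.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    management = list(management)
    x = np.array([1.0 if str(m).upper() == "MANAGED" else 0.0 for m in management])
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ValueError("both management groups need >= 2 samples")
    model = sm.OLS(values, sm.add_constant(x)).fit()
    beta = float(model.params[1])
    resid_var = float(model.ssr)
    if resid_var <= np.finfo(float).eps * max(1.0, float(np.sum(values**2))):
        return GroupContrast(response=response, beta=beta, ci_low=beta, ci_high=beta,
                             p_value=float("nan"), n=len(values), degenerate=True)
    lo, hi = model.conf_int(alpha=0.05)[1]
    return GroupContrast(response=response, beta=beta, ci_low=float(lo),
                         ci_high=float(hi), p_value=float(model.pvalues[1]),
                         n=len(values))
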