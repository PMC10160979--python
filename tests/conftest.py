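import numpy as np
import pandas as pd
import pytest

from rohload import GenotypeDataset, SimConfig, simulate_population


def make_dataset(genotypes, positions=None, chrom="chr1", sample_prefix="S",
                 qual=50.0, mean_depth=10.0, impact_class="OTHER",
                 polarized=False, management=None, populations=None, **site_overrides):
    """Build a small GenotypeDataset from a genotype matrix (samples x sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    chroms = [chrom] * n_sites if isinstance(chrom, str) else list(chrom)
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
        "qual": np.broadcast_to(np.asarray(qual, dtype=float), n_sites).copy(),
        "mean_depth": np.broadcast_to(np.asarray(mean_depth, dtype=float), n_sites).copy(),
        "impact_class": (list(impact_class) if not isinstance(impact_class, str)
                         else [impact_class] * n_sites),
        "polarized": polarized,
    })
    for col, val in site_overrides.items():
        sites[col] = val
    if management is None:
        management = ["MANAGED"] * n_samples
    if populations is None:
        populations = [f"POP_{m}" for m in management]
    samples = pd.DataFrame({
        "sample_id": [f"{sample_prefix}{i}" for i in range(n_samples)],
        "population_id": populations,
        "management": management,
    })
    return GenotypeDataset(sites, samples, g)


@pytest.fixture(scope="session")
def small_cohort():
    """A two-population simulated cohort reused by several test modules."""
    cfg = SimConfig(
        chromosome_lengths=(5_000_000, 5_000_000),
        ne_trajectory=((30, 100),),
        n_sample_per_population={"A": 8, "B": 8},
        population_management={"A": "MANAGED", "B": "UNMANAGED"},
        seed=42,
    )
    return cfg, simulate_population(cfg)
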