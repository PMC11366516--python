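import numpy as np
import pytest

from singlestep.reml import VarianceComponents
from singlestep.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def litter_vc():
    """Variance components of a lowly heritable litter trait (h2 ~ 0.127)."""
    return VarianceComponents(sigma_a2=0.9, sigma_pe2=0.68, sigma_e2=5.49)


@pytest.fixture(scope="session")
def qtl_bundle():
    """Small simulated study with one 25%-variance QTL, shared across tests."""
    cfg = SimConfig(
        n_founders=80, n_generations=2, dams_per_sire=4, offspring_per_dam=4,
        n_chromosomes=5, chrom_length_bp=50_000_000, n_markers=400,
        n_qtl=1, qtl_variance_fractions=(0.25,), genotyping_fraction=0.8,
        seed=42,
    )
    return simulate_dataset(cfg)


def random_pedigree(n_founders: int, n_total: int, seed: int):
    """Random cycle-free pedigree records: each non-founder draws parents
    among older animals (self-mating of a pair allowed, selfing not)."""
    rng = np.random.default_rng(seed)
    recs = [(f"A{i}", "0", "0") for i in range(n_founders)]
    for i in range(n_founders, n_total):
        s, d = rng.integers(0, i, size=2)
        recs.append((f"A{i}", f"A{s}", f"A{d}"))
    return recs
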