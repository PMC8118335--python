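import numpy as np
import pytest

from breedrisk.io import GenotypeMatrix
from breedrisk.synthetic import CohortConfig, simulate_genotypes


def make_genotype_matrix(dosages, chromosomes=None, positions=None,
                         ref=None, alt=None):
    """Build a GenotypeMatrix from a raw (samples x snps) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(p)],
        chromosomes=np.array(chromosomes if chromosomes is not None else ["chr1"] * p, dtype=object),
        positions=np.asarray(positions if positions is not None else (np.arange(p) + 1) * 1000),
        ref=np.array(ref if ref is not None else ["A"] * p, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * p, dtype=object),
        dosages=dosages,
    )


def null_genotypes(n, p, seed=0, freq_low=0.1, freq_high=0.9):
    """Unstructured genotypes: independent SNPs at uniform-random frequencies."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_low, freq_high, size=p)
    return make_genotype_matrix(rng.binomial(2, freqs, size=(n, p)))


@pytest.fixture(scope="session")
def desk_cohort():
    """A small simulated breed cohort shared across tests."""
    cfg = CohortConfig.desk_scale(
        n_snps=800, n_chromosomes=4, n_cases=60, n_controls=50, seed=42
    )
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth
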