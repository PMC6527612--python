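import numpy as np
import pytest

from mrnm import GRM, compute_grm, simulate_genotypes


@pytest.fixture(scope="session")
def grm_study() -> GRM:
    """Study-scale GRM (n=1000, 5000 simulated SNPs) shared across experiments."""
    A = compute_grm(simulate_genotypes(1000, 5000, seed=2024), maf_min=0.01)
    A.eig()
    return A


@pytest.fixture(scope="session")
def grm_ks() -> GRM:
    """n=500 GRM for the p-value calibration studies."""
    A = compute_grm(simulate_genotypes(500, 5000, seed=77), maf_min=0.01)
    A.eig()
    return A


@pytest.fixture(scope="session")
def grm_small() -> GRM:
    """Small GRM for unit-level fitting tests."""
    A = compute_grm(simulate_genotypes(120, 600, seed=5), maf_min=0.01)
    A.eig()
    return A


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
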