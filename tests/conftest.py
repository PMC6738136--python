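from pathlib import Path

import numpy as np
import pytest

from straindiverge import simulate as sim

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_vcf() -> Path:
    return DATA_DIR / "toy.vcf"


@pytest.fixture(scope="session")
def small_dataset() -> sim.SimulatedDataset:
    """Three small strains (150 kb, 80 genes) shared across test modules."""
    specs = [
        sim.StrainSpec(name="alpha", ploidy=3, n_exclusive_genes=4, seed=50),
        sim.StrainSpec(name="beta", ploidy=2, n_exclusive_genes=4, seed=51),
        sim.StrainSpec(name="gamma", ploidy=4, n_exclusive_genes=4, seed=52),
    ]
    return sim.simulate_strain_set(
        haploid_bp=150_000, n_genes=80, specs=specs, seed=3
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
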