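import numpy as np
import pytest

from regengwas.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_structured():
    """Small structured population shared by read-only tests."""
    cfg = SimulationConfig(n_samples=120, n_snps=400, n_subpops=3, fst=0.2,
                           h2_poly=0.0, seed=42,
                           chrom_lengths={"Chr01": 200_000, "Chr02": 200_000})
    return cfg, simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
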