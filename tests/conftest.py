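import numpy as np
import pytest

from hapgwas.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """120-line, 2-chromosome panel with moderate LD, no missing data."""
    cfg = SimConfig(
        n_lines=120,
        n_subpops=2,
        fst=0.15,
        chromosomes=[("1A", 80.0), ("2B", 80.0)],
        markers_per_chrom=80,
        ld_rho=0.5,
        missing_rate=0.0,
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def structured_panel():
    """169-line, 4-subpopulation panel used by structure/association tests."""
    cfg = SimConfig(
        n_lines=169,
        n_subpops=4,
        fst=0.2,
        chromosomes=[("1A", 100.0), ("2A", 100.0), ("3B", 100.0)],
        markers_per_chrom=150,
        ld_rho=0.5,
        h2_polygenic=0.4,
        noise_sd=1.0,
        seed=7,
    )
    return simulate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
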