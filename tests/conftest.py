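import numpy as np
import pytest

from padscan.core import GenomeLayout
from padscan.domains import IslandParams
from padscan.pipeline import run_domain_recovery
from padscan.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Two 1-Mb chromosomes with central pericentromeres."""
    return GenomeLayout(
        chromosomes=[("chr1", 1_000_000), ("chr2", 1_000_000)],
        pericentromere={"chr1": (400_000, 600_000), "chr2": (400_000, 600_000)},
        centromere={"chr1": (460_000, 540_000), "chr2": (460_000, 540_000)},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (5 chromosomes x 3 Mb), fixed seed."""
    return generate_dataset(SimulationConfig(seed=7),
                            genotypes=("WT", "cmt2-like", "drm12-like"))


@pytest.fixture(scope="session")
def recovery():
    """The headline domain-recovery run on the default configuration."""
    return run_domain_recovery(SimulationConfig(seed=7), IslandParams())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
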