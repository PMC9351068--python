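from pathlib import Path

import numpy as np
import pytest

from clonemap import Chromosome, GenomeConfig, default_toy_genome

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def toy_genome() -> GenomeConfig:
    return default_toy_genome()


@pytest.fixture
def chrt_genome() -> GenomeConfig:
    """Single 10-Mb chromosome with a mid-chromosome centromere."""
    return GenomeConfig(
        chromosomes=[Chromosome("chrT", 10_000_000)],
        centromeres={"chrT": (4_000_000, 4_500_000)},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
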