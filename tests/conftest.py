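import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spaceracq import CRISPRLocus, GeneratorConfig, generate_dataset
from spaceracq.synthetic import DEFAULT_LEADER, DEFAULT_REPEAT


@pytest.fixture(scope="session")
def small_dataset():
    """A mixed-mode, mixed-source dataset small enough for unit tests."""
    cfg = GeneratorConfig(
        seed=42,
        n_clones=40,
        replicon_lengths={"host": 20000, "plasmid": 6000, "virus": 10000},
        mode_weights={
            "canonical": 0.5,
            "flip": 0.25,
            "slip": 0.1,
            "mismatch": 0.1,
            "other": 0.05,
        },
        multiplicity_weights={0: 0.1, 1: 0.5, 2: 0.2, 3: 0.15, 4: 0.05},
        source_weights={"host": 0.2, "plasmid": 0.4, "virus": 0.4},
    )
    return generate_dataset(cfg)


@pytest.fixture()
def toy_locus():
    spacers = (
        "ACGTTGCAGGTTACGATCCGTGCAATTGCAGGCTA",
        "TTGACCATGGACGTTCAAGGTCCATAGCTAGGCTA",
        "GGATCCTTAACGGCATTAGCCGGTAATCGATCGTA",
    )
    return CRISPRLocus(DEFAULT_LEADER, DEFAULT_REPEAT, spacers)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
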