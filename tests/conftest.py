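import numpy as np
import pytest

from mitocms.config import PipelineConfig
from mitocms.simulate import SimulationSpec, simulate


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free body + TAA."""
    body = "".join(rng.choice([c for c in SENSE if c != "ATG"], size=n_codons))
    return "ATG" + body + "TAA"


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim():
    """One default synthetic trio shared across tests."""
    return simulate(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A smaller trio (proportionally smaller planted events) for heavier tests."""
    from mitocms.simulate import PlantedRepeatSpec, PlantedUniqueSpec

    return simulate(SimulationSpec(
        ancestor_length=30_000,
        n_genes=8,
        planted_repeats=[
            PlantedRepeatSpec(1000, "direct", 2),
            PlantedRepeatSpec(600, "inverted", 2),
        ],
        planted_unique=[
            PlantedUniqueSpec(1500, 1, (45,), 402, True),
            PlantedUniqueSpec(1200, 1, (60,), 402, False),
        ],
        seed=7,
    ))
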