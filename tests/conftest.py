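import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phyletic.io_formats import GeneModel, GenomeEntry, GenomeSet

_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, 20, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_genome_set(tags, groups=None) -> GenomeSet:
    return GenomeSet(
        entries=[GenomeEntry(tag=t, name=t) for t in tags],
        groups={k: tuple(v) for k, v in (groups or {}).items()},
    )


def make_model(gid: str, tag: str, seq: str) -> GeneModel:
    return GeneModel(id=gid, genome=tag, sequence=seq)
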