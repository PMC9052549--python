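import numpy as np
import pytest

from bmctyper import (build_library, build_profile, generate_world,
                      make_registry)
from bmctyper.alphabet import AMINO_ACIDS


@pytest.fixture(scope="session")
def small_world():
    """3 synthetic types, 2 loci each, 12 genes per locus."""
    return generate_world(seed=11, n_types=3, loci_per_type=2, locus_len=12)


@pytest.fixture(scope="session")
def small_library(small_world):
    return build_library(small_world)


@pytest.fixture(scope="session")
def small_registry(small_world):
    return make_registry(small_world)


@pytest.fixture(scope="session")
def peaked_profile():
    """A sharply peaked profile: 20 identical ungapped training rows."""
    motif = "MKVLAADWGTTNFRAYLVDE"
    return build_profile([motif] * 20, "H_azure")


@pytest.fixture(scope="session")
def world_dir(tmp_path_factory, small_world):
    """The small world written to disk for CLI tests."""
    from bmctyper import write_world

    out = tmp_path_factory.mktemp("world")
    write_world(small_world, out)
    return out


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS)) for _ in range(length))
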