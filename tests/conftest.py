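import numpy as np
import pytest

from tilefold.io import SynthSpec, synth_rna

#: tile sizes of the desk-scale fixture grid
FIXTURE_TILE_SIZES = [(1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 3, 5), (1, 4, 2), (3, 3, 3)]


def seeded_sequence(n: int, seed: int):
    """Deterministic random strand of length n."""
    return synth_rna(SynthSpec(length=n, seed=seed))


@pytest.fixture(scope="session")
def sequence_pool():
    """200 seeded strands with lengths spread over 2..64."""
    rng = np.random.default_rng(20180115)
    lengths = rng.integers(2, 65, size=200)
    return [seeded_sequence(int(n), seed=idx) for idx, n in enumerate(lengths)]


@pytest.fixture(scope="session")
def long_sequences():
    return {n: seeded_sequence(n, seed=n) for n in (128, 300)}
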