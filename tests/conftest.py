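import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_cds  # noqa: E402
from retrocomp.seq_io import CodingSequence  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cds_factory(rng):
    """Factory of random validated coding sequences (no internal stops)."""
    from retrocomp.genetic_code import SENSE_CODONS

    codons = list(SENSE_CODONS)

    def factory(n_codons: int, seed: int | None = None) -> CodingSequence:
        local = np.random.default_rng(seed) if seed is not None else rng
        seq = "ATG" + "".join(local.choice(codons, size=n_codons - 1))
        return make_cds(seq)

    return factory
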