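from __future__ import annotations

import numpy as np
import pytest

from orfdiv.io_formats import GenomeRecord

_BASES = "ACGT"


def random_genome(rng: np.random.Generator, length: int, circular: bool = False) -> GenomeRecord:
    seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    return GenomeRecord(id="rnd", sequence=seq, circular=circular)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genome() -> GenomeRecord:
    # ATG AAA TAG on the plus strand, frame 0
    return GenomeRecord(id="tiny", sequence="ATGAAATAG", circular=False)
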