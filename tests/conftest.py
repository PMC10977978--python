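import math
from collections import Counter

import numpy as np
import pytest

from her2het.fish import FISHSample


@pytest.fixture
def make_sample():
    """Factory: FISHSample from bare (erbb2, cep17) pairs."""

    def _make(pairs, patient_id="p1", timepoint="pre"):
        return FISHSample.from_counts(patient_id, timepoint, pairs)

    return _make


@pytest.fixture
def random_fish_pairs():
    """Factory: random (erbb2, cep17) pair lists of varied size/richness."""

    def _make(rng: np.random.Generator, n_min=5, n_max=200):
        n = int(rng.integers(n_min, n_max + 1))
        erbb2 = rng.integers(0, 25, size=n)
        cep17 = rng.integers(0, 8, size=n)
        return list(zip(erbb2.tolist(), cep17.tolist()))

    return _make


def brute_force_shannon(pairs):
    """Independent oracle: H and both equitability normalizations directly
    from the raw cell list, using math.fsum over an explicit tally."""
    tally = Counter(pairs)
    total = len(pairs)
    h = -math.fsum((n / total) * math.log(n / total) for n in tally.values())
    s = len(tally)
    e_species = 0.0 if s < 2 else h / math.log(s)
    e_cells = 0.0 if total < 2 else h / math.log(total)
    return h, e_species, e_cells
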