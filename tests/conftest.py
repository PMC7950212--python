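from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ciffrac.features import AMINO_ACIDS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_peptides(n: int, seed: int = 0, min_len: int = 7, max_len: int = 30) -> list:
    """Random standard-residue peptides for oracle comparisons."""
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    lengths = rng.integers(min_len, max_len + 1, n)
    return ["".join(rng.choice(alphabet, L)) for L in lengths]


@pytest.fixture
def peptides_50() -> list:
    return random_peptides(50, seed=42)
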