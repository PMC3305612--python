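import numpy as np
import pytest

from entroseq.signature import SequenceRecord
from entroseq.simulate import simulate_biased, simulate_zero_order


def random_sequence(rng: np.random.Generator, length: int,
                    with_ambiguity: bool = False) -> str:
    """Uniform random DNA string, optionally salted with N symbols."""
    alphabet = "ACGTN" if with_ambiguity else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_ambiguity else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def null_cohort():
    """30 zero-order sequences at mixed AT content (null for D_KL)."""
    return [simulate_zero_order(20_000, at, seed=100 + i, id=f"null_{i}")
            for i, at in enumerate(np.linspace(0.3, 0.7, 30))]


@pytest.fixture
def biased_record():
    return simulate_biased(100_000, 0.5, 0.8, seed=7, id="biased")
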