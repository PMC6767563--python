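import numpy as np
import pytest

from ecfmap import (build_validated_pwms, load_table1,
                    load_validated_promoters)


@pytest.fixture(scope="session")
def table1_entries():
    return load_table1()


@pytest.fixture(scope="session")
def validated_entries():
    return load_validated_promoters()


@pytest.fixture(scope="session")
def validated_pwms(validated_entries):
    return build_validated_pwms(validated_entries)


@pytest.fixture()
def gc_rng():
    """Seeded generator plus a GC-rich random-DNA helper."""
    rng = np.random.default_rng(20240917)

    def random_dna(length, gc=0.72):
        at = (1 - gc) / 2
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return rng.choice(bases, size=length,
                          p=[at, gc / 2, gc / 2, at]).tobytes().decode()

    return rng, random_dna
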