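import numpy as np
import pytest

from tfsigkit import (
    Direction,
    GeneId,
    SignatureRecord,
    SignatureTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_signature():
    return SignatureTable(
        [
            SignatureRecord(GeneId("A"), Direction.UP, True),
            SignatureRecord(GeneId("B"), Direction.DOWN, False),
            SignatureRecord(GeneId("C"), Direction.UP, True),
        ]
    )


def random_signature(rng, n=20, universe_prefix="R"):
    syms = rng.choice(np.arange(1, 10 * n), size=n, replace=False)
    return SignatureTable(
        [
            SignatureRecord(
                GeneId(f"{universe_prefix}{s:05d}"),
                Direction.UP if rng.random() < 0.5 else Direction.DOWN,
                bool(rng.random() < 0.4),
            )
            for s in syms
        ]
    )
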