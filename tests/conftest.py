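import random

import pytest

from screp.align import ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20260922)


def random_protein(rng: random.Random, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
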