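import numpy as np
import pytest

from biotrig.schema import BioTagset, EventTypeSchema
from biotrig.synth import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def mlee_schema():
    return EventTypeSchema.builtin("mlee")


@pytest.fixture(scope="session")
def small_schema():
    return EventTypeSchema(types=("Growth", "Localization"), name="small")


@pytest.fixture(scope="session")
def small_tagset(small_schema):
    return BioTagset.from_schema(small_schema)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small deterministic synthetic corpus shared across tests."""
    spec = SyntheticSpec()
    return generate_corpus(spec, 60, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_nonoverlapping_spans(rng, n, schema, max_spans=3):
    """Independent generator of valid span sets for round-trip tests."""
    from biotrig.schema import TriggerSpan

    spans = []
    cursor = 0
    for _ in range(int(rng.integers(0, max_spans + 1))):
        if cursor >= n:
            break
        start = int(rng.integers(cursor, n))
        end = int(rng.integers(start + 1, min(start + 3, n) + 1))
        spans.append(TriggerSpan(start, end, str(rng.choice(schema.types))))
        cursor = end
    return spans
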