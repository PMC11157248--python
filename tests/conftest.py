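import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from horscan import ArraySpec, CanonicalUnit, ConsensusQuery, build_array
from horscan.synthetic import CANONICAL_17MER_UNIT, WILLARD_10MER_UNIT

# the cascading 17mer of the worked examples: t1..t15, t1, t16
U17 = list(CANONICAL_17MER_UNIT)
U10 = list(WILLARD_10MER_UNIT)

# the canonical 36mer: rows t1,t16,t17,t2-t4 | t1,t16,t17,t2-t15 |
# t1,t16,t17,t2-t5,t18 | t11-t15  (18 distinct types, n = 36)
_t = lambda i: i - 1
U36 = (
    [_t(1), _t(16), _t(17)] + [_t(i) for i in range(2, 5)]
    + [_t(1), _t(16), _t(17)] + [_t(i) for i in range(2, 16)]
    + [_t(1), _t(16), _t(17)] + [_t(i) for i in range(2, 6)] + [_t(18)]
    + [_t(i) for i in range(11, 16)]
)
# dense-relabel so the unit is a valid generator spec (labels 0..17)
_seen: dict[int, int] = {}
U36 = [_seen.setdefault(x, len(_seen)) for x in U36]


@pytest.fixture(scope="session")
def unit17() -> CanonicalUnit:
    return CanonicalUnit(tuple(U17))


@pytest.fixture(scope="session")
def unit10() -> CanonicalUnit:
    return CanonicalUnit(tuple(U10))


@pytest.fixture(scope="session")
def unit36() -> CanonicalUnit:
    return CanonicalUnit(tuple(U36))


@pytest.fixture(scope="session")
def small_array():
    """A 10-copy cascading 17mer array with 1% mutation, plus its truth."""
    spec = ArraySpec(n_copies=10, per_base_mutation=0.01, seed=7)
    seq, truth = build_array(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def small_query(small_array) -> ConsensusQuery:
    _, _, truth = small_array
    return ConsensusQuery("ancestral", truth["query"])


def canon(labels) -> tuple[int, ...]:
    """Renumber a label sequence by first occurrence, for pattern equality."""
    seen: dict = {}
    return tuple(seen.setdefault(x, len(seen)) for x in labels)
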