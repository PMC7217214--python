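import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ladder_specs():
    from poolpcr.fixtures import x_ladder

    return x_ladder()


@pytest.fixture(scope="session")
def s1_spec():
    from poolpcr.fixtures import s1

    return s1()


@pytest.fixture(scope="session")
def sx10_code_set():
    from poolpcr.fixtures import code_set_sx10

    return code_set_sx10()


def brute_force_mismatch_pmf(spec, distinct=False):
    """Independent oracle: mismatch pmf by exhaustive enumeration of all
    ordered member pairs (only for small libraries)."""
    from poolpcr.library import enumerate_members, hamming

    members = list(enumerate_members(spec, limit=5000))
    counts = {}
    total = 0
    for a in members:
        for b in members:
            if distinct and a == b:
                continue
            d = hamming(a, b)
            counts[d] = counts.get(d, 0) + 1
            total += 1
    return {d: c / total for d, c in counts.items()}
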