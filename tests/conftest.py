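"""Shared fixtures: the two full-scale grown states used by the
acceptance tests are built once per session."""

import pytest
from hypothesis import settings

from xpdt import load_config, run

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def avascular_endpoint():
    """Non-vascularized default scenario at the end of the avascular
    growth phase (41.6 simulated days, 200x200 lattice)."""
    report, state = run({"vascularized": False}, seed=11,
                        until_days=41.6, record_every=100)
    return report, state


@pytest.fixture(scope="session")
def vascularized_state():
    """Default vascularized scenario at the treatment snapshot
    (141.6 simulated days, 200x200 lattice)."""
    report, state = run(None, seed=11, until_days=141.6, record_every=100)
    return report, state
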