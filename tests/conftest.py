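import numpy as np
import pytest
from hypothesis import settings

import ringmem as rm

# property tests run derandomized so every run explores the same cases
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_spec():
    return rm.NetworkSpec.reference()


@pytest.fixture(scope="session")
def quarter_net():
    """Quarter-scale fixture network used by the dynamical tests."""
    return rm.make_fixture_network(0.25)


@pytest.fixture(scope="session")
def sero():
    return rm.SerotoninSpec()


@pytest.fixture(scope="session")
def short_protocol():
    """A protocol short enough for per-test simulation."""
    return rm.TrialProtocol(periods=(("fixation", 100.0, None),
                                     ("cue", 100.0, "cue"),
                                     ("delay", 100.0, None)))
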