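import numpy as np
import pytest

import isonich as iso


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic reservoir realization shared by read-only tests."""
    return iso.generate(iso.SynthConfig(seed=42))


@pytest.fixture
def three_sources():
    """Well-separated POM-like sources spanning a wide mixing triangle."""
    return [
        iso.SourceSummary("pico", -32.0, 0.5, 2.0, 0.5),
        iso.SourceSummary("nano", -26.0, 0.5, 8.0, 0.5),
        iso.SourceSummary("micro", -20.0, 0.5, 3.0, 0.5),
    ]
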