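import numpy as np
import pytest

from cytoport.model import (
    ChannelMeta,
    GateDimension,
    RectangleGate,
    Sample,
)
from cytoport.synth import standard_fixture


@pytest.fixture(scope="session")
def std_fixture():
    """Standard 3-population, 4-channel fixture with spillover, n=10^4."""
    return standard_fixture()


@pytest.fixture(scope="session")
def std_small():
    """Smaller standard fixture for I/O-heavy tests."""
    return standard_fixture(n_events=2000)


def make_sample(events, names=None, **keywords) -> Sample:
    events = np.asarray(events, dtype=float)
    names = names or [f"C{j}" for j in range(events.shape[1])]
    return Sample(sample_id="s", events=events,
                  channels=[ChannelMeta(n) for n in names],
                  keywords={k: str(v) for k, v in keywords.items()})


def rect1d(channel, lo, hi, transform_ref="identity"):
    return RectangleGate(dims=[GateDimension(channel, transform_ref)],
                         bounds=[(lo, hi)])
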