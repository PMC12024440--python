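import numpy as np
import pytest

from edgefc import TimeSeriesPanel, zscore_panel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_panel(n=5, t=50, seed=0, subject_id="test"):
    rng = np.random.default_rng(seed)
    return TimeSeriesPanel(
        subject_id=subject_id,
        values=rng.standard_normal((n, t)) * rng.uniform(0.5, 2.0, (n, 1))
        + rng.uniform(-3, 3, (n, 1)),
        component_ids=[f"C{i + 1}" for i in range(n)],
    )


@pytest.fixture
def panel():
    return make_panel()


@pytest.fixture
def zpanel(panel):
    return zscore_panel(panel)
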