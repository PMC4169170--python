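import numpy as np
import pytest

import biofilmquant as bq


@pytest.fixture
def rng():
    return np.random.default_rng(20140724)


@pytest.fixture
def small_panel():
    """Deterministic 12-strain panel with the default study structure."""
    return bq.simulate_panel(bq.PanelSpec(n_strains=12, seed=7))


def vertical_lines(image, n=3):
    """Evenly spaced full-height profile lines for a tube image."""
    xs = np.linspace(image.width * 0.25, image.width * 0.75, n)
    return [bq.ProfileLine((x, 0.0), (x, image.height - 1.0)) for x in xs]
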