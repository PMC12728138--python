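import numpy as np
import pytest

import erplatency as e


def make_gaussian(center, width, amplitude, times=None):
    """A single Gaussian bump on a uniform epoch grid."""
    if times is None:
        times = np.arange(-200.0, 1000.0, 2.0)
    values = amplitude * np.exp(-0.5 * ((times - center) / width) ** 2)
    return e.SampledSignal(times, values)


@pytest.fixture(scope="session")
def template():
    """Default two-component (N2 + P3) population template, 2 ms step."""
    return e.make_population_template()


@pytest.fixture(scope="session")
def window():
    return e.WeightingWindow(250.0, 700.0)


@pytest.fixture(scope="session")
def l_ga(template, window):
    lat = e.template_latency(template, window)
    assert 300 < lat < 500
    return lat
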