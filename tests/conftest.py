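import numpy as np
import pytest

from rapidibd.types import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel(rng, m, n, freq=None, span_cm=None):
    """Small random panel with a uniform-ish synthetic map."""
    f = freq if freq is not None else rng.uniform(0.2, 0.8)
    alleles = (rng.random((m, n)) < f).astype(np.uint8)
    site_bp = 1000 + np.arange(n) * 500
    gaps = rng.uniform(0.01, 0.2, size=n)
    site_cm = np.cumsum(gaps)
    site_cm -= site_cm[0]
    if span_cm is not None and site_cm[-1] > 0:
        site_cm *= span_cm / site_cm[-1]
    return HaplotypePanel(alleles=alleles, site_bp=site_bp, site_cm=site_cm)


@pytest.fixture
def panel_factory():
    return random_panel
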