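import numpy as np
import pytest

from mirsensor.fit import BinnedCurve
from mirsensor.model import RateConstants


@pytest.fixture
def unit_rates():
    """All-ones kinetics: makes closed-form arithmetic transparent."""
    return RateConstants(k_trs=1, k_tln_ebfp2=1, k_tln_mkate2=1,
                         delta_m=1, delta_p=1, k_cat=1)


@pytest.fixture
def rates():
    return RateConstants()


@pytest.fixture
def as_binned():
    """Wrap a noiseless PredictionCurve as a fully-occupied BinnedCurve."""

    def _wrap(curve, counts=1000):
        g = np.asarray(curve.grid, dtype=float)
        edges = np.concatenate([g * 0.999, [g[-1] * 1.001]])
        return BinnedCurve(edges, np.arange(g.size), g, curve.output,
                           np.full(g.size, counts))

    return _wrap
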