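import numpy as np
import pytest

from spopulse.biofilm_ode import BiofilmParams
from spopulse.phosphorelay import PhosphorelayParams, periodic_pulse
from spopulse.cellcycle import timing_from_growth


@pytest.fixture(scope="session")
def phos_params():
    return PhosphorelayParams.default()


@pytest.fixture(scope="session")
def bio_params():
    return BiofilmParams.default()


@pytest.fixture(scope="session")
def pulse_cache(phos_params):
    """Post-transient single-cycle natural pulses, computed once per rate."""
    cache = {}

    def get(g: float):
        if g not in cache:
            cache[g] = periodic_pulse(phos_params,
                                      timing_from_growth(g, allow_overlap=True))
        return cache[g]

    return get
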