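import pytest

from cflux import ecosys, synthgen
from cflux.ecosys import CohortState, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def climatology(params):
    """Noise-free mean seasonal forcing of the default synthetic climate."""
    cfg = synthgen.SynthConfig(
        ny=1, nx=1, tair_sd=0.0, prec_sd=0.0, vapr_sd=0.0, cloud_sd=0.0, seed=1
    )
    forcing = synthgen.gen_climate(cfg)
    return ecosys.make_climatology(forcing.climatology(0, 0), float(forcing.co2[0]))


@pytest.fixture(scope="session")
def spun_state(params, climatology):
    """A cohort equilibrated for 120 years under the climatology."""
    state0 = CohortState(moss_cm=params.moss_max, moss_postfire=params.moss_max)
    state, _ = ecosys.spinup(state0, climatology, params, years=120)
    return state
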