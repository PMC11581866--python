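import pytest

from arcsim import make_subject
from arcsim.protocol import run_cohort, run_protocol


@pytest.fixture
def quiet_subject():
    """Default 40-kg subject with pressure noise disabled."""
    return make_subject({"noise_sd": 0.0})


@pytest.fixture(scope="session")
def protocol_result():
    """One full noise-free two-event protocol run, shared across tests."""
    params = make_subject({"noise_sd": 0.0})
    return run_protocol(params, seed=1)


@pytest.fixture(scope="session")
def cohort11():
    """Noise-free 11-subject cohort: 5 ketamine, 6 isoflurane strata."""
    return run_cohort(
        11,
        strata={"ketamine": 5, "isoflurane": 6},
        base_seed=1,
        overrides={"noise_sd": 0.0},
    )
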