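import numpy as np
import pytest

from lynchrisk import CancerEvent, CarrierRecord, default_config, simulate_cohort


def make_carrier(
    cid="c1",
    gene="MLH1",
    sex="F",
    incl=40.0,
    last=52.0,
    vital="alive",
    events=(),
):
    return CarrierRecord(
        carrier_id=cid,
        gene=gene,
        sex=sex,
        age_inclusion=incl,
        age_last_obs=last,
        vital_status=vital,
        events=[CancerEvent(*e) for e in events],
    )


@pytest.fixture(scope="session")
def hand_cohort():
    """Twelve hand-written carriers with known person-time and events."""
    return [
        make_carrier("h01", "MLH1", "F", 40.0, 52.0),
        make_carrier("h02", "MLH1", "F", 40.0, 60.0,
                     events=[("colon", 47.0, "prospective")]),
        make_carrier("h03", "MLH1", "M", 38.0, 50.0, "dead",
                     events=[("colon", 44.0, "prospective")]),
        make_carrier("h04", "MLH1", "M", 73.0, 79.0),
        make_carrier("h05", "MSH2", "F", 30.0, 45.0,
                     events=[("endometrium", 41.0, "prospective")]),
        make_carrier("h06", "MSH2", "F", 35.0, 55.0,
                     events=[("colon", 33.0, "prevalent"),
                             ("rectum", 50.0, "prospective")]),
        make_carrier("h07", "MSH2", "M", 45.0, 62.0,
                     events=[("colon", 47.0, "prospective"),
                             ("colon", 55.0, "prospective")]),
        make_carrier("h08", "MSH6", "F", 50.0, 58.0),
        make_carrier("h09", "MSH6", "M", 25.0, 41.0, "dead"),
        make_carrier("h10", "PMS2", "F", 42.0, 44.5),
        make_carrier("h11", "PMS2", "M", 55.0, 72.0,
                     events=[("prostate", 68.0, "prospective")]),
        make_carrier("h12", "MLH1", "F", 28.0, 36.0,
                     events=[("colon", 33.0, "prospective"),
                             ("rectum", 33.0, "prospective")]),
    ]


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderately sized simulated cohort shared across tests."""
    return simulate_cohort(default_config(n_carriers=4000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
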