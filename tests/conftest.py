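import dataclasses

import pytest

from evocea.cohort import CohortSpec, PatientProfile, generate_cohort
from evocea.config import paper_replication_config
from evocea.costs import DEFAULT_EVENT_MIX


def make_patient(**overrides) -> PatientProfile:
    """A plain secondary-prevention patient; override fields as needed."""
    base = dict(
        id=0,
        age=60.0,
        sex="female",
        hypertension=True,
        diabetes=False,
        smoking=False,
        prior_mi=True,
        prior_stroke=False,
        ckd=False,
        pad=False,
        recent_acs=True,
        familial_hyperchol=False,
        ezetimibe=False,
        ldl=110.0,
        hdl=45.0,
        tg=150.0,
    )
    base.update(overrides)
    return PatientProfile(**base)


@pytest.fixture(scope="session")
def replication_config():
    return paper_replication_config()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(n=61, seed=1))


@pytest.fixture
def event_mix():
    return DEFAULT_EVENT_MIX
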