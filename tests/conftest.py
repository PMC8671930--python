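import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voihbp as v

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ctx():
    """Small-simulation context for fast tests."""
    return v.DecisionContext(n_simulations=2000, seed=7)


@pytest.fixture
def record():
    return v.InterventionRecord(
        id="demo",
        name="demo intervention",
        delta_cost_pp=75.0,
        delta_benefit_pp=1.5,
        eligible_population=1000.0,
        coverage=0.5,
    )


@pytest.fixture
def small_eb(record):
    """Three interventions: SE payload, CI payload, and no payload."""
    se = record.model_copy(
        update={
            "id": "a",
            "evidence": v.datamodel.MeanSEPayload(se_cost=30.0, se_benefit=0.2, rho=0.1),
        }
    )
    ci = record.model_copy(
        update={
            "id": "b",
            "evidence": v.datamodel.MeanCIPayload(
                ci_cost=(15.0, 135.0), ci_benefit=(1.0, 2.0), level=0.95, rho=-0.2
            ),
        }
    )
    none = record.model_copy(update={"id": "c"})
    return v.EvidenceBase(
        context=v.DecisionContext(n_simulations=2000, seed=7),
        interventions=(se, ci, none),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
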