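import numpy as np
import pandas as pd
import pytest

from ghqlong import simulate
from ghqlong.grm import ModelSpec, build_design


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 12-person cohort with complete and attrited responses."""
    cfg = simulate.CohortConfig(n_persons=12, seed=42)
    persons, items, complete, observed = simulate.simulate_study(cfg)
    return {
        "config": cfg,
        "persons": persons,
        "items": items,
        "complete": complete,
        "observed": observed,
    }


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size (N=174) synthetic cohort with study-like attrition."""
    cfg = simulate.CohortConfig(seed=7)
    persons, items, complete, observed = simulate.simulate_study(cfg)
    return {
        "config": cfg,
        "persons": persons,
        "items": items,
        "complete": complete,
        "observed": observed,
    }


@pytest.fixture(scope="session")
def toy_design(small_cohort):
    return build_design(small_cohort["persons"], n_waves=3, spec=ModelSpec("m4"))


@pytest.fixture(scope="session")
def m1_fit_small(small_cohort):
    """A quick two-chain m1 fit on the small cohort, shared across tests."""
    from ghqlong.grm import GradedResponseModel

    model = GradedResponseModel(variant="m1", chains=2, warmup=250, draws=250, seed=3)
    model.fit(small_cohort["complete"], small_cohort["persons"])
    return model
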