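import numpy as np
import pytest

import spcddi as sp


@pytest.fixture(scope="session")
def fixture_cohort():
    """The hand-traced 8-stay edge-case cohort."""
    return sp.make_fixture_cohort()


@pytest.fixture(scope="session")
def included_fixture(fixture_cohort):
    sub, counts = sp.apply_inclusion_criteria(fixture_cohort.cohort)
    return sub, counts


@pytest.fixture(scope="session")
def small_sim():
    """A 600-stay simulated cohort with one moderately protective drug."""
    spec = sp.DrugSpec(
        label="drugX", atc_code="N02AX02", direction="potentiates_vka",
        exposure_prevalence=0.3, co_administration_probability=0.9,
        true_log_or_initiation=float(np.log(0.5)),
        true_log_or_discontinuation=float(np.log(0.5)),
    )
    config = sp.SimulationConfig(n_stays=600, seed=7, drug_specs=[spec])
    cohort, truth = sp.simulate_cohort(config)
    return config, cohort, truth
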