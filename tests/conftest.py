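import numpy as np
import pandas as pd
import pytest

from screenpp import (GeneratorParams, ProtocolSpec, build_cohort,
                      build_person_intervals, generate_population)


@pytest.fixture(scope="session")
def small_dataset():
    """2,000-beneficiary synthetic claims dataset with default dynamics."""
    params = GeneratorParams(n_beneficiaries=2000, seed=42)
    return params, generate_population(params)


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    _, data = small_dataset
    cohort, exclusions = build_cohort(data.demographics, data.enrollment,
                                      data.claims)
    return cohort, exclusions, data


@pytest.fixture(scope="session")
def small_intervals(small_cohort):
    cohort, _, data = small_cohort
    spec = ProtocolSpec(cadence_years=10)
    return build_person_intervals(cohort, data.claims, spec)


@pytest.fixture(scope="session")
def aj_fixture():
    """200-person cohort with entry at baseline 0 (no delayed entry), used for
    the cross-check against an external competing-risks implementation."""
    params = GeneratorParams(n_beneficiaries=200, seed=7).replace(
        entry_model={"fixed_entry_month": -6},
        # higher event rates so all status types appear at this small n
        cancer_hazard={"base_monthly": 2e-3},
        death_hazard={"base_monthly": 3e-3},
    )
    data = generate_population(params)
    cohort, _ = build_cohort(data.demographics, data.enrollment, data.claims)
    spec = ProtocolSpec(cadence_years=2)
    intervals = build_person_intervals(cohort, data.claims, spec)
    return intervals
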