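import numpy as np
import pytest

from ibp.cohort import (
    CONTROL,
    EXPOSED,
    POST_TRAUMA,
    BehavioralRecord,
    CohortTable,
    Direction,
    ParameterSpec,
    ProfileDefinition,
)


@pytest.fixture(scope="session")
def tiny_profile() -> ProfileDefinition:
    """Three-parameter, k=2 profile with one direction of each kind."""
    params = (
        ParameterSpec("dist", "WAZM", Direction.LOW_IS_AFFECTED, "cm"),
        ParameterSpec("freeze", "WAZM", Direction.HIGH_IS_AFFECTED, "s"),
        ParameterSpec("index", "EPM", Direction.TWO_SIDED, "%"),
    )
    return ProfileDefinition("TINY", {POST_TRAUMA: params}, k=2)


def make_cohort(control_values, exposed_values, timepoint=POST_TRAUMA):
    """Build a cohort from per-animal dicts of parameter values."""
    records = []
    for i, vals in enumerate(control_values):
        records.append(BehavioralRecord(f"C{i}", CONTROL, timepoint, dict(vals)))
    for i, vals in enumerate(exposed_values):
        records.append(BehavioralRecord(f"E{i}", EXPOSED, timepoint, dict(vals)))
    return CohortTable(records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
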