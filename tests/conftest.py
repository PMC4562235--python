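import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmaze.assay_data import ArmDesign, Assay, TrialRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(
    n_orange,
    n_apple,
    arm=ArmDesign.A_THEN_O,
    assay=Assay.PREFERENCE,
    cohort="population",
    trial_id="t0",
    n_released=None,
):
    return TrialRecord(
        trial_id=trial_id,
        cohort=cohort,
        assay=assay,
        arm_design=arm,
        n_orange=n_orange,
        n_apple=n_apple,
        n_released=n_released,
    )


@pytest.fixture
def trial_factory():
    return make_trial


def random_records(rng, n=50):
    """Random valid records across both assays, for round-trip properties."""
    records = []
    for i in range(n):
        assay = Assay.PREFERENCE if rng.random() < 0.5 else Assay.LEARNING
        arms = (
            (ArmDesign.A_THEN_O, ArmDesign.O_THEN_A)
            if assay is Assay.PREFERENCE
            else (ArmDesign.A_AVERSIVE_O_PALATABLE, ArmDesign.O_AVERSIVE_A_PALATABLE)
        )
        n_or = int(rng.integers(0, 40))
        n_ap = int(rng.integers(0, 40))
        records.append(
            TrialRecord(
                trial_id=f"t{i:03d}",
                cohort=f"R{int(rng.integers(1, 5))}",
                assay=assay,
                arm_design=arms[int(rng.integers(0, 2))],
                n_orange=n_or,
                n_apple=n_ap,
                n_released=n_or + n_ap + int(rng.integers(0, 10)),
            )
        )
    return records
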