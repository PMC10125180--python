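import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pompesim as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def drug():
    return ps.DrugParams()


@pytest.fixture(scope="session")
def pilot_dosage():
    return ps.PILOT_DOSAGE_PLAN


@pytest.fixture(scope="session")
def pilot_cost():
    return ps.PILOT_COST_PLAN


@pytest.fixture()
def fresh_state():
    return ps.AnnualClaimState()


@pytest.fixture(scope="session")
def hand_cohort():
    """Five households with hand-computed stepwise CHE/IDI truth.

    All household sizes are 3 (poverty threshold 3 x 4978 = 14 934 RMB of
    net income).  R3 sits exactly on the 10%-of-income CHE boundary after
    the BMI step; R5 is already below the poverty line before treatment.
    """
    return pd.DataFrame(
        {
            "id": ["R1", "R2", "R3", "R4", "R5"],
            "group": ["pediatric", "pediatric", "pediatric", "adult", "adult"],
            "age": [6.0, 10.0, 3.0, 30.0, 45.0],
            "weight": [20.0, 28.0, 14.0, 60.0, 70.0],
            "household_income": [40_000.0, 200_000.0, 100_000.0, 30_000.0, 12_000.0],
            "household_size": [3, 3, 3, 3, 3],
            "direct_medical": [100_000.0, 15_000.0, 12_000.0, 50_000.0, 500.0],
            "bmi_reimbursed": [5_000.0, 3_000.0, 2_000.0, 10_000.0, 0.0],
            "ci_reimbursed": [1_000.0, 0.0, 0.0, 5_000.0, 0.0],
            "non_medical": [20_000.0, 6_000.0, 0.0, 5_000.0, 300.0],
            "adherence": [1.0, 1.0, 1.0, 0.2, 0.125],
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    return ps.generate_cohort(ps.default_spec(seed=0))


def per_vial_oracle(vials: int, price: float, plan: ps.DosagePlan) -> float:
    """Brute-force reimbursement: loop over each dispensed vial."""
    reimbursed = 0.0
    for i in range(1, vials + 1):
        tier = (i - 1) // plan.tier_width
        rate = plan.tier_rates[tier] if tier < len(plan.tier_rates) else 0.0
        reimbursed += price * rate
    return reimbursed
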