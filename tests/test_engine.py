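import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pompesim as ps
from conftest import per_vial_oracle

RMB = 0.005  # currency comparison tolerance


class TestVialsPerMonth:
    @pytest.mark.parametrize(
        "weight,adherence,expected",
        [
            (12.5, 1.0, 10),  # 250 mg/infusion = 5 vials x 2
            (60.0, 1.0 / 8.0, 6),  # 150 mg/infusion = 3 vials x 2
            (2.5, 1.0, 2),  # single-vial floor
            (12.6, 1.0, 12),  # 252 mg rounds UP to 6 vials
        ],
    )
    def test_dose_rounds_up_to_whole_vials(self, weight, adherence, expected):
        assert ps.vials_per_month(weight, adherence) == expected

    @pytest.mark.parametrize("weight,adherence", [(0, 1), (-5, 1), (60, 0), (60, 1.2)])
    def test_rejects_invalid_inputs(self, weight, adherence):
        with pytest.raises(ps.ConfigError):
            ps.vials_per_month(weight, adherence)


class TestDosageMonth:
    def test_worked_example_14_vials(self, pilot_dosage):
        out = ps.dosage_month(14, 5645, pilot_dosage)
        assert out.total_cost == pytest.approx(79_030, abs=RMB)
        assert out.bmi_reimbursed == pytest.approx(19_757.5 + 16_935 + 11_290, abs=RMB)
        assert out.out_of_pocket == pytest.approx(31_047.5, abs=RMB)

    def test_zero_vials_zero_outcome(self, pilot_dosage):
        out = ps.dosage_month(0, 5645, pilot_dosage)
        assert out == ps.MonthlyOutcome(0.0, 0.0, 0.0, 0.0)

    def test_vials_beyond_last_tier_unreimbursed(self, pilot_dosage):
        # reimbursement saturates at 15 covered vials: 5645 x (3.5+3+2.5)
        out15 = ps.dosage_month(15, 5645, pilot_dosage)
        out20 = ps.dosage_month(20, 5645, pilot_dosage)
        assert out15.bmi_reimbursed == pytest.approx(50_805, abs=RMB)
        assert out20.bmi_reimbursed == pytest.approx(out15.bmi_reimbursed, abs=RMB)
        assert out20.out_of_pocket == pytest.approx(20 * 5645 - 50_805, abs=RMB)

    def test_rejects_negative_or_fractional_vials(self, pilot_dosage):
        with pytest.raises(ps.ConfigError):
            ps.dosage_month(-1, 5645, pilot_dosage)
        with pytest.raises(ps.ConfigError):
            ps.dosage_month(2.5, 5645, pilot_dosage)

    @given(vials=st.integers(0, 100), plan_idx=st.integers(0, 10))
    def test_matches_per_vial_oracle(self, vials, plan_idx):
        from pompesim.simulate import DOSAGE_PLAN_STRINGS

        plan = ps.parse_dosage_plan(DOSAGE_PLAN_STRINGS[plan_idx])
        out = ps.dosage_month(vials, 5645, plan)
        assert out.bmi_reimbursed == pytest.approx(
            per_vial_oracle(vials, 5645, plan), abs=RMB
        )


class TestCostMonth:
    def test_worked_example_first_month(self, pilot_cost, fresh_state):
        out, state = ps.cost_month(79_030, pilot_cost, fresh_state)
        assert out.bmi_reimbursed == pytest.approx(38_724.7, abs=RMB)
        # CI-eligible after the 12 000 annual deductible line: 4 596.3
        assert state.ci_deductible_consumed == pytest.approx(12_000, abs=RMB)
        assert out.ci_reimbursed == pytest.approx(2_298.15, abs=RMB)
        assert out.out_of_pocket == pytest.approx(38_007.15, abs=RMB)

    def test_second_identical_month_has_no_deductible_left(self, pilot_cost, fresh_state):
        _, state = ps.cost_month(79_030, pilot_cost, fresh_state)
        out2, _ = ps.cost_month(79_030, pilot_cost, state)
        # full CI base 16 596.3 is now eligible at the 50% base rate
        assert out2.ci_reimbursed == pytest.approx(8_298.15, abs=RMB)
        assert out2.out_of_pocket == pytest.approx(32_007.15, abs=RMB)

    def test_zero_cost_zero_outcome_state_unchanged(self, pilot_cost, fresh_state):
        out, state = ps.cost_month(0.0, pilot_cost, fresh_state)
        assert out == ps.MonthlyOutcome(0.0, 0.0, 0.0, 0.0)
        assert state == fresh_state

    def test_bmi_ceiling_overflow_joins_ci_base(self, pilot_cost):
        # nearly exhausted BMI ceiling: the unpaid insured cost flows to CI
        state = ps.AnnualClaimState(bmi_paid_ytd=150_000, ci_deductible_consumed=12_000)
        out, _ = ps.cost_month(10_000, pilot_cost, state)
        assert out.bmi_reimbursed == 0.0
        assert out.ci_reimbursed == pytest.approx(7_000 * 0.5, abs=RMB)

    def test_ci_rate_boost_after_threshold(self, pilot_cost):
        state = ps.AnnualClaimState(
            ci_paid_ytd=100_001, ci_deductible_consumed=12_000
        )
        out, _ = ps.cost_month(10_000, pilot_cost, state)
        assert out.ci_reimbursed == pytest.approx(10_000 * 0.7 * 0.3 * 0.6, abs=RMB)

    def test_rejects_negative_cost_and_bad_state(self, pilot_cost, fresh_state):
        with pytest.raises(ps.ConfigError):
            ps.cost_month(-1.0, pilot_cost, fresh_state)
        with pytest.raises(ps.ConfigError):
            ps.cost_month(1.0, pilot_cost, ps.AnnualClaimState(bmi_paid_ytd=1e9))


class TestCombinedMonth:
    def test_dosage_residual_then_ci(self, pilot_dosage, pilot_cost, fresh_state):
        out, _ = ps.combined_month(14, 5645, pilot_dosage, pilot_cost, fresh_state)
        # dosage residual 31 047.5, minus 12 000 deductible, at 50%
        assert out.ci_reimbursed == pytest.approx((31_047.5 - 12_000) * 0.5, abs=RMB)
        assert out.out_of_pocket == pytest.approx(21_523.75, abs=RMB)

    def test_zero_vials(self, pilot_dosage, pilot_cost, fresh_state):
        out, _ = ps.combined_month(0, 5645, pilot_dosage, pilot_cost, fresh_state)
        assert out == ps.MonthlyOutcome(0.0, 0.0, 0.0, 0.0)

    def test_degenerate_ci_arm_equals_dosage_only(self, pilot_dosage, fresh_state):
        huge_deductible = ps.CostPlan(ci_deductible=1e12)
        out, _ = ps.combined_month(14, 5645, pilot_dosage, huge_deductible, fresh_state)
        dosage_only = ps.dosage_month(14, 5645, pilot_dosage)
        assert out.out_of_pocket == pytest.approx(dosage_only.out_of_pocket, abs=RMB)
        assert out.ci_reimbursed == 0.0


class TestAnnual:
    def test_dosage_annual_is_twelve_identical_months(self, pilot_dosage, drug):
        # 17.5 kg at full adherence -> 7 vials/infusion -> 14 vials/month
        patient = {"weight": 17.5, "adherence": 1.0}
        res = ps.annual_outcomes(patient, "dosage", dplan=pilot_dosage, drug=drug)
        assert res["vials_per_month"] == 14
        assert res["out_of_pocket"] == pytest.approx(12 * 31_047.5, abs=RMB)

    def test_scheme_none_pays_full_drug_cost(self, drug):
        res = ps.annual_outcomes({"weight": 60.0, "adherence": 1 / 8}, "none", drug=drug)
        assert res["out_of_pocket"] == pytest.approx(6 * 5645 * 12, abs=RMB)
        assert res["bmi_reimbursed"] == 0.0

    def test_all_zero_plan_pays_nothing(self, drug):
        zero = ps.DosagePlan((0.0, 0.0, 0.0))
        res = ps.annual_outcomes({"weight": 30, "adherence": 1.0}, "dosage", dplan=zero)
        assert res["out_of_pocket"] == pytest.approx(res["total_cost"], abs=RMB)

    def test_full_coverage_plan_pays_everything(self):
        full = ps.DosagePlan((1.0,), tier_width=1000)
        res = ps.annual_outcomes({"weight": 30, "adherence": 1.0}, "dosage", dplan=full)
        assert res["out_of_pocket"] == pytest.approx(0.0, abs=RMB)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ps.ConfigError):
            ps.annual_outcomes({"weight": 30, "adherence": 1.0}, "voucher")

    def test_annual_totals_are_sums_of_monthly_outcomes(self, pilot_cost, drug):
        vials, price = 9, drug.vial_price
        state = ps.AnnualClaimState()
        sums = np.zeros(4)
        for _ in range(12):
            out, state = ps.cost_month(vials * price, pilot_cost, state)
            sums += [out.total_cost, out.bmi_reimbursed, out.ci_reimbursed, out.out_of_pocket]
        annual = ps.annual_totals_for_vials(vials, "cost", cplan=pilot_cost, drug=drug)
        assert np.allclose(annual, sums, atol=RMB)

    def test_ceiling_saturation_stops_accumulation(self, pilot_cost):
        # enormous monthly bill: BMI ceiling is reached in month 1
        state = ps.AnnualClaimState()
        _, state = ps.cost_month(1e6, pilot_cost, state)
        assert state.bmi_paid_ytd == pytest.approx(150_000, abs=RMB)
        out2, state2 = ps.cost_month(1e6, pilot_cost, state)
        assert out2.bmi_reimbursed == 0.0
        assert state2.bmi_paid_ytd == state.bmi_paid_ytd
        # CI ceiling saturates too, given enough months
        for _ in range(10):
            _, state2 = ps.cost_month(1e7, pilot_cost, state2)
        assert state2.ci_paid_ytd <= 500_000 + 1e-6


# --- properties -------------------------------------------------------------

cost_plan_strategy = st.builds(
    ps.CostPlan,
    deductible_share=st.floats(0.0, 0.9),
    bmi_copay=st.floats(0.0, 1.0),
    bmi_annual_ceiling=st.floats(0.0, 400_000),
    ci_deductible=st.floats(0.0, 50_000),
    ci_copay_base=st.floats(0.0, 0.9),
    ci_tier_threshold=st.floats(0.0, 200_000),
    ci_annual_ceiling=st.floats(0.0, 700_000),
)

monthly_costs_strategy = st.lists(st.floats(0, 600_000), min_size=12, max_size=12)


def annual_cost_oop(costs, plan):
    """Run a year month by month; assert conservation; return annual OOP."""
    state = ps.AnnualClaimState()
    oop = 0.0
    for c in costs:
        out, state = ps.cost_month(c, plan, state)
        assert out.total_cost == pytest.approx(
            out.bmi_reimbursed + out.ci_reimbursed + out.out_of_pocket, abs=1e-6
        )
        assert out.bmi_reimbursed >= -1e-9 and out.ci_reimbursed >= -1e-9
        assert out.bmi_reimbursed + out.ci_reimbursed <= out.total_cost + 1e-6
        oop += out.out_of_pocket
    return oop


GENEROSITY_DIRECTIONS = {
    "deductible_share": -1,
    "bmi_copay": +1,
    "bmi_annual_ceiling": +1,
    "ci_deductible": -1,
    "ci_copay_base": +1,
    "ci_tier_threshold": -1,
    "ci_annual_ceiling": +1,
}


@given(
    plan=cost_plan_strategy,
    costs=monthly_costs_strategy,
    param=st.sampled_from(sorted(GENEROSITY_DIRECTIONS)),
    delta=st.floats(0.001, 0.3),
)
def test_cost_oop_monotone_in_every_plan_parameter(plan, costs, param, delta):
    """Making any cost-plan parameter more generous never raises annual OOP."""
    value = getattr(plan, param)
    if param in ("deductible_share", "bmi_copay", "ci_copay_base", "ci_tier_threshold", "ci_deductible"):
        step = delta * (value if value > 0 else 1.0)
    else:
        step = delta * 100_000
    new_value = value + GENEROSITY_DIRECTIONS[param] * step
    if param in ("deductible_share", "bmi_copay", "ci_copay_base"):
        new_value = min(max(new_value, 0.0), 1.0 if param != "ci_copay_base" else 0.9)
    else:
        new_value = max(new_value, 0.0)
    better = plan.with_(**{param: new_value})
    assert annual_cost_oop(costs, better) <= annual_cost_oop(costs, plan) + 1e-6


@given(
    vials=st.integers(0, 40),
    rates=st.lists(st.floats(0, 0.9), min_size=1, max_size=4),
    tier=st.integers(0, 3),
    delta=st.floats(0.01, 0.1),
)
def test_dosage_oop_monotone_in_tier_rates(vials, rates, tier, delta):
    tier = tier % len(rates)
    plan = ps.DosagePlan(tuple(rates))
    raised = list(rates)
    raised[tier] = min(raised[tier] + delta, 1.0)
    better = ps.DosagePlan(tuple(raised))
    assert (
        ps.dosage_month(vials, 5645, better).out_of_pocket
        <= ps.dosage_month(vials, 5645, plan).out_of_pocket + 1e-6
    )


@given(plan=cost_plan_strategy, costs=monthly_costs_strategy)
def test_combined_never_pays_more_than_dosage_alone(plan, costs):
    """Adding the CI arm on top of the dosage schedule can only help."""
    del costs  # vial counts drive the combined scheme
    state = ps.AnnualClaimState()
    for vials in (3, 14, 25):
        out, state = ps.combined_month(vials, 5645, ps.PILOT_DOSAGE_PLAN, plan, state)
        alone = ps.dosage_month(vials, 5645, ps.PILOT_DOSAGE_PLAN)
        assert out.out_of_pocket <= alone.out_of_pocket + 1e-6
        assert out.total_cost == pytest.approx(
            out.bmi_reimbursed + out.ci_reimbursed + out.out_of_pocket, abs=1e-6
        )
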