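"""Monthly and annual reimbursement arithmetic for the three schemes.

The month is the claim unit.  The dosage-based scheme is stateless across
months; the cost-based scheme and the CI arm of the combined scheme carry
annual accumulators (BMI paid year-to-date, CI paid year-to-date, CI
deductible consumed) in :class:`AnnualClaimState`, reset each January.

Amounts are plain floats in RMB; the worked-example quantities are exactly
representable to well below the 0.005 RMB verification tolerance because no
intermediate rounding is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import ClassVar

from .errors import ConfigError
from .plans import CostPlan, DosagePlan, DrugParams

__all__ = [
    "SCHEMES",
    "AnnualClaimState",
    "MonthlyOutcome",
    "vials_per_month",
    "dosage_month",
    "cost_month",
    "combined_month",
    "annual_outcomes",
    "annual_totals_for_vials",
]

#: Recognised reimbursement schemes. "none" means the patient pays the full
#: drug cost out of pocket.
SCHEMES = ("none", "dosage", "cost", "combined")

# Guard against float noise pushing an exactly-divisible dose over the next
# whole vial (e.g. 20 mg/kg * 12.5 kg / 50 mg == 5.0).
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class AnnualClaimState:
    """Running annual accumulators for the cost-based / combined schemes."""

    bmi_paid_ytd: float = 0.0
    ci_paid_ytd: float = 0.0
    ci_deductible_consumed: float = 0.0

    def validate(self, plan: CostPlan) -> None:
        if min(self.bmi_paid_ytd, self.ci_paid_ytd, self.ci_deductible_consumed) < 0:
            raise ConfigError("AnnualClaimState accumulators must be non-negative")
        if self.bmi_paid_ytd > plan.bmi_annual_ceiling + 1e-6:
            raise ConfigError("bmi_paid_ytd exceeds the plan's BMI annual ceiling")
        if self.ci_paid_ytd > plan.ci_annual_ceiling + 1e-6:
            raise ConfigError("ci_paid_ytd exceeds the plan's CI annual ceiling")
        if self.ci_deductible_consumed > plan.ci_deductible + 1e-6:
            raise ConfigError("ci_deductible_consumed exceeds the plan's CI deductible")


@dataclass(frozen=True)
class MonthlyOutcome:
    """One month's drug bill split into payers.

    Invariant: ``out_of_pocket == total_cost - bmi_reimbursed - ci_reimbursed``.
    For the dosage-based scheme the tiered reimbursement is carried in the
    ``bmi_reimbursed`` slot (it is the government-sponsored arm).
    """

    total_cost: float
    bmi_reimbursed: float
    ci_reimbursed: float
    out_of_pocket: float

    ZERO: ClassVar["MonthlyOutcome"]


MonthlyOutcome.ZERO = MonthlyOutcome(0.0, 0.0, 0.0, 0.0)


def vials_per_month(
    weight: float, adherence: float, drug: DrugParams = DrugParams()
) -> int:
    """Whole vials dispensed per month for a patient.

    The per-infusion dose is ``adherence * dose_per_kg * weight`` mg,
    rounded *up* to whole vials (partial vials cannot be dispensed), then
    multiplied by the number of infusions per month.
    """
    if weight <= 0:
        raise ConfigError("weight must be strictly positive")
    if not 0.0 < adherence <= 1.0:
        raise ConfigError("adherence must lie in (0, 1]")
    mg = adherence * drug.dose_per_kg * weight
    per_infusion = max(1, math.ceil(mg / drug.vial_mg - _CEIL_EPS))
    return per_infusion * drug.infusions_per_month


def dosage_month(vials: int, price: float, plan: DosagePlan) -> MonthlyOutcome:
    """One month under the dosage-based scheme.

    Vials are reimbursed block by block at the plan's tier rates; vials
    beyond the covered range are paid fully by the patient.
    """
    if vials < 0 or int(vials) != vials:
        raise ConfigError("vials must be a non-negative integer")
    if price <= 0:
        raise ConfigError("price must be strictly positive")
    vials = int(vials)
    reimbursed = 0.0
    for i, rate in enumerate(plan.tier_rates):
        in_tier = min(max(vials - i * plan.tier_width, 0), plan.tier_width)
        reimbursed += in_tier * price * rate
    total = vials * price
    return MonthlyOutcome(total, reimbursed, 0.0, total - reimbursed)


def _ci_claim(
    base: float, plan: CostPlan, state: AnnualClaimState
) -> tuple[float, float]:
    """CI arm: consume the annual deductible line, then reimburse.

    The base co-pay applies until the annual amount claimed from CI
    reaches the tier threshold; reimbursement beyond the threshold is paid
    at the boosted rate, splitting the claim on which the threshold is
    crossed.  (The split makes the annual CI payout a function of the
    annual eligible total alone, so plan generosity is monotone — see
    docs/methods.md.)  Returns ``(claim, deductible_consumed_now)``.
    """
    remaining_deductible = plan.ci_deductible - state.ci_deductible_consumed
    consumed_now = min(base, remaining_deductible)
    eligible = base - consumed_now
    paid = state.ci_paid_ytd
    if paid >= plan.ci_tier_threshold:
        claim = eligible * plan.ci_copay_boosted
    else:
        gap = plan.ci_tier_threshold - paid  # payout room left at the base rate
        eligible_at_base = gap / plan.ci_copay_base if plan.ci_copay_base > 0 else float("inf")
        if eligible <= eligible_at_base:
            claim = eligible * plan.ci_copay_base
        else:
            claim = gap + (eligible - eligible_at_base) * plan.ci_copay_boosted
    claim = min(claim, plan.ci_annual_ceiling - paid)
    return max(claim, 0.0), consumed_now


def cost_month(
    total_cost: float, plan: CostPlan, state: AnnualClaimState
) -> tuple[MonthlyOutcome, AnnualClaimState]:
    """One month under the cost-based scheme.

    The deductible share of the bill is never insured.  BMI pays its co-pay
    fraction of the insured cost up to its annual ceiling; the remainder of
    the insured cost — including any amount BMI could not pay because its
    ceiling was reached — forms the CI base, which is reimbursed after the
    CI annual deductible line at the (possibly boosted) CI rate, capped by
    the CI annual ceiling.
    """
    if total_cost < 0:
        raise ConfigError("total_cost must be non-negative")
    state.validate(plan)
    if total_cost == 0:
        return MonthlyOutcome.ZERO, state

    insured = total_cost * (1.0 - plan.deductible_share)
    bmi_claim = min(insured * plan.bmi_copay, plan.bmi_annual_ceiling - state.bmi_paid_ytd)
    bmi_claim = max(bmi_claim, 0.0)
    ci_base = insured - bmi_claim
    ci_claim, consumed_now = _ci_claim(ci_base, plan, state)

    outcome = MonthlyOutcome(
        total_cost, bmi_claim, ci_claim, total_cost - bmi_claim - ci_claim
    )
    new_state = AnnualClaimState(
        bmi_paid_ytd=state.bmi_paid_ytd + bmi_claim,
        ci_paid_ytd=state.ci_paid_ytd + ci_claim,
        ci_deductible_consumed=state.ci_deductible_consumed + consumed_now,
    )
    return outcome, new_state


def combined_month(
    vials: int,
    price: float,
    dplan: DosagePlan,
    cplan: CostPlan,
    state: AnnualClaimState,
) -> tuple[MonthlyOutcome, AnnualClaimState]:
    """One month under the combined scheme.

    The month first runs through the dosage-based schedule; the residual
    self-paid amount then becomes the CI base of the cost-based scheme
    (annual CI deductible line, base/boosted rate, CI annual ceiling).  The
    BMI arm of the cost plan is not involved.
    """
    state.validate(cplan)
    d = dosage_month(vials, price, dplan)
    residual = d.out_of_pocket
    ci_claim, consumed_now = _ci_claim(residual, cplan, state)
    outcome = MonthlyOutcome(
        d.total_cost, d.bmi_reimbursed, ci_claim, residual - ci_claim
    )
    new_state = AnnualClaimState(
        bmi_paid_ytd=state.bmi_paid_ytd,
        ci_paid_ytd=state.ci_paid_ytd + ci_claim,
        ci_deductible_consumed=state.ci_deductible_consumed + consumed_now,
    )
    return outcome, new_state


@lru_cache(maxsize=4096)
def annual_totals_for_vials(
    vials: int,
    scheme: str,
    dplan: DosagePlan | None = None,
    cplan: CostPlan | None = None,
    drug: DrugParams = DrugParams(),
) -> tuple[float, float, float, float]:
    """Twelve months at a constant monthly vial count, fresh claim year.

    Returns ``(total_cost, bmi_reimbursed, ci_reimbursed, out_of_pocket)``
    annual sums.  Cached: cohorts map onto a small set of vial counts.
    """
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}; valid: {', '.join(SCHEMES)}")
    if scheme in ("dosage", "combined") and dplan is None:
        raise ConfigError(f"scheme {scheme!r} requires a dosage plan")
    if scheme in ("cost", "combined") and cplan is None:
        raise ConfigError(f"scheme {scheme!r} requires a cost plan")

    price = drug.vial_price
    monthly_cost = vials * price
    totals = [0.0, 0.0, 0.0, 0.0]
    state = AnnualClaimState()
    for _ in range(12):
        if scheme == "none":
            out = MonthlyOutcome(monthly_cost, 0.0, 0.0, monthly_cost)
        elif scheme == "dosage":
            out = dosage_month(vials, price, dplan)
        elif scheme == "cost":
            out, state = cost_month(monthly_cost, cplan, state)
        else:
            out, state = combined_month(vials, price, dplan, cplan, state)
        totals[0] += out.total_cost
        totals[1] += out.bmi_reimbursed
        totals[2] += out.ci_reimbursed
        totals[3] += out.out_of_pocket
    return tuple(totals)  # type: ignore[return-value]


def annual_outcomes(
    patient,
    scheme: str,
    dplan: DosagePlan | None = None,
    cplan: CostPlan | None = None,
    drug: DrugParams = DrugParams(),
) -> dict[str, float]:
    """Annual payer split for one patient under a scheme.

    ``patient`` is anything with ``weight`` and ``adherence`` attributes or
    keys (a :class:`~pompesim.cohort.PatientRecord`, a pandas row, a dict).
    """
    weight = getattr(patient, "weight", None)
    adherence = getattr(patient, "adherence", None)
    if weight is None or adherence is None:
        weight = patient["weight"]
        adherence = patient["adherence"]
    vials = vials_per_month(float(weight), float(adherence), drug)
    total, bmi, ci, oop = annual_totals_for_vials(vials, scheme, dplan, cplan, drug)
    return {
        "vials_per_month": vials,
        "total_cost": total,
        "bmi_reimbursed": bmi,
        "ci_reimbursed": ci,
        "out_of_pocket": oop,
    }
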