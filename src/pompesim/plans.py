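"""Drug and reimbursement-plan parameterizations.

Two pilot schemes for alglucosidase alfa (Myozyme) reimbursement are
modelled:

* a *dosage-based* plan (Tianjin style): a tiered per-vial reimbursement
  schedule applied monthly, e.g. ``"70-60-50"`` = 70% on vials 1-5, 60% on
  vials 6-10, 50% on vials 11-15, nothing afterwards;
* a *cost-based* plan (Jining style): a deductible share excluded from
  insurance, basic medical insurance (BMI) paying a co-pay fraction of the
  insured cost up to an annual ceiling, and critical-illness commercial
  insurance (CI) covering the rest above an annual deductible line, at a
  base rate that is boosted by 10 points once the annual amount claimed
  from CI exceeds a threshold, up to its own annual ceiling.

All money is in RMB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigError

__all__ = [
    "DrugParams",
    "DosagePlan",
    "CostPlan",
    "PILOT_DOSAGE_PLAN",
    "PILOT_COST_PLAN",
    "parse_dosage_plan",
    "parse_cost_plan",
]


@dataclass(frozen=True)
class DrugParams:
    """Prescription and pricing constants for the enzyme replacement therapy.

    Defaults are the guideline regimen: 20 mg per kg body weight, infused
    twice a month, dispensed in 50 mg vials at 5645 RMB per vial.
    """

    dose_per_kg: float = 20.0
    infusions_per_month: int = 2
    vial_mg: float = 50.0
    vial_price: float = 5645.0

    def __post_init__(self) -> None:
        for name in ("dose_per_kg", "infusions_per_month", "vial_mg", "vial_price"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"DrugParams.{name} must be strictly positive")


@dataclass(frozen=True)
class DosagePlan:
    """Tiered per-vial reimbursement schedule, applied to each month's vials.

    ``tier_rates[i]`` is the reimbursement fraction for vials in the i-th
    block of ``tier_width`` vials; vials beyond the last tier are not
    reimbursed at all.
    """

    tier_rates: tuple[float, ...]
    tier_width: int = 5

    def __post_init__(self) -> None:
        if len(self.tier_rates) < 1:
            raise ConfigError("DosagePlan needs at least one tier")
        if any(not 0.0 <= r <= 1.0 for r in self.tier_rates):
            raise ConfigError("DosagePlan tier rates must lie in [0, 1]")
        if self.tier_width < 1:
            raise ConfigError("DosagePlan tier_width must be >= 1")
        object.__setattr__(self, "tier_rates", tuple(float(r) for r in self.tier_rates))

    @property
    def covered_vials(self) -> int:
        """Number of vials per month with any reimbursement."""
        return self.tier_width * len(self.tier_rates)

    @classmethod
    def from_string(cls, text: str, tier_width: int = 5) -> "DosagePlan":
        """Parse a hyphenated percentage string such as ``"70-60-50"``."""
        try:
            pcts = [int(tok) for tok in text.strip().split("-")]
        except ValueError:
            raise ConfigError(f"unparsable dosage plan string: {text!r}") from None
        if not pcts or any(not 0 <= p <= 100 for p in pcts):
            raise ConfigError(f"dosage plan percentages must be 0-100: {text!r}")
        return cls(tuple(p / 100.0 for p in pcts), tier_width=tier_width)

    def to_string(self) -> str:
        return "-".join(str(round(r * 100)) for r in self.tier_rates)


def parse_dosage_plan(text: str) -> DosagePlan:
    """Convenience alias for :meth:`DosagePlan.from_string`."""
    return DosagePlan.from_string(text)


@dataclass(frozen=True)
class CostPlan:
    """Cost-based scheme: deductible share, BMI co-pay/ceiling, CI arm.

    Defaults are the pilot plan: 30% deductible share, BMI pays 70% of the
    insured cost up to 150 000 RMB/year; CI covers the rest above a
    12 000 RMB annual deductible line at 50% (60% once the annual amount
    claimed from CI exceeds 100 000 RMB), up to 500 000 RMB/year.
    """

    deductible_share: float = 0.30
    bmi_copay: float = 0.70
    bmi_annual_ceiling: float = 150_000.0
    ci_deductible: float = 12_000.0
    ci_copay_base: float = 0.50
    ci_copay_boosted: float | None = None
    ci_tier_threshold: float = 100_000.0
    ci_annual_ceiling: float = 500_000.0

    def __post_init__(self) -> None:
        if self.ci_copay_boosted is None:
            object.__setattr__(
                self, "ci_copay_boosted", min(self.ci_copay_base + 0.10, 1.0)
            )
        for name in ("deductible_share", "bmi_copay", "ci_copay_base", "ci_copay_boosted"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"CostPlan.{name} must lie in [0, 1]")
        for name in (
            "bmi_annual_ceiling",
            "ci_deductible",
            "ci_tier_threshold",
            "ci_annual_ceiling",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"CostPlan.{name} must be non-negative")
        if self.ci_copay_boosted < self.ci_copay_base:
            raise ConfigError("CostPlan boosted CI rate cannot be below the base rate")

    def with_(self, **kwargs) -> "CostPlan":
        """Return a copy with some parameters replaced.

        If ``ci_copay_base`` changes and no explicit boosted rate is given,
        the boosted rate is re-derived as base + 10 points.
        """
        if "ci_copay_base" in kwargs and "ci_copay_boosted" not in kwargs:
            kwargs["ci_copay_boosted"] = None
        return replace(self, **kwargs)


PILOT_DOSAGE_PLAN = DosagePlan.from_string("70-60-50")
PILOT_COST_PLAN = CostPlan()

_COST_PARAM_NAMES = (
    "deductible_share",
    "bmi_copay",
    "bmi_annual_ceiling",
    "ci_deductible",
    "ci_copay_base",
    "ci_tier_threshold",
    "ci_annual_ceiling",
)


def parse_cost_plan(text: str) -> CostPlan:
    """Parse a cost-plan key: ``"pilot"`` or a ``param=value`` variant.

    Examples: ``"pilot"``, ``"bmi_copay=0.8"``,
    ``"deductible_share=0.2,ci_copay_base=0.7"``.
    """
    text = text.strip()
    if text == "pilot":
        return PILOT_COST_PLAN
    if "=" not in text:
        raise ConfigError(
            f"unknown cost plan {text!r}: expected 'pilot' or 'param=value[,param=value...]'"
        )
    kwargs: dict[str, float] = {}
    for token in text.split(","):
        name, _, value = token.partition("=")
        name = name.strip()
        if name not in _COST_PARAM_NAMES:
            raise ConfigError(
                f"unknown cost plan parameter {name!r}; valid: {', '.join(_COST_PARAM_NAMES)}"
            )
        try:
            kwargs[name] = float(value)
        except ValueError:
            raise ConfigError(f"bad value for cost plan parameter {name!r}: {value!r}") from None
    return PILOT_COST_PLAN.with_(**kwargs)
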