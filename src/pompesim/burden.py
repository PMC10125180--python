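"""Catastrophic health expenditure (CHE) and impoverishment (IDI) indicators.

CHE: a household's out-of-pocket health spending *exceeds* (strictly) a
share of annual household income — 10% by default.

IDI: post-payment per-capita household income *falls below* (strictly) a
poverty line — the World Bank $1.90/day line, 4978 RMB/person/year at the
study-period exchange rate, by default.  The baseline step counts
households already below the line before any health spending, so IDI is an
absolute post-payment poverty head count, not only the newly impoverished.

The stepwise decomposition mirrors the published burden table: expenses are
introduced payer by payer (direct medical cost, minus BMI reimbursement,
minus CI reimbursement, plus direct non-medical cost) so each step isolates
one payer's contribution to the burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .errors import ConfigError
from .plans import CostPlan, DosagePlan, DrugParams

__all__ = [
    "BurdenThresholds",
    "che_flag",
    "idi_flag",
    "stepwise_burden",
    "format_stepwise",
    "simulate_flags",
    "simulated_burden",
    "CHE_STEPS",
    "IDI_STEPS",
]


@dataclass(frozen=True)
class BurdenThresholds:
    """CHE income share and IDI poverty line (RMB/person/year)."""

    che_income_share: float = 0.10
    poverty_line: float = 4978.0

    def __post_init__(self) -> None:
        if not 0.0 < self.che_income_share < 1.0:
            raise ConfigError("che_income_share must lie in (0, 1)")
        if self.poverty_line <= 0:
            raise ConfigError("poverty_line must be positive")


def che_flag(oop_expense, household_income, thresholds: BurdenThresholds = BurdenThresholds()):
    """True where out-of-pocket spending strictly exceeds the income share.

    Zero income with positive spending is catastrophic.  Vectorized.
    """
    oop = np.asarray(oop_expense, dtype=float)
    income = np.asarray(household_income, dtype=float)
    if (oop < 0).any():
        raise ConfigError("out-of-pocket expense must be non-negative")
    if (income < 0).any():
        raise ConfigError("household income must be non-negative")
    out = oop > thresholds.che_income_share * income
    return bool(out) if out.ndim == 0 else out


def idi_flag(
    household_income,
    net_health_spend,
    household_size,
    thresholds: BurdenThresholds = BurdenThresholds(),
):
    """True where post-payment per-capita income falls strictly below the line.

    ``net_health_spend`` may be any step's expense aggregate; net income
    may go negative (deep impoverishment).  Vectorized.
    """
    income = np.asarray(household_income, dtype=float)
    spend = np.asarray(net_health_spend, dtype=float)
    size = np.asarray(household_size, dtype=float)
    if (size < 1).any():
        raise ConfigError("household_size must be >= 1")
    out = (income - spend) / size < thresholds.poverty_line
    return bool(out) if out.ndim == 0 else out


# Step label -> expense aggregate, as functions of the cohort columns.
CHE_STEPS = (
    ("Only consider direct medical expense", lambda d: d["direct_medical"]),
    ("Above - reimbursement by BMI", lambda d: d["direct_medical"] - d["bmi_reimbursed"]),
    (
        "Above - reimbursement by CI",
        lambda d: d["direct_medical"] - d["bmi_reimbursed"] - d["ci_reimbursed"],
    ),
    (
        "Above + direct non-medical expense",
        lambda d: d["direct_medical"]
        - d["bmi_reimbursed"]
        - d["ci_reimbursed"]
        + d["non_medical"],
    ),
)

IDI_STEPS = (
    ("Only consider annual household income", lambda d: 0.0 * d["direct_medical"]),
    ("Above - direct medical expense", lambda d: d["direct_medical"]),
    ("Above + reimbursement by BMI", lambda d: d["direct_medical"] - d["bmi_reimbursed"]),
    (
        "Above + reimbursement by CI",
        lambda d: d["direct_medical"] - d["bmi_reimbursed"] - d["ci_reimbursed"],
    ),
    (
        "Above - direct non-medical expense",
        lambda d: d["direct_medical"]
        - d["bmi_reimbursed"]
        - d["ci_reimbursed"]
        + d["non_medical"],
    ),
)


def _step_table(cohort, steps, flag_fn) -> pd.DataFrame:
    rows = []
    groups = [g for g in ("pediatric", "adult") if (cohort["group"] == g).any()]
    for label, expense_fn in steps:
        for group in groups:
            sub = cohort[cohort["group"] == group]
            # full reimbursement can leave a -1e-12 residue in float math
            expense = np.maximum(np.asarray(expense_fn(sub), dtype=float), 0.0)
            flags = flag_fn(sub, expense)
            rows.append(
                {
                    "step": label,
                    "group": group,
                    "n": int(np.sum(flags)),
                    "N": len(sub),
                    "rate": float(np.mean(flags)),
                }
            )
    return pd.DataFrame(rows)


def stepwise_burden(
    cohort: pd.DataFrame, thresholds: BurdenThresholds = BurdenThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stepwise CHE and IDI tables (one row per step x group, n/N layout)."""
    if len(cohort) == 0:
        raise ConfigError("cohort is empty")
    che = _step_table(
        cohort,
        CHE_STEPS,
        lambda sub, expense: che_flag(expense, sub["household_income"], thresholds),
    )
    idi = _step_table(
        cohort,
        IDI_STEPS,
        lambda sub, spend: idi_flag(
            sub["household_income"], spend, sub["household_size"], thresholds
        ),
    )
    return che, idi


def format_stepwise(che: pd.DataFrame, idi: pd.DataFrame) -> str:
    """Pretty-print the two step tables (percentages to 1 decimal place)."""
    lines = []
    for title, table in (("CHE", che), ("IDI", idi)):
        lines.append(title)
        for label in table["step"].unique():
            parts = [f"  {label:<42s}"]
            for _, row in table[table["step"] == label].iterrows():
                parts.append(
                    f"{row['group']}: {row['n']}/{row['N']} ({100 * row['rate']:.1f}%)"
                )
            lines.append("  ".join(parts))
    return "\n".join(lines)


def simulate_flags(
    cohort: pd.DataFrame,
    scheme: str,
    dplan: DosagePlan | None = None,
    cplan: CostPlan | None = None,
    drug: DrugParams = DrugParams(),
    thresholds: BurdenThresholds = BurdenThresholds(),
    include_nonmedical: bool = False,
) -> pd.DataFrame:
    """Per-patient simulated annual OOP and CHE/IDI flags under a scheme.

    Each patient's observed medical expense is replaced by the scheme's
    simulated annual out-of-pocket drug cost (guideline dosing scaled by
    the patient's adherence).  Observed non-medical expense is added only
    when ``include_nonmedical`` is set — the policy simulation is primarily
    about direct medical cost.
    """
    oop = np.array(
        [
            engine.annual_totals_for_vials(
                engine.vials_per_month(w, a, drug), scheme, dplan, cplan, drug
            )[3]
            for w, a in zip(cohort["weight"].to_numpy(), cohort["adherence"].to_numpy())
        ]
    )
    expense = oop + (cohort["non_medical"].to_numpy() if include_nonmedical else 0.0)
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "group": cohort["group"].to_numpy(),
            "annual_oop": oop,
            "expense": expense,
            "che": che_flag(expense, cohort["household_income"], thresholds),
            "idi": idi_flag(
                cohort["household_income"], expense, cohort["household_size"], thresholds
            ),
        }
    )


def simulated_burden(
    cohort: pd.DataFrame,
    scheme: str,
    dplan: DosagePlan | None = None,
    cplan: CostPlan | None = None,
    drug: DrugParams = DrugParams(),
    thresholds: BurdenThresholds = BurdenThresholds(),
    include_nonmedical: bool = False,
) -> pd.DataFrame:
    """Group-level simulated CHE/IDI rates under a scheme.

    One row per group plus an ``all`` row for the pooled cohort.
    """
    flags = simulate_flags(
        cohort, scheme, dplan, cplan, drug, thresholds, include_nonmedical
    )
    rows = []
    groups = [g for g in ("pediatric", "adult") if (flags["group"] == g).any()]
    for group in groups + ["all"]:
        sub = flags if group == "all" else flags[flags["group"] == group]
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "che_rate": float(sub["che"].mean()),
                "idi_rate": float(sub["idi"].mean()),
                "mean_annual_oop": float(sub["annual_oop"].mean()),
                "mean_monthly_oop": float(sub["annual_oop"].mean()) / 12.0,
            }
        )
    return pd.DataFrame(rows)
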