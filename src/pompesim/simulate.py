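"""Plan-grid sweeps with bootstrap uncertainty and policy-ceiling detection.

The variant grids reproduce the study's simulation table: eleven dosage
plans (the "70-60-50" pilot, three three-tier variants, seven four-tier
variants) and one-parameter-at-a-time variants of the pilot cost plan
(deductible share, BMI co-pay and ceiling, CI co-pay, tier threshold and
ceiling), with a full-factorial escape hatch.

Uncertainty is quantified with the percentile bootstrap on per-patient
burden flags (95% interval from the 2.5/97.5 percentiles of B resampled
means).  A *stagnation point* is the plan generosity beyond which the
burden metric stops improving materially — the policy ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .burden import BurdenThresholds, simulate_flags
from .errors import ConfigError
from .plans import PILOT_COST_PLAN, CostPlan, DosagePlan, DrugParams

__all__ = [
    "PlanGrid",
    "BootstrapRate",
    "bootstrap_rate",
    "sweep",
    "stagnation_point",
    "plot_sweep",
]

#: Dosage plan strings of the simulation table, pilot first, by generosity
#: within each family.
DOSAGE_PLAN_STRINGS = (
    "70-60-50",
    "80-70-60",
    "90-80-70",
    "100-90-80",
    "40-30-20-10",
    "50-40-30-20",
    "60-50-40-30",
    "70-60-50-40",
    "80-70-60-50",
    "90-80-70-60",
    "100-90-80-70",
)

#: Cost-plan parameter variants (pilot value listed first).
COST_PARAM_VARIANTS: dict[str, tuple[float, ...]] = {
    "deductible_share": (0.30, 0.20, 0.10),
    "bmi_copay": (0.70, 0.80, 0.90, 1.00),
    "bmi_annual_ceiling": (150_000.0, 175_000.0, 200_000.0),
    "ci_copay_base": (0.50, 0.60, 0.70, 0.80, 0.90),
    "ci_tier_threshold": (100_000.0, 50_000.0, 75_000.0, 125_000.0),
    "ci_annual_ceiling": (
        500_000.0,
        400_000.0,
        425_000.0,
        450_000.0,
        475_000.0,
        525_000.0,
        550_000.0,
        575_000.0,
        600_000.0,
    ),
}


@dataclass(frozen=True)
class PlanGrid:
    """The sweep grids; defaults reproduce the study's simulation table."""

    dosage_plans: tuple[str, ...] = DOSAGE_PLAN_STRINGS
    cost_variants: tuple[tuple[str, tuple[float, ...]], ...] = tuple(
        (k, v) for k, v in COST_PARAM_VARIANTS.items()
    )

    def dosage_grid(self) -> list[tuple[str, DosagePlan]]:
        return [(s, DosagePlan.from_string(s)) for s in self.dosage_plans]

    def cost_grid(self, factorial: bool = False) -> list[tuple[str, CostPlan]]:
        """One-parameter-at-a-time variants about the pilot (default), or
        the full cartesian product with ``factorial=True``."""
        if not factorial:
            plans = [("pilot", PILOT_COST_PLAN)]
            for name, values in self.cost_variants:
                for value in values:
                    if value == getattr(PILOT_COST_PLAN, name):
                        continue
                    plans.append((f"{name}={value:g}", PILOT_COST_PLAN.with_(**{name: value})))
            return plans
        plans = []
        names = [name for name, _ in self.cost_variants]
        grids = [values for _, values in self.cost_variants]
        for combo in np.ndindex(*[len(v) for v in grids]):
            kwargs = {n: g[i] for n, g, i in zip(names, grids, combo)}
            label = ",".join(f"{n}={kwargs[n]:g}" for n in names)
            plans.append((label, PILOT_COST_PLAN.with_(**kwargs)))
        return plans


@dataclass(frozen=True)
class BootstrapRate:
    rate: float
    lower: float
    upper: float


def bootstrap_rate(
    flags: Sequence[bool] | np.ndarray, B: int = 1000, seed: int = 0
) -> BootstrapRate:
    """Percentile-bootstrap point estimate and 95% interval of a flag rate.

    The flags are treated as a multiset (sorted before resampling), so the
    result is invariant to input order at a fixed seed.
    """
    x = np.sort(np.asarray(flags, dtype=float))
    if x.size == 0:
        raise ConfigError("flags must be non-empty")
    if B < 1:
        raise ConfigError("B must be >= 1")
    rate = float(x.mean())
    if x.min() == x.max():  # degenerate: every resample has the same mean
        return BootstrapRate(rate, rate, rate)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    means = x[idx].mean(axis=1)
    lower, upper = np.percentile(means, [2.5, 97.5])
    return BootstrapRate(rate, float(lower), float(upper))


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def sweep(
    cohort: pd.DataFrame,
    grid: PlanGrid = PlanGrid(),
    scheme: str = "dosage",
    B: int = 1000,
    seed: int = 0,
    drug: DrugParams = DrugParams(),
    thresholds: BurdenThresholds = BurdenThresholds(),
    include_nonmedical: bool = False,
    factorial: bool = False,
) -> pd.DataFrame:
    """Simulate every plan in the grid; one row per plan x group.

    ``scheme`` selects which grid applies: "dosage" and "combined" sweep
    the dosage plans (combined keeps the pilot CI arm), "cost" sweeps the
    cost-plan variants.  Reproducible given the seed.
    """
    if scheme == "cost":
        plans = [(pid, None, cplan) for pid, cplan in grid.cost_grid(factorial)]
    elif scheme in ("dosage", "combined"):
        plans = [
            (pid, dplan, PILOT_COST_PLAN if scheme == "combined" else None)
            for pid, dplan in grid.dosage_grid()
        ]
    else:
        raise ConfigError(f"sweep does not apply to scheme {scheme!r}")

    rows = []
    seeds = iter(_child_seeds(seed, 4 * len(plans) * 3))
    for order, (plan_id, dplan, cplan) in enumerate(plans):
        flags = simulate_flags(
            cohort, scheme, dplan, cplan, drug, thresholds, include_nonmedical
        )
        groups = [g for g in ("pediatric", "adult") if (flags["group"] == g).any()]
        for group in groups + ["all"]:
            sub = flags if group == "all" else flags[flags["group"] == group]
            che = bootstrap_rate(sub["che"].to_numpy(), B, int(next(seeds)))
            idi = bootstrap_rate(sub["idi"].to_numpy(), B, int(next(seeds)))
            rows.append(
                {
                    "plan": plan_id,
                    "order": order,
                    "scheme": scheme,
                    "group": group,
                    "n": len(sub),
                    "che_rate": che.rate,
                    "che_lower": che.lower,
                    "che_upper": che.upper,
                    "idi_rate": idi.rate,
                    "idi_lower": idi.lower,
                    "idi_upper": idi.upper,
                    "mean_annual_oop": float(sub["annual_oop"].mean()),
                    "mean_monthly_oop": float(sub["annual_oop"].mean()) / 12.0,
                    "B": B,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def stagnation_point(
    results: Sequence[tuple[str, float]] | pd.DataFrame,
    tolerance: float = 0.005,
    metric: str = "che_rate",
) -> str | None:
    """First plan after which the metric never improves by >= tolerance.

    ``results`` must be ordered by increasing plan generosity; improvement
    is a *decrease* in the burden rate.  Returns ``None`` when improvement
    continues to the end of the grid.
    """
    if tolerance < 0:
        raise ConfigError("tolerance must be non-negative")
    if isinstance(results, pd.DataFrame):
        pairs = list(zip(results["plan"], results[metric]))
    else:
        pairs = list(results)
    if len(pairs) < 2:
        raise ConfigError("stagnation_point needs at least two results")
    rates = [r for _, r in pairs]
    for i in range(len(pairs) - 1):
        if all(rates[i] - rates[j] < tolerance for j in range(i + 1, len(pairs))):
            return pairs[i][0]
    return None


def plot_sweep(results: pd.DataFrame, path, metric: str = "che_rate") -> None:
    """Rate-vs-plan curves per group, saved to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    lo, hi = metric.replace("_rate", "_lower"), metric.replace("_rate", "_upper")
    for group, sub in results.groupby("group"):
        sub = sub.sort_values("order")
        ax.plot(sub["plan"], sub[metric], marker="o", label=group)
        if lo in sub and hi in sub:
            ax.fill_between(sub["plan"], sub[lo], sub[hi], alpha=0.2)
    ax.set_xlabel("plan")
    ax.set_ylabel(metric)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
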