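"""Cost-minimisation from the provider perspective.

With noninferiority established, the economic comparison reduces to costs:
strategy-coded delivery cost ledgers (2019 AUD) are totalled per arm, averaged
per school, differenced between arms, and given 95% uncertainty intervals by
non-parametric bootstrap over schools (the costing unit), resampled with
replacement within arm.  Scale-up projections multiply the per-school saving
by a target school count; research and development costs are excluded by
never being ledger items.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import BootstrapError, ConfigurationError, ParseError, ValidationError

__all__ = [
    "STRATEGY_CODES",
    "read_ledger",
    "packaged_ledger_path",
    "summarise_costs",
    "bootstrap_uncertainty",
    "scaleup_projection",
    "relative_cost_reduction",
    "CostSummary",
]

ARMS = ("original", "adapted")

#: declared strategy vocabulary for ledger items
STRATEGY_CODES = (
    "champion_training",
    "ongoing_support",
    "equipment_pack",
    "staff_session",
    "principal_meeting",
    "educational_materials",
    "program_delivery",
)

LEDGER_COLUMNS = ["arm", "strategy_code", "school_id", "amount"]


def read_ledger(path, n_schools: dict[str, int] | None = None) -> pd.DataFrame:
    """Read a cost ledger CSV and apportion shared items across schools.

    Rows with ``school_id == 'shared'`` are split equally over the arm's
    schools (``n_schools``, default 24 per arm), producing synthetic
    per-school ids ``<arm>_sNN``.  Negative amounts and unknown arm or
    strategy labels raise :class:`ValidationError`.
    """
    n_schools = n_schools or {"original": 24, "adapted": 24}
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty ledger") from None
        if [h.strip() for h in header] != LEDGER_COLUMNS:
            raise ParseError(f"{path}: line 1: expected header {','.join(LEDGER_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(LEDGER_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            arm, strategy, school, amount = (c.strip() for c in row)
            if arm not in ARMS:
                raise ValidationError(f"{path}: line {lineno}: unknown arm {arm!r}")
            if strategy not in STRATEGY_CODES:
                raise ValidationError(f"{path}: line {lineno}: unknown strategy {strategy!r}")
            try:
                value = float(amount)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric amount {amount!r}") from None
            if value < 0:
                raise ValidationError(f"{path}: line {lineno}: negative amount {value}")
            if school == "shared":
                n = n_schools[arm]
                for i in range(n):
                    rows.append(
                        {
                            "arm": arm,
                            "strategy_code": strategy,
                            "school_id": f"{arm}_s{i:02d}",
                            "amount": value / n,
                        }
                    )
            else:
                rows.append(
                    {"arm": arm, "strategy_code": strategy, "school_id": school, "amount": value}
                )
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)


def packaged_ledger_path():
    """Path to the packaged synthetic delivery-cost ledger fixture."""
    return resources.files("clusterni.data") / "synthetic_cost_ledger.csv"


@dataclass
class CostSummary:
    """Point estimates of the cost comparison (2019 AUD)."""

    total: dict[str, float]
    per_school: dict[str, float]
    per_school_rounded: dict[str, int]
    by_strategy: pd.DataFrame
    difference_total: float
    difference_per_school: float
    n_schools: dict[str, int]


def summarise_costs(items: pd.DataFrame, n_schools: dict[str, int] | None = None) -> CostSummary:
    """Arm totals, per-school means and between-arm differences.

    The difference convention is original minus adapted, so a positive value
    is the saving achieved by the adapted delivery model.  Per-school values
    are reported both unrounded and rounded to whole AUD (internal arithmetic
    is never rounded).
    """
    n_schools = n_schools or {
        arm: items.loc[items["arm"] == arm, "school_id"].nunique() for arm in ARMS
    }
    for arm in ARMS:
        if arm not in set(items["arm"]):
            raise ValidationError(f"ledger has no items for arm {arm!r}")
        if n_schools.get(arm, 0) < 1:
            raise ConfigurationError(f"n_schools for arm {arm!r} must be >= 1")
    total = {arm: float(items.loc[items["arm"] == arm, "amount"].sum()) for arm in ARMS}
    per_school = {arm: total[arm] / n_schools[arm] for arm in ARMS}
    by_strategy = (
        items.groupby(["arm", "strategy_code"], as_index=False)["amount"]
        .sum()
        .sort_values(["arm", "strategy_code"])
        .reset_index(drop=True)
    )
    return CostSummary(
        total=total,
        per_school=per_school,
        per_school_rounded={arm: round(per_school[arm]) for arm in ARMS},
        by_strategy=by_strategy,
        difference_total=total["original"] - total["adapted"],
        difference_per_school=per_school["original"] - per_school["adapted"],
        n_schools=dict(n_schools),
    )


def per_school_costs(items: pd.DataFrame) -> dict[str, np.ndarray]:
    """Total cost per school within each arm (bootstrap resampling unit)."""
    out = {}
    for arm in ARMS:
        sub = items.loc[items["arm"] == arm]
        out[arm] = sub.groupby("school_id")["amount"].sum().to_numpy(dtype=float)
    return out


def bootstrap_uncertainty(
    per_school: dict[str, np.ndarray],
    n_reps: int = 1000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """95% percentile uncertainty intervals by school-level bootstrap.

    Schools are resampled with replacement within arm; per replicate the arm
    totals, per-school means and between-arm differences are recomputed.
    Returns intervals keyed ``total_<arm>``, ``per_school_<arm>``,
    ``difference_total`` and ``difference_per_school``.
    """
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >= 1, got {n_reps}")
    for arm in ARMS:
        if arm not in per_school:
            raise BootstrapError(f"missing per-school costs for arm {arm!r}")
        if len(per_school[arm]) < 2:
            raise BootstrapError(f"arm {arm!r} has a single school; bootstrap undefined")
    rng = np.random.default_rng(seed)
    stats: dict[str, np.ndarray] = {}
    means = {}
    totals = {}
    for arm in ARMS:
        costs = np.asarray(per_school[arm], dtype=float)
        n = costs.size
        idx = rng.integers(0, n, size=(n_reps, n))
        resampled = costs[idx]
        totals[arm] = resampled.sum(axis=1)
        means[arm] = resampled.mean(axis=1)
        stats[f"total_{arm}"] = totals[arm]
        stats[f"per_school_{arm}"] = means[arm]
    stats["difference_total"] = totals["original"] - totals["adapted"]
    stats["difference_per_school"] = means["original"] - means["adapted"]
    return {
        key: tuple(float(q) for q in np.percentile(vals, [2.5, 97.5]))
        for key, vals in stats.items()
    }


def scaleup_projection(per_school_saving: float, n_target_schools: int) -> float:
    """Projected saving from rolling the cheaper model out to more schools.

    When the target count is a "400+"-style floor, the product is a lower
    bound on the projected saving.
    """
    if per_school_saving < 0 or n_target_schools < 0:
        raise ConfigurationError("scale-up inputs must be >= 0")
    return float(per_school_saving) * float(n_target_schools)


def relative_cost_reduction(per_school_original: float, per_school_adapted: float) -> float:
    """Percentage reduction in per-school cost, 100 x (orig - adapted)/orig."""
    if per_school_original <= 0:
        raise ConfigurationError("per_school_original must be > 0")
    return 100.0 * (per_school_original - per_school_adapted) / per_school_original
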