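"""Societal costing of resource use, informal care and lost productivity.

Costs are valued per participant per 3-month recall period (index year
2021, EUR) in five resource categories — intervention, mental
healthcare, other healthcare, medication, informal care — plus three
productivity components: absenteeism from paid work, absenteeism from
unpaid work and presenteeism.  Absenteeism from paid work is valued
either by the friction-cost approach (each sickness episode valued up
to the friction period, default 12 weeks = 60 working days, after which
a replacement restores productivity) or by the human-capital approach
(full episode duration).  Presenteeism is valued as
(1 - efficiency score) x days with health complaints x hours per day,
at gender-specific wage rates; unpaid work is valued at the shadow
price of a legally employed cleaner.

The societal perspective sums all components; the healthcare
perspective keeps only the healthcare-tagged categories (intervention,
mental healthcare, other healthcare, medication).  No discounting is
applied over the 12-month horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import TrialDataset, RESOURCE_COLUMNS

CATEGORIES = ("intervention", "mental_healthcare", "other_healthcare", "medication", "informal_care")
HEALTHCARE_CATEGORIES = ("intervention", "mental_healthcare", "other_healthcare", "medication")
PRODUCTIVITY_COMPONENTS = ("absenteeism_paid", "absenteeism_unpaid", "presenteeism")
ALL_COMPONENTS = CATEGORIES + PRODUCTIVITY_COMPONENTS

#: share of attended psychotherapy sessions falling in each follow-up
#: period, by arm: twice-weekly delivers 16 sessions in the first 8 weeks
#: and 4 in weeks 9-16; once-weekly spreads 16 over 16 weeks plus 4 more.
SESSION_PERIOD_SHARES = {
    "twice": (0.80, 0.20, 0.0, 0.0),
    "once": (0.65, 0.35, 0.0, 0.0),
}


class CostingError(ValueError):
    pass


@dataclass(frozen=True)
class UnitCostTable:
    """Item code -> (unit cost EUR, unit, category); price index year."""

    items: dict[str, tuple[float, str, str]]
    index_year: int = 2021

    def __post_init__(self) -> None:
        for code, (cost, _unit, category) in self.items.items():
            if cost < 0:
                raise CostingError(f"negative unit cost for {code!r}")
            if category not in CATEGORIES:
                raise CostingError(f"unknown category {category!r} for item {code!r}")

    def unit_cost(self, code: str) -> float:
        try:
            return self.items[code][0]
        except KeyError:
            raise CostingError(f"unit-cost table has no entry for item {code!r}") from None

    def category(self, code: str) -> str:
        try:
            return self.items[code][2]
        except KeyError:
            raise CostingError(f"unit-cost table has no entry for item {code!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path, index_year: int = 2021) -> "UnitCostTable":
        table = pd.read_csv(path)
        items = {
            str(r["item"]): (float(r["unit_cost"]), str(r["unit"]), str(r["category"]))
            for _, r in table.iterrows()
        }
        return cls(items=items, index_year=index_year)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"item": code, "unit": unit, "category": cat, "unit_cost": cost}
            for code, (cost, unit, cat) in self.items.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_unit_costs() -> UnitCostTable:
    """Illustrative 2021 unit costs for the TiC-P-style items the generator emits."""
    return UnitCostTable(
        items={
            "gp_visits": (33.0, "visit", "other_healthcare"),
            "psychiatrist_visits": (120.0, "visit", "mental_healthcare"),
            "psychologist_visits": (100.0, "visit", "mental_healthcare"),
            "psych_hospital_days": (800.0, "day", "mental_healthcare"),
            "antidepressant_ddd": (0.50, "defined daily dose", "medication"),
            "informal_care_hours": (16.0, "hour", "informal_care"),
        }
    )


@dataclass(frozen=True)
class WageSchedule:
    """Gender-specific hourly wages, shadow price for unpaid work, friction period."""

    hourly_wage: dict[str, float] = field(
        default_factory=lambda: {"female": 34.0, "male": 40.0}
    )
    shadow_price: float = 15.0          # EUR/hour, legally employed cleaner
    friction_days: int = 60             # 12 weeks x 5 working days

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hourly_wage.values()):
            raise CostingError("wages must be positive")
        if self.friction_days <= 0:
            raise CostingError("friction period must be positive")

    def wage(self, gender: str) -> float:
        try:
            return self.hourly_wage[gender]
        except KeyError:
            raise CostingError(f"no wage rate for gender {gender!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WageSchedule":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            hourly_wage={str(k): float(v) for k, v in data["hourly_wage"].items()},
            shadow_price=float(data.get("shadow_price", 15.0)),
            friction_days=int(data.get("friction_days", 60)),
        )


# ---------------------------------------------------------------------------
# element-wise valuation operations
# ---------------------------------------------------------------------------

def value_resource_use(counts: dict[str, float], table: UnitCostTable) -> dict[str, float]:
    """Per-category cost of a bundle of resource-use quantities."""
    out = {cat: 0.0 for cat in CATEGORIES}
    for code, qty in counts.items():
        if qty < 0:
            raise CostingError(f"negative quantity for item {code!r}")
        out[table.category(code)] += qty * table.unit_cost(code)
    return out


def intervention_cost(sessions_attended: float, session_unit_cost: float) -> float:
    if sessions_attended < 0:
        raise CostingError("sessions_attended must be non-negative")
    return sessions_attended * session_unit_cost


def presenteeism_cost(efficiency: float, days_with_complaints: float,
                      hours_per_day: float, wage: float) -> float:
    """(1 - efficiency) x complaint days x hours/day, valued at the wage rate."""
    if not 0.0 <= efficiency <= 1.0:
        raise CostingError("efficiency score must lie in [0, 1]")
    if min(days_with_complaints, hours_per_day, wage) < 0:
        raise CostingError("days, hours and wage must be non-negative")
    return (1.0 - efficiency) * days_with_complaints * hours_per_day * wage


def absenteeism_cost(absence_episodes, wage: float, hours_per_day: float,
                     approach: str = "friction", friction_days: int = 60) -> float:
    """Value paid-work absence episodes.

    ``absence_episodes`` is an iterable of (start, length-in-working-days)
    pairs.  Under the human-capital approach the full length of every
    episode is valued; under the friction-cost approach each episode is
    valued only up to ``friction_days``.
    """
    if approach not in ("friction", "human_capital"):
        raise CostingError(f"unknown costing approach {approach!r}")
    total_days = 0.0
    for _start, length in absence_episodes:
        if length < 0:
            raise CostingError("episode length must be non-negative")
        total_days += min(length, friction_days) if approach == "friction" else length
    return total_days * hours_per_day * wage


def unpaid_work_cost(hours_lost: float, shadow_price: float) -> float:
    if hours_lost < 0 or shadow_price < 0:
        raise CostingError("hours and shadow price must be non-negative")
    return hours_lost * shadow_price


# ---------------------------------------------------------------------------
# dataset-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class CostBreakdown:
    """Per-participant cost components and totals.

    ``period`` has one row per participant per 3-month follow-up period
    (months 3, 6, 9, 12) with every component, ``healthcare_total``,
    ``lost_productivity_total`` and ``societal_total``; components of an
    unobserved assessment are missing (NaN).  ``annual`` sums the four
    periods per participant (missing if any period is missing) and
    ``baseline_societal`` is the societal cost of the 3 months before
    the start of treatment.
    """

    period: pd.DataFrame
    annual: pd.DataFrame
    baseline_societal: pd.Series
    perspective: str
    approach: str

    def to_csv(self, path: str | Path) -> None:
        self.period.to_csv(path, index=False)


def _capped_absence_days(long: pd.DataFrame, friction_days: int) -> pd.Series:
    """Absence days per row after applying the friction cap per episode.

    Episodes may span recall periods; the cap is applied to the episode's
    cumulative duration in chronological order, identified by episode id.
    """
    df = long[["id", "month", "absence_days", "absence_episode_id"]].copy()
    df["_row"] = np.arange(len(df))
    capped = df["absence_days"].astype(float).copy()
    with_ep = df.dropna(subset=["absence_episode_id", "absence_days"])
    if len(with_ep):
        with_ep = with_ep.sort_values(["id", "absence_episode_id", "month"])
        cum = with_ep.groupby(["id", "absence_episode_id"])["absence_days"].cumsum()
        prev = cum - with_ep["absence_days"]
        valued = np.clip(cum, None, friction_days) - np.clip(prev, None, friction_days)
        capped.iloc[with_ep["_row"].to_numpy()] = valued.to_numpy()
    return capped


def aggregate_costs(data: TrialDataset, table: UnitCostTable, wages: WageSchedule,
                    approach: str = "friction", perspective: str = "societal",
                    session_unit_cost: float = 100.0) -> CostBreakdown:
    """Value a whole trial dataset into a :class:`CostBreakdown`.

    Component costs are computed for every assessment row; quantities of
    unobserved assessments propagate as missing.  Intervention costs are
    derived from administratively recorded attended sessions and are
    therefore never missing.  The perspective filters the reported
    totals only; all components are retained.
    """
    if perspective not in ("societal", "healthcare"):
        raise CostingError(f"unknown perspective {perspective!r}")
    if approach not in ("friction", "human_capital"):
        raise CostingError(f"unknown costing approach {approach!r}")

    long = data.long.sort_values(["id", "month"]).reset_index(drop=True)
    base = data.baseline.set_index("id")
    ids = long["id"]

    out = pd.DataFrame({"id": ids, "month": long["month"]})

    # resource-use categories (vectorised dot product against the table)
    for cat in ("mental_healthcare", "other_healthcare", "medication", "informal_care"):
        cost = np.zeros(len(long))
        for code in RESOURCE_COLUMNS:
            if table.category(code) == cat:
                cost = cost + long[code].to_numpy(dtype=float) * table.unit_cost(code)
        out[cat] = cost

    # intervention: attended sessions spread over the delivery schedule
    sessions = base["sessions_attended"].reindex(ids).to_numpy(dtype=float)
    arm = base["frequency_arm"].reindex(ids).to_numpy()
    months = sorted(m for m in data.timepoints if m > 0)
    share = np.zeros(len(long))
    for a, shares in SESSION_PERIOD_SHARES.items():
        for k, m in enumerate(months):
            mask = (arm == a) & (long["month"].to_numpy() == m)
            share[mask] = shares[k] if k < len(shares) else 0.0
    out["intervention"] = np.where(long["month"] > 0, sessions * share * session_unit_cost, 0.0)

    # productivity components
    wage = base["gender"].reindex(ids).map(wages.wage).to_numpy(dtype=float)
    hours = base["hours_per_day"].reindex(ids).to_numpy(dtype=float)
    if approach == "friction":
        absence_days = _capped_absence_days(long, wages.friction_days)
    else:
        absence_days = long["absence_days"].astype(float)
    out["absenteeism_paid"] = absence_days.to_numpy() * hours * wage
    eff = long["efficiency"].to_numpy(dtype=float)
    if np.any(eff < -1e-9) or np.any(eff > 1 + 1e-9):  # NaN compares False
        raise CostingError("efficiency scores must lie in [0, 1]")
    out["presenteeism"] = (1.0 - eff) * long["days_with_complaints"].to_numpy(dtype=float) * hours * wage
    out["absenteeism_unpaid"] = long["unpaid_hours_lost"].to_numpy(dtype=float) * wages.shadow_price

    out["healthcare_total"] = out[list(HEALTHCARE_CATEGORIES)].sum(axis=1, skipna=False)
    out["lost_productivity_total"] = out[list(PRODUCTIVITY_COMPONENTS)].sum(axis=1, skipna=False)
    out["societal_total"] = out[list(ALL_COMPONENTS)].sum(axis=1, skipna=False)

    baseline_rows = out[out["month"] == 0].set_index("id")
    baseline_societal = baseline_rows["societal_total"].rename("baseline_societal")

    period = out[out["month"] > 0].reset_index(drop=True)
    annual = period.drop(columns="month").groupby("id").sum(min_count=len(months))

    return CostBreakdown(
        period=period,
        annual=annual,
        baseline_societal=baseline_societal,
        perspective=perspective,
        approach=approach,
    )


def perspective_total(breakdown: CostBreakdown, which: str | None = None) -> pd.DataFrame:
    """Per-period totals under a perspective (components are never dropped)."""
    which = which or breakdown.perspective
    if which == "societal":
        col = "societal_total"
    elif which == "healthcare":
        col = "healthcare_total"
    else:
        raise CostingError(f"unknown perspective {which!r}")
    return breakdown.period[["id", "month", col]].rename(columns={col: "cost"})
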