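"""Clinical and quality-of-life outcome construction.

Utilities are obtained from EQ-5D-5L health-state profiles through an
additive value set (tariff): utility = 1 minus the sum of the decrements
for each dimension at its reported level.  QALYs over the trial year are
the area under the utility-versus-time curve by the trapezoid rule: for
each pair of consecutive measurements the average of the two utilities
is multiplied by the time in years between them, and the segments are
summed.  RAND-36 subscale sums are rescaled linearly to 0-100 with
higher scores meaning better functioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")


class ValidationError(ValueError):
    """Raised on malformed profiles, trajectories or scores."""


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L tariff: per-dimension decrements for levels 2-5.

    ``decrements[dim]`` is a 4-tuple of utility losses for levels 2, 3,
    4 and 5 of that dimension; level 1 (no problems) loses nothing, so
    the profile ``11111`` is anchored at utility 1.  Decrements must be
    non-negative and non-decreasing with level.
    """

    name: str
    decrements: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        missing = set(DIMENSIONS) - set(self.decrements)
        if missing:
            raise ValidationError(f"value set {self.name!r} lacks dimensions {missing}")
        for dim, decs in self.decrements.items():
            if len(decs) != 4:
                raise ValidationError(f"{dim}: need decrements for levels 2-5")
            if any(d < 0 for d in decs):
                raise ValidationError(f"{dim}: decrements must be >= 0")
            if any(b < a for a, b in zip(decs, decs[1:])):
                raise ValidationError(f"{dim}: decrements must be non-decreasing with level")

    @property
    def minimum_utility(self) -> float:
        """Utility of the worst state 55555."""
        return 1.0 - sum(self.decrements[d][3] for d in DIMENSIONS)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "ValueSet":
        """Read a tariff table with columns dimension, level, decrement."""
        table = pd.read_csv(path)
        decs: dict[str, list[float]] = {}
        for dim in DIMENSIONS:
            rows = table[table["dimension"] == dim].sort_values("level")
            if list(rows["level"]) != [2, 3, 4, 5]:
                raise ValidationError(f"tariff table must list levels 2-5 for {dim}")
            decs[dim] = tuple(rows["decrement"].astype(float))
        return cls(name=name or str(path), decrements=decs)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"dimension": dim, "level": lvl + 2, "decrement": dec}
            for dim in DIMENSIONS
            for lvl, dec in enumerate(self.decrements[dim])
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def example_value_set() -> ValueSet:
    """Illustrative additive tariff for testing (synthetic, not a national tariff)."""
    return ValueSet(
        name="illustrative-synthetic",
        decrements={
            "mobility": (0.04, 0.10, 0.22, 0.34),
            "self_care": (0.04, 0.09, 0.21, 0.27),
            "usual_activities": (0.03, 0.08, 0.17, 0.22),
            "pain_discomfort": (0.05, 0.12, 0.26, 0.39),
            "anxiety_depression": (0.06, 0.14, 0.29, 0.43),
        },
    )


def utility_from_state(state: str, value_set: ValueSet) -> float:
    """Map a five-digit EQ-5D-5L profile (e.g. ``"21321"``) to a utility."""
    state = str(state)
    if len(state) != 5 or any(c not in "12345" for c in state):
        raise ValidationError(f"malformed EQ-5D-5L profile {state!r}: need five digits 1-5")
    u = 1.0
    for dim, ch in zip(DIMENSIONS, state):
        level = int(ch)
        if level > 1:
            u -= value_set.decrements[dim][level - 2]
    return u


def qaly_auc(times_years, utilities) -> float:
    """Total QALYs: sum over segments of mean(u_i, u_{i+1}) x (t_{i+1} - t_i).

    ``times_years`` must be strictly increasing with at least two points.
    No flooring is applied, so value sets allowing negative utilities can
    yield negative QALYs.
    """
    t = np.asarray(times_years, dtype=float)
    u = np.asarray(utilities, dtype=float)
    if t.ndim != 1 or t.shape != u.shape:
        raise ValidationError("times and utilities must be 1-D and equal length")
    if t.size < 2:
        raise ValidationError("a QALY trajectory needs at least two measurements")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("measurement times must be strictly increasing")
    if np.any(np.isnan(u)):
        raise ValidationError("utility trajectory contains missing values; impute first")
    if np.any(u > 1.0 + 1e-12):
        raise ValidationError("utilities cannot exceed 1 (full health)")
    return float(np.trapezoid(u, t))


def disease_burden(utility: float) -> float:
    """Disease burden of a health state: 1 minus its utility.

    Used to place a condition on willingness-to-pay scales; e.g. mean
    utilities of 0.52 (moderate) and 0.39 (severe depression) give
    burdens of 0.48 and 0.61.
    """
    if utility > 1.0:
        raise ValidationError("utility cannot exceed 1")
    return 1.0 - utility


def subscale_score(raw_item_sum: float, raw_min: float, raw_max: float) -> float:
    """Linear 0-100 transform of a RAND-36 subscale raw sum."""
    if not raw_min < raw_max:
        raise ValidationError("raw_min must be below raw_max")
    if not raw_min <= raw_item_sum <= raw_max:
        raise ValidationError(
            f"raw sum {raw_item_sum} outside its range [{raw_min}, {raw_max}]"
        )
    return 100.0 * (raw_item_sum - raw_min) / (raw_max - raw_min)


def qalys_per_participant(long: pd.DataFrame, timepoints) -> pd.Series:
    """QALYs over the trial span for every participant in a long table.

    Requires complete (post-imputation) utility trajectories; months are
    converted to years as months/12.
    """
    months = np.asarray(sorted(timepoints), dtype=float)
    years = months / 12.0
    wide = long.pivot(index="id", columns="month", values="utility").reindex(columns=months)
    if wide.isna().any().any():
        raise ValidationError("utility trajectories incomplete; impute before computing QALYs")
    values = wide.to_numpy(dtype=float)
    qalys = np.trapezoid(values, years, axis=1)
    return pd.Series(qalys, index=wide.index, name="qaly")
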