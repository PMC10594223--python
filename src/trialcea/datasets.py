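"""Longitudinal trial data container and delimited-text I/O.

A :class:`TrialDataset` holds a 2x2 factorial psychotherapy trial
(session frequency x therapy type) as two tidy tables:

``baseline``
    one row per participant: arm labels, site, severity stratum,
    demographics, employment, sessions attended and the pre-treatment
    (3 months before start) resource use.
``long``
    one row per participant per assessment (months 0, 3, 6, 9, 12):
    clinical outcomes (BDI-II, EQ-5D-5L utility, RAND-36 physical and
    social functioning), resource-use counts and productivity-loss
    fields covering the 3 months before the assessment.

Missing values are plain NaN / empty cells; month-0 rows are always
complete.  Everything round-trips through uncompressed CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: participant-level columns, in canonical order
BASELINE_COLUMNS = [
    "id", "frequency_arm", "therapy", "site", "severity_stratum",
    "age", "gender", "education", "employed", "hours_per_day",
    "sessions_attended",
]

#: outcome columns measured at every assessment
OUTCOME_COLUMNS = ["bdi", "utility", "pfs", "sfs"]

#: resource-use count columns (quantities per 3-month recall period)
RESOURCE_COLUMNS = [
    "gp_visits", "psychiatrist_visits", "psychologist_visits",
    "psych_hospital_days", "antidepressant_ddd", "informal_care_hours",
]

#: productivity-loss columns per recall period
PRODUCTIVITY_COLUMNS = [
    "absence_days", "absence_episode_id", "days_with_complaints",
    "efficiency", "unpaid_hours_lost",
]

LONG_COLUMNS = ["id", "month"] + OUTCOME_COLUMNS + RESOURCE_COLUMNS + PRODUCTIVITY_COLUMNS

ARMS = ("twice", "once")
THERAPIES = ("CBT", "IPT")


@dataclass
class TrialDataset:
    """Participant-level longitudinal records of a frequency-of-sessions trial."""

    baseline: pd.DataFrame
    long: pd.DataFrame
    timepoints: tuple[float, ...] = (0, 3, 6, 9, 12)
    eq5d_states: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in BASELINE_COLUMNS if c not in self.baseline.columns]
        if missing:
            raise ValueError(f"baseline table lacks columns {missing}")
        missing = [c for c in LONG_COLUMNS if c not in self.long.columns]
        if missing:
            raise ValueError(f"long table lacks columns {missing}")
        bad = set(self.baseline["frequency_arm"]) - set(ARMS)
        if bad:
            raise ValueError(f"unknown frequency arm labels {bad}")
        bad = set(self.baseline["therapy"]) - set(THERAPIES)
        if bad:
            raise ValueError(f"unknown therapy labels {bad}")

    @property
    def n_participants(self) -> int:
        return len(self.baseline)

    @property
    def followup_months(self) -> tuple[float, ...]:
        return tuple(t for t in self.timepoints if t > 0)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            baseline=self.baseline.copy(),
            long=self.long.copy(),
            timepoints=self.timepoints,
            eq5d_states=None if self.eq5d_states is None else self.eq5d_states.copy(),
        )

    def observed_counts(self) -> pd.Series:
        """Participants with an observed assessment (non-missing BDI) per month."""
        obs = self.long.dropna(subset=["bdi"])
        return obs.groupby("month")["id"].nunique()

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, directory: str | Path) -> None:
        """Write ``baseline.csv`` and ``long.csv`` (empty cells = missing)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(directory / "baseline.csv", index=False)
        self.long.to_csv(directory / "long.csv", index=False)
        if self.eq5d_states is not None:
            self.eq5d_states.to_csv(directory / "eq5d_states.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "TrialDataset":
        directory = Path(directory)
        baseline = pd.read_csv(directory / "baseline.csv")
        long = pd.read_csv(directory / "long.csv")
        states_path = directory / "eq5d_states.csv"
        states = pd.read_csv(states_path, dtype={"state": str}) if states_path.exists() else None
        timepoints = tuple(sorted(long["month"].unique()))
        return cls(baseline=baseline, long=long, timepoints=timepoints, eq5d_states=states)

    def equals(self, other: "TrialDataset") -> bool:
        a = self.long.reset_index(drop=True)
        b = other.long.reset_index(drop=True)
        return self.baseline.reset_index(drop=True).equals(
            other.baseline.reset_index(drop=True)
        ) and a.equals(b)


def arm_indicator(baseline: pd.DataFrame) -> np.ndarray:
    """1 for the twice-weekly arm, 0 for once-weekly (the comparator)."""
    return (baseline["frequency_arm"].to_numpy() == "twice").astype(float)


def therapy_indicator(baseline: pd.DataFrame) -> np.ndarray:
    """1 for IPT, 0 for CBT (factorial-design adjuster)."""
    return (baseline["therapy"].to_numpy() == "IPT").astype(float)
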