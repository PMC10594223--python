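"""Configuration objects for the synthetic trial generator and the analysis.

Both configs are plain dataclasses with eager validation and YAML/JSON
loaders, so a pipeline run is fully specified by one file plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


# Paper-reported follow-up fractions at months 0, 3, 6, 9, 12.
DEFAULT_DROPOUT_TARGETS = (1.0, 0.725, 0.765, 0.70, 0.69)

# Group trajectory differences (twice-weekly minus once-weekly), one per
# timepoint.  BDI difference peaks at month 6, near-zero at month 9 and
# modest again at 12 months; the utility differences integrate to about
# 0.0175 QALYs over the year.
DEFAULT_EFFECT_BDI = (0.0, -2.0, -3.5, -0.5, -2.0)
DEFAULT_EFFECT_UTILITY = (0.0, 0.02, 0.03, 0.01, 0.02)


@dataclass
class TrialConfig:
    """Parameters of the synthetic 2x2 factorial trial.

    The defaults emulate the study conditions: cell sizes 49/49/47/55
    (frequency x therapy), nine sites, assessments at months 0-12,
    an annual societal cost difference of ~EUR 2000 driven by mental
    healthcare, occasional very expensive mental-healthcare outliers,
    and follow-up falling to 69% at 12 months with dropout predicted
    by education and baseline physical functioning.
    """

    cell_sizes: tuple[int, int, int, int] = (49, 49, 47, 55)  # twice-CBT, once-CBT, twice-IPT, once-IPT
    n_sites: int = 9
    timepoints: tuple[float, ...] = (0, 3, 6, 9, 12)
    true_effect_bdi: tuple[float, ...] = DEFAULT_EFFECT_BDI
    true_effect_utility: tuple[float, ...] = DEFAULT_EFFECT_UTILITY
    true_cost_diff: float = 2000.0
    outlier_rate: float = 0.04
    dropout_targets: tuple[float, ...] = DEFAULT_DROPOUT_TARGETS
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_sizes = tuple(int(c) for c in self.cell_sizes)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.true_effect_bdi = tuple(float(x) for x in self.true_effect_bdi)
        self.true_effect_utility = tuple(float(x) for x in self.true_effect_utility)
        self.dropout_targets = tuple(float(x) for x in self.dropout_targets)
        if len(self.cell_sizes) != 4 or any(c < 0 for c in self.cell_sizes):
            raise ConfigurationError("cell_sizes must be four non-negative integers")
        if sum(self.cell_sizes) <= 0:
            raise ConfigurationError("cell_sizes must sum to a positive total")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be positive")
        if self.timepoints[0] != 0 or any(
            b <= a for a, b in zip(self.timepoints, self.timepoints[1:])
        ):
            raise ConfigurationError("timepoints must start at 0 and strictly increase")
        k = len(self.timepoints)
        for name in ("true_effect_bdi", "true_effect_utility", "dropout_targets"):
            if len(getattr(self, name)) != k:
                raise ConfigurationError(
                    f"{name} must have one entry per timepoint ({k}), "
                    f"got {len(getattr(self, name))}"
                )
        if any(not (0.0 < f <= 1.0) for f in self.dropout_targets):
            raise ConfigurationError("dropout_targets must lie in (0, 1]")
        if self.dropout_targets[0] != 1.0:
            raise ConfigurationError("baseline follow-up fraction must be 1.0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ConfigurationError("outlier_rate must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(self.cell_sizes)

    @classmethod
    def from_file(cls, path: str | Path) -> "TrialConfig":
        return cls(**_load_mapping(path))

    def to_dict(self) -> dict:
        return asdict(self)


SENSITIVITY_VARIANTS = ("healthcare", "human_capital", "outliers", "baseline_adjust")


@dataclass
class AnalysisConfig:
    """Settings of one cost-effectiveness analysis run.

    ``perspective`` selects which cost components enter the totals,
    ``approach`` the absenteeism valuation, and the outlier / baseline
    switches reproduce the sensitivity analyses.  ``b_replications`` is
    the bootstrap size per imputed dataset (5000 in a full run) and the
    ``m_*`` / ``fmi_threshold`` fields govern the adaptive number of
    imputations.
    """

    perspective: str = "societal"            # societal | healthcare
    approach: str = "friction"               # friction | human_capital
    outlier_rule: bool = False
    outlier_threshold: float = 10_000.0      # EUR per 3-month period
    outlier_whole_participant: bool = True   # recode all periods vs offending period only
    baseline_cost_adjust: bool = False
    outcomes: tuple[str, ...] = ("bdi", "qaly", "pfs", "sfs")
    b_replications: int = 5000
    m_initial: int = 5
    m_max: int = 40
    fmi_threshold: float = 0.05
    stratify_imputation: bool = True
    acceleration: bool = True                # BCa vs bias-corrected-only bootstrap
    session_unit_cost: float = 100.0         # EUR per 45-min psychotherapy session
    seed: int = 0
    lambda_grid: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.perspective not in ("societal", "healthcare"):
            raise ConfigurationError(f"unknown perspective {self.perspective!r}")
        if self.approach not in ("friction", "human_capital"):
            raise ConfigurationError(f"unknown costing approach {self.approach!r}")
        if self.outlier_rule and not self.outlier_threshold > 0:
            raise ConfigurationError("outlier_threshold must be positive when the rule is on")
        if self.b_replications < 1:
            raise ConfigurationError("b_replications must be >= 1")
        if self.m_initial < 2:
            raise ConfigurationError("m_initial must be >= 2")
        if self.m_max < self.m_initial:
            raise ConfigurationError("m_max must be >= m_initial")
        if not (0.0 < self.fmi_threshold <= 1.0):
            raise ConfigurationError("fmi_threshold must lie in (0, 1]")
        unknown = set(self.outcomes) - {"bdi", "qaly", "pfs", "sfs"}
        if unknown:
            raise ConfigurationError(f"unknown outcomes {unknown}")
        if self.lambda_grid is None:
            self.lambda_grid = default_lambda_grid()
        self.lambda_grid = tuple(float(x) for x in self.lambda_grid)
        if any(x < 0 for x in self.lambda_grid) or any(
            b <= a for a, b in zip(self.lambda_grid, self.lambda_grid[1:])
        ):
            raise ConfigurationError("lambda_grid must be non-negative and increasing")

    def variant(self, which: str) -> "AnalysisConfig":
        """Return the config for one of the four sensitivity analyses."""
        if which not in SENSITIVITY_VARIANTS:
            raise ConfigurationError(
                f"unknown sensitivity variant {which!r}; choose from {SENSITIVITY_VARIANTS}"
            )
        d = asdict(self)
        if which == "healthcare":
            d["perspective"] = "healthcare"
        elif which == "human_capital":
            d["approach"] = "human_capital"
        elif which == "outliers":
            d["outlier_rule"] = True
        elif which == "baseline_adjust":
            d["baseline_cost_adjust"] = True
        return AnalysisConfig(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**_load_mapping(path))

    def to_dict(self) -> dict:
        return asdict(self)


def default_lambda_grid() -> tuple[float, ...]:
    """0 to 100 000 EUR in 251 steps, plus the commonly quoted ceiling ratios."""
    grid = set(float(x) for x in range(0, 100_001, 400))
    grid.update({1000.0, 20_000.0, 23_000.0, 30_000.0, 34_000.0, 50_000.0})
    return tuple(sorted(grid))


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    for key in ("cell_sizes", "timepoints", "true_effect_bdi", "true_effect_utility",
                "dropout_targets", "outcomes", "lambda_grid"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return data
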