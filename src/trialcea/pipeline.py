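"""End-to-end orchestration: data -> costing -> imputation -> inference -> CEA.

Thin layer over :class:`~trialcea.model.CostEffectivenessModel` that
wires a data source (a synthetic-trial config or CSV inputs) to a fitted
:class:`~trialcea.model.CEAResults` and optionally writes the report
artefacts.  The four sensitivity analyses re-run the same pipeline with
exactly one stage changed: the perspective filter, the absenteeism
valuation, the cost-outlier recode before imputation, or the
baseline-cost adjuster in the cost models.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .config import AnalysisConfig, TrialConfig, SENSITIVITY_VARIANTS
from .costing import UnitCostTable, WageSchedule, default_unit_costs
from .datasets import TrialDataset
from .model import CEAResults, CostEffectivenessModel
from .simulate import make_trial

logger = logging.getLogger(__name__)


def build_model(trial_config: TrialConfig | None = None,
                data: TrialDataset | None = None,
                data_dir: str | Path | None = None,
                analysis_config: AnalysisConfig | None = None,
                unit_costs: UnitCostTable | None = None,
                wages: WageSchedule | None = None) -> CostEffectivenessModel:
    """Assemble a model from exactly one data source."""
    sources = [s for s in (trial_config, data, data_dir) if s is not None]
    if len(sources) != 1:
        raise ValueError("provide exactly one of trial_config, data or data_dir")
    if trial_config is not None:
        data = make_trial(trial_config)
    elif data_dir is not None:
        data = TrialDataset.from_csv(data_dir)
    return CostEffectivenessModel(
        data, unit_costs=unit_costs or default_unit_costs(),
        wages=wages or WageSchedule(), config=analysis_config or AnalysisConfig())


def run_main(trial_config: TrialConfig | None = None,
             analysis_config: AnalysisConfig | None = None,
             outdir: str | Path | None = None, **kwargs) -> CEAResults:
    """Run the full main analysis; write report files when ``outdir`` is set."""
    t0 = time.time()
    model = build_model(trial_config=trial_config,
                        analysis_config=analysis_config, **kwargs)
    results = model.fit()
    logger.info("pipeline finished in %.1f s (m=%s, FMI=%s)",
                time.time() - t0, results.metadata.get("m"),
                results.metadata.get("fmi"))
    if outdir is not None:
        results.save(outdir)
    return results


def run_sensitivity(which: str, trial_config: TrialConfig | None = None,
                    analysis_config: AnalysisConfig | None = None,
                    outdir: str | Path | None = None, **kwargs) -> CEAResults:
    """Run one of the four sensitivity analyses.

    ``which`` is one of ``healthcare`` (healthcare perspective),
    ``human_capital`` (absenteeism valued over its full duration),
    ``outliers`` (periods costing >= EUR 10 000 recoded missing and
    re-imputed) or ``baseline_adjust`` (cost models adjusted for
    pre-treatment societal costs).
    """
    base = analysis_config or AnalysisConfig()
    cfg = base.variant(which)
    return run_main(trial_config=trial_config, analysis_config=cfg,
                    outdir=outdir, **kwargs)


def run_all(trial_config: TrialConfig | None = None,
            analysis_config: AnalysisConfig | None = None,
            outdir: str | Path | None = None, **kwargs) -> dict[str, CEAResults]:
    """Main analysis plus all four sensitivity analyses."""
    outdir = Path(outdir) if outdir is not None else None
    results = {"main": run_main(trial_config, analysis_config,
                                outdir and outdir / "main", **kwargs)}
    for which in SENSITIVITY_VARIANTS:
        results[which] = run_sensitivity(which, trial_config, analysis_config,
                                         outdir and outdir / which, **kwargs)
    return results
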