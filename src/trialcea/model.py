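"""Trial-based cost-effectiveness model and its fitted results.

:class:`CostEffectivenessModel` bundles a (possibly incomplete)
longitudinal trial dataset with its costing inputs and an
:class:`~trialcea.config.AnalysisConfig`; :meth:`fit` runs the full
analysis — costing and outcome construction, chained-equation multiple
imputation with an adaptive number of imputations, per-imputation
adjusted regression, Rubin's-rules pooling, within-imputation
bootstrap, and the decision-analytic outputs — and returns a
:class:`CEAResults` carrying the estimates, their uncertainty,
diagnostics, a ``summary()`` table and plotting/export helpers.

All randomised participants are analysed in their assigned arms
(intention to treat); missing assessments are filled by imputation,
never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cea import (CEACCurve, CEResult, ceac_cloud, ceac_parametric, icer,
                  orient_effect, quadrant_proportions)
from .config import AnalysisConfig
from .costing import (ALL_COMPONENTS, CostBreakdown, UnitCostTable,
                      WageSchedule, aggregate_costs, default_unit_costs)
from .datasets import TrialDataset, arm_indicator, therapy_indicator
from .imputation import (ImputationSpec, ImputedSet, PooledEstimate,
                         rubin_pool)
from .imputation import adapt_m as _adapt_m
from .inference import (BootstrapCloud, EffectEstimate, adjusted_difference,
                        longitudinal_effect, mi_bootstrap)

OUTCOME_LABELS = {
    "bdi": "BDI-II (overall effect over time)",
    "qaly": "QALYs (12 months)",
    "pfs": "Physical functioning (12 months)",
    "sfs": "Social functioning (12 months)",
}


def _fmt(x, nd=2):
    return "nan" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:,.{nd}f}"


class CostEffectivenessModel:
    """Economic evaluation of twice-weekly vs once-weekly psychotherapy.

    Parameters
    ----------
    data
        Trial dataset (long + baseline tables) with missingness flags
        as NaN.  Baseline must be complete.
    unit_costs, wages
        Valuation inputs; defaults are the illustrative 2021 tables.
    config
        Analysis settings (perspective, costing approach, sensitivity
        switches, imputation and bootstrap policy, seed).
    """

    def __init__(self, data: TrialDataset, unit_costs: UnitCostTable | None = None,
                 wages: WageSchedule | None = None,
                 config: AnalysisConfig | None = None):
        self.data = data
        self.unit_costs = unit_costs or default_unit_costs()
        self.wages = wages or WageSchedule()
        self.config = config or AnalysisConfig()
        self._followups = [m for m in data.timepoints if m > 0]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, directory: str | Path, **kwargs) -> "CostEffectivenessModel":
        return cls(TrialDataset.from_csv(directory), **kwargs)

    # -- stage 1: costing and outcome construction -------------------------

    def cost_breakdown(self) -> CostBreakdown:
        return aggregate_costs(
            self.data, self.unit_costs, self.wages,
            approach=self.config.approach, perspective=self.config.perspective,
            session_unit_cost=self.config.session_unit_cost)

    def build_wide(self, breakdown: CostBreakdown | None = None) -> pd.DataFrame:
        """Participant-level analysis frame (one row each, NaN = missing).

        Holds baseline covariates, the outcome measurements per
        timepoint and the period-level healthcare / non-healthcare
        costs that the imputation model works on.
        """
        breakdown = breakdown or self.cost_breakdown()
        base = self.data.baseline.set_index("id")
        wide = pd.DataFrame(index=base.index)
        wide["arm"] = arm_indicator(self.data.baseline)
        wide["therapy"] = therapy_indicator(self.data.baseline)
        wide["age"] = base["age"].astype(float)
        wide["female"] = (base["gender"] == "female").astype(float)
        wide["education"] = base["education"].astype(float)
        wide["employed"] = base["employed"].astype(float)
        wide["baseline_cost"] = breakdown.baseline_societal.reindex(base.index)

        long = self.data.long
        for col in ("bdi", "utility", "pfs", "sfs"):
            piv = long.pivot(index="id", columns="month", values=col)
            for t in self.data.timepoints:
                if col in ("pfs", "sfs") and t not in (0, self._followups[-1]):
                    continue  # functioning analysed at 12 months only
                wide[f"{col}_{t:g}"] = piv[t].reindex(base.index)

        per = breakdown.period.set_index(["id", "month"])
        for t in self._followups:
            hc = per["healthcare_total"].xs(t, level="month").reindex(base.index)
            soc = per["societal_total"].xs(t, level="month").reindex(base.index)
            wide[f"cost_hc_{t:g}"] = hc
            wide[f"cost_oth_{t:g}"] = soc - hc
        if self.config.outlier_rule:
            wide = self._apply_outlier_rule(wide)
        return wide

    def _apply_outlier_rule(self, wide: pd.DataFrame) -> pd.DataFrame:
        """Recode very expensive periods (societal cost >= threshold) as missing."""
        wide = wide.copy()
        cost_cols = [f"cost_{k}_{t:g}" for t in self._followups for k in ("hc", "oth")]
        period_tot = {
            t: wide[f"cost_hc_{t:g}"] + wide[f"cost_oth_{t:g}"] for t in self._followups
        }
        any_outlier = pd.Series(False, index=wide.index)
        for t, tot in period_tot.items():
            flag = tot >= self.config.outlier_threshold
            any_outlier |= flag.fillna(False)
            if not self.config.outlier_whole_participant:
                wide.loc[flag.fillna(False), [f"cost_hc_{t:g}", f"cost_oth_{t:g}"]] = np.nan
        if self.config.outlier_whole_participant:
            wide.loc[any_outlier, cost_cols] = np.nan
        return wide

    # -- derived quantities on a completed frame ----------------------------

    def _annual_cost(self, completed: pd.DataFrame, perspective: str | None = None) -> pd.Series:
        perspective = perspective or self.config.perspective
        hc = sum(completed[f"cost_hc_{t:g}"] for t in self._followups)
        if perspective == "healthcare":
            return hc
        return hc + sum(completed[f"cost_oth_{t:g}"] for t in self._followups)

    def _qaly(self, completed: pd.DataFrame) -> pd.Series:
        months = np.asarray(self.data.timepoints, dtype=float)
        utils = completed[[f"utility_{t:g}" for t in months]].to_numpy(dtype=float)
        return pd.Series(np.trapezoid(utils, months / 12.0, axis=1),
                         index=completed.index, name="qaly")

    def _analysis_frame(self, completed: pd.DataFrame) -> pd.DataFrame:
        """Completed wide frame plus derived annual cost and QALYs."""
        df = completed.copy()
        df["annual_cost"] = self._annual_cost(completed)
        df["qaly"] = self._qaly(completed)
        last = self._followups[-1]
        df["pfs_final"] = df[f"pfs_{last:g}"]
        df["sfs_final"] = df[f"sfs_{last:g}"]
        return df

    def _cost_adjusters(self) -> tuple[str, ...]:
        if self.config.baseline_cost_adjust:
            return ("therapy", "baseline_cost")
        return ("therapy",)

    def _bdi_long(self, completed: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for t in self._followups:
            rows.append(pd.DataFrame({
                "id": completed.index,
                "month": t,
                "bdi": completed[f"bdi_{t:g}"].to_numpy(dtype=float),
                "bdi_baseline": completed["bdi_0"].to_numpy(dtype=float),
                "arm": completed["arm"].to_numpy(dtype=float),
                "therapy": completed["therapy"].to_numpy(dtype=float),
            }))
        return pd.concat(rows, ignore_index=True)

    def _effect_estimate(self, completed: pd.DataFrame, outcome: str) -> EffectEstimate:
        df = self._analysis_frame(completed)
        if outcome == "bdi":
            return longitudinal_effect(self._bdi_long(completed))
        column = {"qaly": "qaly", "pfs": "pfs_final", "sfs": "sfs_final",
                  "cost": "annual_cost"}[outcome]
        adj = self._cost_adjusters() if outcome == "cost" else ("therapy",)
        est = adjusted_difference(df, column, adjusters=adj)
        est.outcome = outcome
        return est

    # -- imputation ---------------------------------------------------------

    def imputation_spec(self, wide: pd.DataFrame) -> ImputationSpec:
        variables = [c for c in wide.columns if wide[c].isna().any()]
        return ImputationSpec(
            variables=tuple(variables),
            k=5, sweeps=10,
            m_initial=self.config.m_initial, m_max=self.config.m_max,
            fmi_threshold=self.config.fmi_threshold,
            stratify_by="arm" if self.config.stratify_imputation else None,
            seed=self.config.seed)

    def _monitor(self, completed: pd.DataFrame) -> dict[str, tuple[float, float]]:
        """Headline parameters whose FMI steers the number of imputations."""
        cost = self._effect_estimate(completed, "cost")
        qaly = self._effect_estimate(completed, "qaly")
        return {"delta_cost": (cost.estimate, cost.se ** 2),
                "delta_qaly": (qaly.estimate, qaly.se ** 2)}

    def impute(self, wide: pd.DataFrame | None = None) -> ImputedSet:
        wide = wide if wide is not None else self.build_wide()
        spec = self.imputation_spec(wide)
        if not spec.variables:
            from .imputation import mice_pmm
            return mice_pmm(wide, spec, m=spec.m_initial)
        return _adapt_m(wide, spec, self._monitor)

    # -- the full fit -------------------------------------------------------

    def fit(self) -> "CEAResults":
        cfg = self.config
        breakdown = self.cost_breakdown()
        wide = self.build_wide(breakdown)
        imputed = self.impute(wide)

        # per-imputation regression estimates, pooled by Rubin's rules
        pooled: dict[str, PooledEstimate] = {}
        names = list(cfg.outcomes) + ["cost"]
        per_imp: dict[str, list[EffectEstimate]] = {n: [] for n in names}
        for completed in imputed.datasets:
            for name in names:
                per_imp[name].append(self._effect_estimate(completed, name))
        for name in names:
            ests = per_imp[name]
            pooled[name] = rubin_pool([e.estimate for e in ests],
                                      [e.se ** 2 for e in ests])

        # bootstrap clouds and CEA per outcome
        effect_columns = {"qaly": "qaly", "pfs": "pfs_final", "sfs": "sfs_final"}
        frames = [self._analysis_frame(c) for c in imputed.datasets]
        ce_results: dict[str, CEResult] = {}
        clouds: dict[str, BootstrapCloud] = {}
        for name in cfg.outcomes:
            if name == "bdi":
                cloud, boot_pooled = self._bdi_mi_bootstrap(imputed)
            else:
                cloud, boot_pooled = mi_bootstrap(
                    frames, "annual_cost", effect_columns[name],
                    b_per_dataset=cfg.b_replications, seed=cfg.seed,
                    cost_adjusters=self._cost_adjusters(),
                    acceleration=cfg.acceleration)
            clouds[name] = cloud
            ce_results[name] = self._assemble_ce(name, cloud, boot_pooled, pooled)

        return CEAResults(
            model=self, effects=pooled, per_imputation=per_imp,
            ce_results=ce_results, clouds=clouds, imputed=imputed,
            cost_breakdown_=breakdown,
            metadata={
                "n_participants": self.data.n_participants,
                "m": imputed.m, "fmi": imputed.fmi,
                "fmi_converged": imputed.converged,
                "b_replications": cfg.b_replications,
                "seed": cfg.seed, "perspective": cfg.perspective,
                "approach": cfg.approach, "outlier_rule": cfg.outlier_rule,
                "baseline_cost_adjust": cfg.baseline_cost_adjust,
                "version": _pkg_version,
            })

    def _bdi_mi_bootstrap(self, imputed: ImputedSet):
        """Joint (delta cost, longitudinal BDI effect) bootstrap."""
        cfg = self.config
        T = len(self._followups)
        datasets = imputed.datasets
        dc_all, de_all, imp_all = [], [], []
        est_c, var_c, est_e, var_e = [], [], [], []
        from .inference import (_bca_interval, delta_statistic_factory,
                                stratified_indices)
        per_imp = []
        for j, completed in enumerate(datasets):
            df = self._analysis_frame(completed)
            f_cost = delta_statistic_factory(df, "annual_cost", self._cost_adjusters())
            f_bdi = self._longitudinal_factory(completed)
            arm = df["arm"].to_numpy()
            n = len(df)
            rng = np.random.default_rng([cfg.seed, 4, j])
            theta_c, theta_e = f_cost(np.arange(n)), f_bdi(np.arange(n))
            dc = np.empty(cfg.b_replications)
            de = np.empty(cfg.b_replications)
            for b in range(cfg.b_replications):
                idx = stratified_indices(arm, rng)
                dc[b] = f_cost(idx)
                de[b] = f_bdi(idx)
            jack_c = jack_e = None
            if cfg.acceleration:
                all_idx = np.arange(n)
                jack_c = np.array([f_cost(np.delete(all_idx, i)) for i in all_idx])
                jack_e = np.array([f_bdi(np.delete(all_idx, i)) for i in all_idx])
            ci_c = _bca_interval(theta_c, dc, jack_c, 0.05, cfg.acceleration)
            ci_e = _bca_interval(theta_e, de, jack_e, 0.05, cfg.acceleration)
            per_imp.append({"delta_cost": (theta_c, ci_c), "delta_effect": (theta_e, ci_e)})
            dc_all.append(dc)
            de_all.append(de)
            imp_all.append(np.full(cfg.b_replications, j))
            est_c.append(theta_c)
            var_c.append(dc.var(ddof=1))
            est_e.append(theta_e)
            var_e.append(de.var(ddof=1))
        cloud = BootstrapCloud(
            delta_cost=np.concatenate(dc_all), delta_effect=np.concatenate(de_all),
            imputation=np.concatenate(imp_all), b_per_dataset=cfg.b_replications,
            seed=cfg.seed)
        boot_pooled = {"delta_cost": rubin_pool(est_c, var_c),
                       "delta_effect": rubin_pool(est_e, var_e),
                       "per_imputation": per_imp}
        return cloud, boot_pooled

    def _longitudinal_factory(self, completed: pd.DataFrame):
        """Fast closed-form longitudinal arm coefficient for resamples."""
        T = len(self._followups)
        n = len(completed)
        y = completed[[f"bdi_{t:g}" for t in self._followups]].to_numpy(dtype=float).ravel()
        arm = np.repeat(completed["arm"].to_numpy(dtype=float), T)
        base = np.repeat(completed["bdi_0"].to_numpy(dtype=float), T)
        ther = np.repeat(completed["therapy"].to_numpy(dtype=float), T)
        X = np.column_stack([np.ones(n * T), arm, base, ther] + [
            np.tile((np.arange(T) == k).astype(float), n) for k in range(1, T)
        ])
        offsets = np.arange(T)

        def f(idx: np.ndarray) -> float:
            rows = (np.asarray(idx)[:, None] * T + offsets).ravel()
            Xi, yi = X[rows], y[rows]
            beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
            return float(beta[1])

        return f

    def _assemble_ce(self, name: str, cloud: BootstrapCloud, boot_pooled,
                     pooled: dict[str, PooledEstimate]) -> CEResult:
        cfg = self.config
        lam = np.asarray(cfg.lambda_grid)
        dC, dE = pooled["cost"].estimate, pooled[name].estimate
        dE_orient = float(orient_effect(dE, name))
        the_icer = icer(dC, dE_orient)

        de_cloud = orient_effect(cloud.delta_effect, name)
        quads = quadrant_proportions(delta_cost=cloud.delta_cost, delta_effect=de_cloud)

        # parametric CEAC: per-imputation NMB and bootstrap (co)variances,
        # pooled per ceiling ratio by Rubin's rules
        m = int(cloud.imputation.max()) + 1
        est_c = np.array([v["delta_cost"][0] for v in boot_pooled["per_imputation"]])
        est_e = orient_effect(
            np.array([v["delta_effect"][0] for v in boot_pooled["per_imputation"]]), name)
        var_c = np.empty(m)
        var_e = np.empty(m)
        cov_ce = np.empty(m)
        for j in range(m):
            mask = cloud.imputation == j
            dcj, dej = cloud.delta_cost[mask], de_cloud[mask]
            var_c[j] = dcj.var(ddof=1)
            var_e[j] = dej.var(ddof=1)
            cov_ce[j] = np.cov(dcj, dej, ddof=1)[0, 1]
        nmb_j = lam[:, None] * est_e[None, :] - est_c[None, :]          # (L, m)
        vnmb_j = (lam[:, None] ** 2 * var_e[None, :] + var_c[None, :]
                  - 2 * lam[:, None] * cov_ce[None, :])
        vnmb_j = np.maximum(vnmb_j, 0.0)
        qbar = nmb_j.mean(axis=1)
        W = vnmb_j.mean(axis=1)
        Bv = nmb_j.var(axis=1, ddof=1) if m > 1 else np.zeros_like(qbar)
        Tv = W + (1 + 1 / m) * Bv if m > 1 else W
        se = np.sqrt(np.maximum(Tv, 0.0))
        curve = ceac_parametric(qbar, se, lam)
        cloud_curve = ceac_cloud(cloud, lam)
        # cloud effects must be orientation-corrected for BDI
        if name == "bdi":
            cloud_curve = CEACCurve(
                tuple(float(x) for x in lam),
                tuple(float(np.mean(l * de_cloud - cloud.delta_cost > 0)) for l in lam),
                "cloud-proportion")

        pc = boot_pooled["delta_cost"]
        pe = boot_pooled["delta_effect"]
        return CEResult(
            outcome=name, delta_cost=dC, delta_effect=dE, icer=the_icer,
            quadrants=quads, ceac=curve, ceac_cloud=cloud_curve,
            cost_ci=(pc.ci_low, pc.ci_high), effect_ci=(pe.ci_low, pe.ci_high),
            extras={"pooled_cost": pc, "pooled_effect": pe})


@dataclass
class CEAResults:
    """Fitted economic-evaluation results.

    ``effects`` maps outcome names (plus ``"cost"``) to Rubin-pooled
    adjusted differences (twice-weekly minus once-weekly);
    ``ce_results`` holds the decision-analytic outputs per outcome and
    ``clouds`` the bootstrap cost-effect pairs behind them.
    """

    model: CostEffectivenessModel
    effects: dict[str, PooledEstimate]
    per_imputation: dict[str, list[EffectEstimate]]
    ce_results: dict[str, CEResult]
    clouds: dict[str, BootstrapCloud]
    imputed: ImputedSet
    cost_breakdown_: CostBreakdown
    metadata: dict = field(default_factory=dict)

    # -- tables -------------------------------------------------------------

    def effects_table(self) -> pd.DataFrame:
        rows = []
        for name, p in self.effects.items():
            rows.append({
                "outcome": name, "difference": p.estimate, "se": p.se,
                "ci_low": p.ci_low, "ci_high": p.ci_high,
                "fmi": p.fmi, "m": p.m,
            })
        return pd.DataFrame(rows).set_index("outcome")

    def cost_category_table(self) -> pd.DataFrame:
        """Observed-case annual cost components per arm (descriptive)."""
        period = self.cost_breakdown_.period.copy()
        base = self.model.data.baseline.set_index("id")
        period["arm"] = base["frequency_arm"].reindex(period["id"]).to_numpy()
        rows = {}
        for comp in list(ALL_COMPONENTS) + ["healthcare_total",
                                            "lost_productivity_total", "societal_total"]:
            annual = period.groupby(["arm", "id"])[comp].sum(min_count=1)
            means = annual.groupby("arm").mean()
            rows[comp] = {
                "twice_weekly_mean": means.get("twice", np.nan),
                "once_weekly_mean": means.get("once", np.nan),
            }
        out = pd.DataFrame(rows).T
        out["difference"] = out["twice_weekly_mean"] - out["once_weekly_mean"]
        return out

    def ceac_table(self, outcome: str) -> pd.DataFrame:
        curve = self.ce_results[outcome].ceac
        return pd.DataFrame({"lambda": curve.lambdas,
                             "probability": curve.probabilities})

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Cost-effectiveness analysis: twice-weekly vs once-weekly psychotherapy",
            "=" * 74,
            f"participants: {md.get('n_participants')}   imputations m: {md.get('m')}"
            f"   bootstrap B/imputation: {md.get('b_replications')}",
            f"perspective: {md.get('perspective')}   absenteeism: {md.get('approach')}"
            f"   seed: {md.get('seed')}",
            "",
            "Pooled adjusted differences (twice-weekly minus once-weekly)",
            "-" * 74,
            f"{'outcome':<28}{'diff':>12}{'95% CI':>26}{'FMI':>8}",
        ]
        for name, p in self.effects.items():
            label = OUTCOME_LABELS.get(name, name) if name != "cost" else \
                f"Societal costs (EUR)" if md.get("perspective") == "societal" \
                else "Healthcare costs (EUR)"
            nd = 3 if name == "qaly" else 2
            ci = f"({_fmt(p.ci_low, nd)} to {_fmt(p.ci_high, nd)})"
            lines.append(f"{label:<28}{_fmt(p.estimate, nd):>12}{ci:>26}{p.fmi:>8.3f}")
        lines += ["", "Cost-effectiveness", "-" * 74,
                  f"{'outcome':<28}{'ICER':>12}{'NE/SE/SW/NW':>22}{'p(CE)':>10}"]
        for name, ce in self.ce_results.items():
            q = ce.quadrants
            quad = "/".join(f"{q[k]:.2f}" for k in ("NE", "SE", "SW", "NW"))
            lam_ref = 50_000.0 if name == "qaly" else 1000.0
            try:
                p_ce = ce.ceac.at(lam_ref)
                ptxt = f"{p_ce:.2f}@{lam_ref:,.0f}"
            except Exception:
                ptxt = "-"
            icer_txt = _fmt(ce.icer.value, 0) if ce.icer.defined else "undef"
            lines.append(f"{OUTCOME_LABELS.get(name, name):<28}{icer_txt:>12}"
                         f"{quad:>22}{ptxt:>14}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_plane(self, outcome: str, path: str | Path | None = None, ax=None):
        """Scatter of bootstrap (delta effect, delta cost) pairs."""
        import matplotlib.pyplot as plt
        cloud = self.clouds[outcome]
        de = orient_effect(cloud.delta_effect, outcome)
        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 4))
        else:
            fig = ax.figure
        ax.scatter(de, cloud.delta_cost, s=3, alpha=0.25, linewidths=0)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel(f"difference in effect ({outcome}, improvement positive)")
        ax.set_ylabel("difference in societal costs (EUR)")
        ax.set_title("Cost-effectiveness plane")
        if path:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax

    def plot_ceac(self, outcome: str, path: str | Path | None = None, ax=None):
        import matplotlib.pyplot as plt
        ce = self.ce_results[outcome]
        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 4))
        else:
            fig = ax.figure
        ax.plot(ce.ceac.lambdas, ce.ceac.probabilities, label="parametric NMB")
        if ce.ceac_cloud is not None:
            ax.plot(ce.ceac_cloud.lambdas, ce.ceac_cloud.probabilities,
                    ls="--", label="cloud proportion")
        ax.set_ylim(0, 1)
        ax.set_xlabel("ceiling ratio (EUR per unit of effect)")
        ax.set_ylabel("probability cost-effective")
        ax.set_title(f"CEAC: {OUTCOME_LABELS.get(outcome, outcome)}")
        ax.legend(frameon=False)
        if path:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax

    # -- export -------------------------------------------------------------

    def report_dict(self) -> dict:
        out = {"metadata": self.metadata, "effects": {}, "cea": {}}
        for name, p in self.effects.items():
            out["effects"][name] = {
                "difference": p.estimate, "se": p.se,
                "ci": [p.ci_low, p.ci_high], "fmi": p.fmi, "m": p.m,
            }
        for name, ce in self.ce_results.items():
            out["cea"][name] = {
                "delta_cost": ce.delta_cost, "delta_effect": ce.delta_effect,
                "icer": ce.icer.value, "icer_defined": ce.icer.defined,
                "quadrants": ce.quadrants,
                "cost_ci": list(ce.cost_ci) if ce.cost_ci else None,
                "effect_ci": list(ce.effect_ci) if ce.effect_ci else None,
            }
        return out

    def save(self, outdir: str | Path, plots: bool = True) -> None:
        """Write report JSON, tables, bootstrap clouds, CEACs and figures."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.report_dict(), indent=2, default=float, sort_keys=True))
        self.effects_table().to_csv(outdir / "effects.csv")
        self.cost_category_table().to_csv(outdir / "cost_categories.csv")
        for name in self.ce_results:
            self.ceac_table(name).to_csv(outdir / f"ceac_{name}.csv", index=False)
            self.clouds[name].to_frame().to_csv(outdir / f"cloud_{name}.csv", index=False)
            if plots:
                self.plot_plane(name, outdir / f"plane_{name}.png")
                self.plot_ceac(name, outdir / f"ceac_{name}.png")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
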