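"""Between-group estimation and bootstrap uncertainty.

Differences in 12-month outcomes (QALYs, functioning scores, annual
costs) between the twice-weekly and once-weekly arms are estimated with
least-squares regression adjusted for therapy type (the second factor
of the 2x2 design) and optional baseline adjusters.  Depression
severity is analysed longitudinally: BDI-II at months 3-12 is modelled
with time-specific intercepts, the arm main effect, baseline BDI-II and
therapy type, with participant-level dependence handled by
cluster-robust standard errors; the arm coefficient is the overall
average effect over follow-up.

Because costs are heavily skewed, uncertainty around cost and
cost-effect statistics is quantified by nonparametric bootstrap with
bias correction and (optionally) acceleration: participants are
resampled within arm, the bias-correction constant comes from the
share of replicates below the point estimate, the acceleration from
jackknife skewness, and the adjusted percentile endpoints are read off
the replicate distribution.  With multiply imputed data the bootstrap
runs within every completed dataset; the (delta cost, delta effect)
replicate pairs are concatenated across imputations for the
cost-effectiveness plane and acceptability curves, while scalar
intervals are pooled by Rubin's rules using the bootstrap variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .imputation import ImputedSet, PooledEstimate, rubin_pool

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass
class EffectEstimate:
    """Adjusted mean difference, twice-weekly minus once-weekly."""

    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    adjusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9):
            raise InferenceError("confidence interval must contain the point estimate")


@dataclass
class BootstrapCloud:
    """(delta cost, delta effect) bootstrap replicates across imputations."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    imputation: np.ndarray
    b_per_dataset: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.delta_cost)
        if not (len(self.delta_effect) == len(self.imputation) == n):
            raise InferenceError("cloud arrays must have equal length")

    @property
    def n_pairs(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.n_pairs),
            "imputation": self.imputation,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
        })


# ---------------------------------------------------------------------------
# regression estimators
# ---------------------------------------------------------------------------

def _check_design(X: pd.DataFrame) -> None:
    mat = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the aliased column; prefer blaming the latest-added adjuster
        for col in reversed(list(X.columns)):
            reduced = sm.add_constant(X.drop(columns=col).to_numpy(dtype=float),
                                      has_constant="add")
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise InferenceError(f"design is rank deficient: column {col!r} is aliased")
        raise InferenceError("design is rank deficient")


def adjusted_difference(data: pd.DataFrame, outcome: str,
                        adjusters: tuple[str, ...] = ("therapy",),
                        arm_col: str = "arm") -> EffectEstimate:
    """Arm coefficient of OLS ``outcome ~ arm + adjusters`` on one completed dataset."""
    if data[outcome].isna().any():
        raise InferenceError(f"outcome {outcome!r} has missing values; impute first")
    arms = data[arm_col].nunique()
    if arms < 2:
        raise InferenceError("both trial arms must be present")
    X = data[[arm_col, *adjusters]]
    _check_design(X)
    model = sm.OLS(data[outcome].to_numpy(dtype=float),
                   sm.add_constant(X.to_numpy(dtype=float), has_constant="add"))
    res = model.fit()
    est, se = float(res.params[1]), float(res.bse[1])
    lo, hi = res.conf_int()[1]
    return EffectEstimate(outcome, est, se, float(lo), float(hi), tuple(adjusters))


def longitudinal_effect(long: pd.DataFrame, outcome: str = "bdi",
                        baseline_col: str = "bdi_baseline",
                        arm_col: str = "arm", therapy_col: str = "therapy",
                        id_col: str = "id", time_col: str = "month") -> EffectEstimate:
    """Overall arm effect on a repeated outcome over follow-up.

    ``long`` holds post-baseline rows only, complete after imputation,
    with the participant's baseline value merged in.  Time enters as
    categorical intercepts; the participant clustering enters through
    cluster-robust standard errors.
    """
    if long[time_col].nunique() < 2:
        raise InferenceError("need at least two post-baseline timepoints")
    if long[outcome].isna().any():
        raise InferenceError("longitudinal outcome must be complete; impute first")
    times = sorted(long[time_col].unique())
    X = pd.DataFrame({
        "arm": long[arm_col].to_numpy(dtype=float),
        "baseline": long[baseline_col].to_numpy(dtype=float),
        "therapy": long[therapy_col].to_numpy(dtype=float),
    }, index=long.index)
    for t in times[1:]:
        X[f"t{t:g}"] = (long[time_col] == t).astype(float)
    model = sm.OLS(long[outcome].to_numpy(dtype=float),
                   sm.add_constant(X.to_numpy(dtype=float), has_constant="add"))
    res = model.fit(cov_type="cluster", cov_kwds={"groups": long[id_col]})
    est, se = float(res.params[1]), float(res.bse[1])
    lo, hi = res.conf_int()[1]
    return EffectEstimate(outcome, est, se, float(lo), float(hi),
                          ("baseline", "therapy", "time"))


# ---------------------------------------------------------------------------
# bias-corrected (and accelerated) bootstrap
# ---------------------------------------------------------------------------

def _bca_interval(theta: float, reps: np.ndarray, jack: np.ndarray | None,
                  alpha: float, acceleration: bool) -> tuple[float, float]:
    reps = np.asarray(reps, dtype=float)
    if np.ptp(reps) == 0:
        logger.warning("degenerate bootstrap distribution: interval collapses to a point")
        return float(reps[0]), float(reps[0])
    B = len(reps)
    prop = np.clip(np.mean(reps < theta) + 0.5 * np.mean(reps == theta),
                   1 / (B + 1), 1 - 1 / (B + 1))
    z0 = stats.norm.ppf(prop)
    a = 0.0
    if acceleration and jack is not None and np.ptp(jack) > 0:
        d = jack.mean() - jack
        a = float((d ** 3).sum() / (6.0 * ((d ** 2).sum()) ** 1.5))
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
    a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
    lo, hi = np.quantile(reps, [a1, a2], method="linear")
    return float(lo), float(hi)


def bca_bootstrap(sample, statistic, b_replications: int = 5000, seed: int = 0,
                  acceleration: bool = True, alpha: float = 0.05):
    """BCa confidence interval for ``statistic`` of a 1-sample dataset.

    Returns ``(point_estimate, (ci_low, ci_high), replicates)``.  With
    ``acceleration=False`` the interval is bias-corrected only.
    """
    x = np.asarray(sample)
    n = len(x)
    if b_replications < 100:
        raise InferenceError("use at least 100 bootstrap replications")
    rng = np.random.default_rng([seed, 3])
    theta = float(statistic(x))
    idx = rng.integers(0, n, size=(b_replications, n))
    reps = np.array([statistic(x[i]) for i in idx], dtype=float)
    jack = None
    if acceleration:
        jack = np.array([statistic(np.delete(x, i)) for i in range(n)], dtype=float)
    ci = _bca_interval(theta, reps, jack, alpha, acceleration)
    return theta, ci, reps


def delta_statistic_factory(data: pd.DataFrame, outcome: str,
                            adjusters: tuple[str, ...] = ("therapy",),
                            arm_col: str = "arm"):
    """Fast closed-form arm-coefficient evaluator for bootstrap resamples.

    Returns ``f(idx) -> float`` computing the adjusted arm difference on
    the participant rows ``idx`` via the normal equations.
    """
    X = np.column_stack([
        np.ones(len(data)),
        data[arm_col].to_numpy(dtype=float),
        data[list(adjusters)].to_numpy(dtype=float) if adjusters else
        np.empty((len(data), 0)),
    ])
    y = data[outcome].to_numpy(dtype=float)

    def f(idx: np.ndarray) -> float:
        Xi, yi = X[idx], y[idx]
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
        return float(beta[1])

    return f


def stratified_indices(arm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample participants within frequency arm, preserving arm sizes."""
    idx = np.empty(len(arm), dtype=int)
    pos = 0
    for value in np.unique(arm):
        members = np.flatnonzero(arm == value)
        take = rng.integers(0, len(members), size=len(members))
        idx[pos:pos + len(members)] = members[take]
        pos += len(members)
    return idx


def mi_bootstrap(imputed: ImputedSet | list[pd.DataFrame], cost_outcome: str,
                 effect_outcome: str, b_per_dataset: int = 5000, seed: int = 0,
                 cost_adjusters: tuple[str, ...] = ("therapy",),
                 effect_adjusters: tuple[str, ...] = ("therapy",),
                 arm_col: str = "arm", acceleration: bool = True,
                 alpha: float = 0.05):
    """Joint (delta cost, delta effect) bootstrap across imputed datasets.

    Within each completed dataset, participants are resampled (within
    arm, jointly for costs and effects so their correlation is kept)
    ``b_per_dataset`` times; the pairs are concatenated across the m
    datasets.  Returns ``(cloud, pooled)`` where ``pooled`` maps
    ``"delta_cost"`` / ``"delta_effect"`` to Rubin-pooled estimates
    whose within variance is the bootstrap variance, plus per-imputation
    BCa intervals under ``"per_imputation"``.
    """
    datasets = imputed.datasets if isinstance(imputed, ImputedSet) else imputed
    m = len(datasets)
    dc_all, de_all, imp_all = [], [], []
    est_c, var_c, est_e, var_e = [], [], [], []
    per_imp = []
    for j, df in enumerate(datasets):
        rng = np.random.default_rng([seed, 4, j])
        arm = df[arm_col].to_numpy()
        f_cost = delta_statistic_factory(df, cost_outcome, cost_adjusters, arm_col)
        f_eff = delta_statistic_factory(df, effect_outcome, effect_adjusters, arm_col)
        theta_c, theta_e = f_cost(np.arange(len(df))), f_eff(np.arange(len(df)))
        dc = np.empty(b_per_dataset)
        de = np.empty(b_per_dataset)
        for b in range(b_per_dataset):
            idx = stratified_indices(arm, rng)
            dc[b] = f_cost(idx)
            de[b] = f_eff(idx)
        jack_c = jack_e = None
        if acceleration:
            all_idx = np.arange(len(df))
            jack_c = np.array([f_cost(np.delete(all_idx, i)) for i in all_idx])
            jack_e = np.array([f_eff(np.delete(all_idx, i)) for i in all_idx])
        ci_c = _bca_interval(theta_c, dc, jack_c, alpha, acceleration)
        ci_e = _bca_interval(theta_e, de, jack_e, alpha, acceleration)
        per_imp.append({"delta_cost": (theta_c, ci_c), "delta_effect": (theta_e, ci_e)})
        dc_all.append(dc)
        de_all.append(de)
        imp_all.append(np.full(b_per_dataset, j))
        est_c.append(theta_c)
        var_c.append(dc.var(ddof=1))
        est_e.append(theta_e)
        var_e.append(de.var(ddof=1))

    cloud = BootstrapCloud(
        delta_cost=np.concatenate(dc_all), delta_effect=np.concatenate(de_all),
        imputation=np.concatenate(imp_all), b_per_dataset=b_per_dataset, seed=seed)
    pooled: dict[str, PooledEstimate | list] = {
        "delta_cost": rubin_pool(est_c, var_c, alpha=alpha),
        "delta_effect": rubin_pool(est_e, var_e, alpha=alpha),
        "per_imputation": per_imp,
    }
    return cloud, pooled
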