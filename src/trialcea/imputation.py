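"""Multiple imputation by chained equations with predictive mean matching.

Missing outcomes and period-level costs are filled by MICE-PMM: each
incomplete variable is regressed on its predictors among the observed
cases, regression coefficients are perturbed by a proper Bayesian draw,
and every missing entry receives the *observed* value of a donor drawn
uniformly from the ``k`` cases whose predicted means are closest to the
target's predicted mean.  PMM therefore never produces values outside
the observed support — in particular never negative costs — which is
why it suits skewed cost distributions.

Per-imputation results are pooled by Rubin's rules: with estimates
:math:`Q_j` and squared standard errors :math:`U_j` over :math:`m`
imputations, :math:`\\bar Q` is their mean, the within variance
:math:`W = \\bar U`, the between variance :math:`B` the sample variance
of the :math:`Q_j`, and the total variance :math:`T = W + (1 + 1/m) B`.
Confidence intervals use a t reference with Rubin's degrees of freedom.
The number of imputations is doubled — reusing earlier imputations via
per-imputation seed substreams — until the fraction of missing
information (FMI) of the monitored parameters falls below a threshold
(default 5%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSpec:
    """What to impute, from what, and how hard to try."""

    variables: tuple[str, ...]
    predictors: dict[str, tuple[str, ...]] | None = None  # default: all other spec columns
    k: int = 5                 # PMM donor pool size
    sweeps: int = 10           # chained-equation cycles per imputation
    m_initial: int = 5
    m_max: int = 40
    fmi_threshold: float = 0.05
    stratify_by: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ImputationError("donor pool size k must be >= 1")
        if self.m_initial < 2:
            raise ImputationError("m_initial must be >= 2")
        if self.m_max < self.m_initial:
            raise ImputationError("m_max must be >= m_initial")
        if not 0.0 < self.fmi_threshold <= 1.0:
            raise ImputationError("FMI threshold must lie in (0, 1]")


@dataclass
class ImputedSet:
    """m completed datasets plus imputation metadata."""

    datasets: list[pd.DataFrame]
    spec: ImputationSpec
    seed: int
    fmi: dict[str, float] = field(default_factory=dict)
    trace: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True

    @property
    def m(self) -> int:
        return len(self.datasets)

    def missing_fractions(self, original: pd.DataFrame) -> pd.Series:
        return original[list(self.spec.variables)].isna().mean()


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate with its variance decomposition."""

    estimate: float
    within: float
    between: float
    total: float
    m: int
    fmi: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


# ---------------------------------------------------------------------------
# the chained-equation engine
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _drop_unusable_predictors(df: pd.DataFrame, cols: list[str], target: str) -> list[str]:
    """Drop constant or collinear predictors, with a logged warning."""
    usable: list[str] = []
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.warning("dropping constant predictor %r for %r", c, target)
            continue
        usable.append(c)
    if usable:
        X = _design(df.fillna(df.mean(numeric_only=True)), usable)
        rank = np.linalg.matrix_rank(X)
        while rank < X.shape[1] and usable:
            dropped = usable.pop()
            logger.warning("dropping collinear predictor %r for %r", dropped, target)
            X = _design(df.fillna(df.mean(numeric_only=True)), usable)
            rank = np.linalg.matrix_rank(X)
    return usable


def _pmm_update(A: np.ndarray, vi: int, pidx: list[int], k: int,
                rng: np.random.Generator, miss: np.ndarray) -> None:
    """One PMM update of column ``vi`` of matrix ``A`` in place (type-1 matching)."""
    obs = ~miss
    y_obs = A[obs, vi]
    X_obs = np.column_stack([np.ones(obs.sum()), A[np.ix_(obs, pidx)]])
    X_mis = np.column_stack([np.ones(miss.sum()), A[np.ix_(miss, pidx)]])
    n_obs, p = X_obs.shape

    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - p, 1)
    s2 = float(resid @ resid) / dof
    # proper Bayesian perturbation of the coefficients
    sigma2_star = s2 * dof / rng.chisquare(dof)
    xtx = X_obs.T @ X_obs + 1e-10 * np.eye(p)
    cov = sigma2_star * np.linalg.pinv(xtx)
    try:
        L = np.linalg.cholesky((cov + cov.T) / 2)
    except np.linalg.LinAlgError:
        L = np.zeros_like(cov)
    beta_star = beta_hat + L @ rng.standard_normal(p)

    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    kk = min(k, n_obs)
    # nearest observed predicted means, one donor drawn per missing cell
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    choice = rng.integers(0, kk, size=len(pred_mis))
    donors = nearest[np.arange(len(pred_mis)), choice]
    A[miss, vi] = y_obs[donors]


def _predictor_indices(data: pd.DataFrame, spec: ImputationSpec) -> dict[str, list[int]]:
    """Resolve (and prune) the predictor matrix once per dataset."""
    cols = list(data.columns)
    out: dict[str, list[int]] = {}
    for var in spec.variables:
        raw = (list(spec.predictors[var]) if spec.predictors and var in spec.predictors
               else [c for c in cols if c != var])
        usable = _drop_unusable_predictors(data, raw, var)
        out[var] = [cols.index(c) for c in usable]
    return out


def _one_imputation(data: pd.DataFrame, spec: ImputationSpec,
                    rng: np.random.Generator,
                    pred_idx: dict[str, list[int]] | None = None) -> pd.DataFrame:
    cols = list(data.columns)
    A = data.to_numpy(dtype=float).copy()
    if pred_idx is None:
        pred_idx = _predictor_indices(data, spec)
    masks = {}
    for var in spec.variables:
        vi = cols.index(var)
        miss = np.isnan(A[:, vi])
        if miss.all():
            raise ImputationError(f"variable {var!r} has no observed values")
        masks[var] = miss
        if miss.any():  # initial fill: random draws from the observed values
            A[miss, vi] = rng.choice(A[~miss, vi], size=miss.sum(), replace=True)

    need = [v for v in spec.variables if masks[v].any()]
    for _sweep in range(spec.sweeps if need else 0):
        for var in need:
            _pmm_update(A, cols.index(var), pred_idx[var], spec.k, rng, masks[var])
    return pd.DataFrame(A, index=data.index, columns=cols)


def _imputation_rng(seed: int, j: int) -> np.random.Generator:
    # substream per imputation index: extending m keeps earlier imputations
    return np.random.default_rng([seed, 2, j])


def mice_pmm(data: pd.DataFrame, spec: ImputationSpec, m: int | None = None,
             first_index: int = 0) -> ImputedSet:
    """Produce ``m`` completed copies of ``data`` by chained-equation PMM.

    Non-imputed columns must be complete (they act as predictors).  With
    ``stratify_by`` set, chains run separately within each stratum (the
    analysis models can then still pool across strata).
    """
    m = m if m is not None else spec.m_initial
    numeric = data.select_dtypes(include=[np.number])
    missing_vars = [v for v in spec.variables if v not in data.columns]
    if missing_vars:
        raise ImputationError(f"variables not in data: {missing_vars}")
    # resolve strata and predictor matrices once, reused by every imputation
    if spec.stratify_by:
        strata = [sub[numeric.columns] for _, sub in data.groupby(spec.stratify_by, sort=True)]
    else:
        strata = [numeric]
    pred_idx = [_predictor_indices(sub, spec) for sub in strata]

    datasets = []
    for j in range(first_index, first_index + m):
        rng = _imputation_rng(spec.seed, j)
        completed = data.copy()
        for sub, pidx in zip(strata, pred_idx):
            done = _one_imputation(sub, spec, rng, pred_idx=pidx)
            completed.loc[done.index, done.columns] = done
        datasets.append(completed)
    return ImputedSet(datasets=datasets, spec=spec, seed=spec.seed)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Pool m point estimates and their squared standard errors."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ImputationError("estimates and variances must be 1-D and equal length")
    m = q.size
    if m == 0:
        raise ImputationError("need at least one estimate")
    qbar = float(q.mean())
    w = float(u.mean())
    if m == 1:
        se = float(np.sqrt(w))
        z = stats.norm.ppf(1 - alpha / 2)
        return PooledEstimate(qbar, w, 0.0, w, 1, 0.0, np.inf,
                              qbar - z * se, qbar + z * se)
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    if b <= 0 or t <= 0:
        fmi, df = 0.0, np.inf
    else:
        r = (1 + 1 / m) * b / w if w > 0 else np.inf
        df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) and r > 0 else m - 1
        fmi = (r + 2 / (df + 3)) / (r + 1) if np.isfinite(r) else 1.0 - 1e-12
    se = float(np.sqrt(t))
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    return PooledEstimate(qbar, w, b, t, m, min(fmi, 1.0 - 1e-12), df,
                          qbar - tcrit * se, qbar + tcrit * se)


def pool_analyses(imputed: ImputedSet, analysis) -> dict[str, PooledEstimate]:
    """Run ``analysis(completed) -> {name: (estimate, variance)}`` and pool."""
    per_param: dict[str, list[tuple[float, float]]] = {}
    for df in imputed.datasets:
        for name, (est, var) in analysis(df).items():
            per_param.setdefault(name, []).append((est, var))
    return {
        name: rubin_pool([e for e, _ in vals], [v for _, v in vals])
        for name, vals in per_param.items()
    }


def adapt_m(data: pd.DataFrame, spec: ImputationSpec, analysis) -> ImputedSet:
    """Double m until every monitored parameter's FMI is below threshold.

    ``analysis`` maps a completed dataset to ``{name: (estimate,
    variance)}``; the FMI is monitored on those parameters.  Earlier
    imputations are reused when m grows (seed substreams are indexed by
    imputation number).  Hitting ``m_max`` without convergence logs a
    warning but is not an error.
    """
    imputed = mice_pmm(data, spec, m=spec.m_initial)
    while True:
        pooled = pool_analyses(imputed, analysis)
        fmi = {name: p.fmi for name, p in pooled.items()}
        worst = max(fmi.values()) if fmi else 0.0
        imputed.fmi = fmi
        imputed.trace.append((imputed.m, worst))
        if worst < spec.fmi_threshold:
            imputed.converged = True
            return imputed
        if imputed.m >= spec.m_max:
            imputed.converged = False
            warnings.warn(
                f"FMI {worst:.3f} still above {spec.fmi_threshold} at m_max={spec.m_max}",
                stacklevel=2)
            logger.warning("adapt_m stopped at m_max=%d with FMI %.3f", imputed.m, worst)
            return imputed
        extra = min(imputed.m * 2, spec.m_max) - imputed.m
        more = mice_pmm(data, spec, m=extra, first_index=imputed.m)
        imputed.datasets.extend(more.datasets)
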