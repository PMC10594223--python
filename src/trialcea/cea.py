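"""Decision-analytic outputs: ICERs, plane quadrants, NMB and CEACs.

The incremental cost-effectiveness ratio divides the pooled cost
difference by the pooled effect difference.  Uncertainty is shown as
the distribution of bootstrapped (delta effect, delta cost) pairs over
the four quadrants of the cost-effectiveness plane, and as
cost-effectiveness acceptability curves: the probability that the
intervention is cost-effective at a ceiling ratio lambda, i.e. that its
net monetary benefit ``lambda * delta_effect - delta_cost`` exceeds
zero.  The primary curve is parametric — per imputation the NMB and its
standard error are computed, pooled by Rubin's rules, and the
probability is the normal CDF of pooled NMB over pooled SE — with the
cloud-proportion curve as a nonparametric cross-check.

Effects are oriented so that clinical improvement is positive before
any plane or CEAC logic: depression scores (BDI-II), where a decrease
is an improvement, are sign-flipped; QALYs and functioning scores keep
their natural direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .inference import BootstrapCloud


class CEAError(ValueError):
    pass


QUADRANTS = ("NE", "SE", "SW", "NW")


@dataclass
class ICERResult:
    value: float | None
    delta_cost: float
    delta_effect: float
    quadrant: str
    defined: bool = True


@dataclass
class CEACCurve:
    """(ceiling ratio, probability cost-effective) pairs."""

    lambdas: tuple[float, ...]
    probabilities: tuple[float, ...]
    method: str  # parametric-NMB | cloud-proportion

    def __post_init__(self) -> None:
        lam, p = np.asarray(self.lambdas), np.asarray(self.probabilities)
        if lam.shape != p.shape:
            raise CEAError("lambda grid and probabilities must match")
        if np.any(lam < 0) or np.any(np.diff(lam) <= 0):
            raise CEAError("lambda grid must be non-negative and increasing")
        if np.any((p < 0) | (p > 1)):
            raise CEAError("probabilities must lie in [0, 1]")

    def at(self, lam: float) -> float:
        i = np.flatnonzero(np.isclose(self.lambdas, lam))
        if len(i) == 0:
            raise CEAError(f"ceiling ratio {lam} is not on the grid")
        return self.probabilities[int(i[0])]


@dataclass
class CEResult:
    """Cost-effectiveness summary for one outcome."""

    outcome: str
    delta_cost: float
    delta_effect: float
    icer: ICERResult
    quadrants: dict[str, float]
    ceac: CEACCurve
    ceac_cloud: CEACCurve | None = None
    cost_ci: tuple[float, float] | None = None
    effect_ci: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """delta cost / delta effect with its plane quadrant.

    ``delta_effect`` is on the improvement-positive scale.  A zero
    effect difference yields an undefined ICER (flagged, not raised):
    dominance reasoning is left to the caller.
    """
    if delta_effect >= 0:
        quadrant = "NE" if delta_cost >= 0 else "SE"
    else:
        quadrant = "NW" if delta_cost >= 0 else "SW"
    if delta_effect == 0:
        return ICERResult(None, delta_cost, delta_effect, quadrant, defined=False)
    return ICERResult(float(delta_cost / delta_effect), delta_cost, delta_effect, quadrant)


def orient_effect(values, outcome: str):
    """Flip the sign of outcomes where a decrease is an improvement (BDI-II)."""
    arr = np.asarray(values, dtype=float)
    return -arr if outcome.lower().startswith("bdi") else arr


def quadrant_proportions(cloud: BootstrapCloud | None = None,
                         delta_cost=None, delta_effect=None) -> dict[str, float]:
    """Share of bootstrap pairs per cost-effectiveness plane quadrant.

    Effects must already be improvement-positive.  Boundary pairs are
    assigned by the half-open convention: delta effect >= 0 counts as
    favourable, delta cost >= 0 as more costly.
    """
    if cloud is not None:
        delta_cost, delta_effect = cloud.delta_cost, cloud.delta_effect
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_effect, dtype=float)
    if dc.size == 0:
        raise CEAError("empty bootstrap cloud")
    fav, costly = de >= 0, dc >= 0
    n = dc.size
    return {
        "NE": float(np.sum(fav & costly)) / n,
        "SE": float(np.sum(fav & ~costly)) / n,
        "SW": float(np.sum(~fav & ~costly)) / n,
        "NW": float(np.sum(~fav & costly)) / n,
    }


def nmb(delta_effect: float, delta_cost: float, lam: float) -> float:
    """Net monetary benefit at ceiling ratio ``lam`` (improvement-positive effect)."""
    if lam < 0:
        raise CEAError("ceiling ratio must be non-negative")
    return lam * delta_effect - delta_cost


def ceac_parametric(pooled_nmb, pooled_se, lambdas) -> CEACCurve:
    """Probability cost-effective from pooled NMB estimates and their SEs.

    At each ceiling ratio the probability is ``Phi(NMB / SE)``; a zero
    SE degenerates to 0 or 1 by the sign of the NMB.
    """
    lam = tuple(float(x) for x in lambdas)
    est = np.asarray(pooled_nmb, dtype=float)
    se = np.asarray(pooled_se, dtype=float)
    if not (len(lam) == est.size == se.size):
        raise CEAError("need one pooled NMB and SE per ceiling ratio")
    ok = se > 0
    ratio = np.zeros_like(est)
    ratio[ok] = est[ok] / se[ok]
    p = np.where(ok, stats.norm.cdf(ratio),
                 (est > 0).astype(float) + 0.5 * (est == 0))
    return CEACCurve(lam, tuple(float(x) for x in p), "parametric-NMB")


def ceac_cloud(cloud: BootstrapCloud, lambdas, outcome: str | None = None) -> CEACCurve:
    """Fraction of bootstrap pairs with positive NMB per ceiling ratio."""
    dc = np.asarray(cloud.delta_cost, dtype=float)
    de = np.asarray(cloud.delta_effect, dtype=float)
    if outcome is not None:
        de = orient_effect(de, outcome)
    if dc.size == 0:
        raise CEAError("empty bootstrap cloud")
    lam = np.asarray(sorted(float(x) for x in lambdas))
    p = [(float(np.mean(l * de - dc > 0))) for l in lam]
    return CEACCurve(tuple(lam), tuple(p), "cloud-proportion")
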