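"""Seeded synthetic 2x2 factorial psychotherapy trial generator.

Emulates the statistical structure of a session-frequency trial in
depression so the whole analysis pipeline can be exercised without
patient data:

* four cells (session frequency x therapy type), block randomisation
  emulated within depression-severity stratum (baseline BDI-II >= 29
  vs below) and treatment site, blocks of 4;
* all participants enter with baseline BDI-II >= 20; symptom
  trajectories follow configurable group mean curves (the default
  difference peaks at month 6, almost vanishes at month 9 and is
  modest at 12 months) on top of a participant random effect;
* EQ-5D-5L utilities are generated directly with a built-in negative
  correlation to concurrent BDI-II; physical and social functioning
  track symptoms on a 0-100 scale;
* resource use is heavy-tailed via lognormal participant frailties,
  with occasional very expensive mental-healthcare users (psychiatric
  admissions) as a separate mixture component; the configured annual
  societal cost difference is loaded onto mental-healthcare use;
* follow-up loss is missing-at-random given education and baseline
  physical functioning (whole assessments, plus a little item-level
  missingness), baseline always complete.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import ConfigurationError, TrialConfig
from .datasets import (LONG_COLUMNS, OUTCOME_COLUMNS, RESOURCE_COLUMNS,
                       TrialDataset)
from .outcomes import ValueSet, example_value_set, utility_from_state

#: mean BDI-II change from baseline in the once-weekly (reference) arm
CONTROL_BDI_CHANGE = (0.0, -6.0, -7.5, -8.0, -8.5)

#: mean attended sessions by arm (truncated to [0, 20])
MEAN_SESSIONS = {"twice": 16.5, "once": 14.7}

WORKING_DAYS_PER_MONTH = 21.7
BLOCK_SIZE = 4

# logistic dropout coefficients (per SD of the covariate); completers are
# more highly educated and have higher baseline physical functioning
EDU_COEF = -0.45
PFS_COEF = -0.45
ITEM_MISSING_RATE = 0.02

CELLS = (("twice", "CBT"), ("once", "CBT"), ("twice", "IPT"), ("once", "IPT"))


def _truncated_normal(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size=size)
    bad = (x < low) | (x > high)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = (x < low) | (x > high)
    return x


def _assign_cells(rng, site, stratum, cell_sizes):
    """Permuted-block arm assignment within site x severity stratum.

    Blocks of 4 alternate 2 twice-weekly / 2 once-weekly slots; therapy
    is drawn within frequency proportionally to the remaining cell
    quotas, so the requested cell sizes are met exactly while blocks
    stay balanced wherever quotas allow.
    """
    n = len(site)
    freq_quota = {"twice": cell_sizes[0] + cell_sizes[2], "once": cell_sizes[1] + cell_sizes[3]}
    cell_quota = {cell: size for cell, size in zip(CELLS, cell_sizes)}
    freq_arm = np.empty(n, dtype=object)
    therapy = np.empty(n, dtype=object)
    order = np.lexsort((rng.random(n), stratum, site))
    blocks = [order[start:start + BLOCK_SIZE] for start in range(0, n, BLOCK_SIZE)]
    # process blocks in random order so that, when the smaller arm's quota
    # runs out (96 vs 104 in the default design), the forced assignments
    # scatter over strata instead of piling up in the last site/stratum
    for bi in rng.permutation(len(blocks)):
        idx = blocks[bi]
        pattern = list(rng.permutation(["twice", "twice", "once", "once"]))[: len(idx)]
        for i, want in zip(idx, pattern):
            freq = want if freq_quota[want] > 0 else ("once" if want == "twice" else "twice")
            freq_quota[freq] -= 1
            options = [c for c in CELLS if c[0] == freq and cell_quota[c] > 0]
            weights = np.array([cell_quota[c] for c in options], dtype=float)
            cell = options[rng.choice(len(options), p=weights / weights.sum())]
            cell_quota[cell] -= 1
            freq_arm[i], therapy[i] = cell
    return freq_arm, therapy


def generate_trial(config: TrialConfig, with_states: bool = False,
                   value_set: ValueSet | None = None) -> TrialDataset:
    """Generate a fully observed synthetic trial dataset.

    With ``with_states=True`` an EQ-5D-5L profile table is attached and
    utilities are derived from the profiles through ``value_set``
    (default: the illustrative tariff) instead of being drawn directly.
    """
    tp = np.asarray(config.timepoints)
    if len(CONTROL_BDI_CHANGE) != len(tp):
        raise ConfigurationError("control trajectory and timepoints are non-conformable")
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_total
    vs = value_set or example_value_set()

    # -- participants -------------------------------------------------------
    ids = np.array([f"p{i:04d}" for i in range(1, n + 1)])
    site = rng.integers(1, config.n_sites + 1, size=n)
    age = np.round(_truncated_normal(rng, 38, 12, 18, 64.99, n)).astype(int)
    gender = np.where(rng.random(n) < 0.64, "female", "male")
    education = rng.choice([0, 1, 2], size=n, p=[0.25, 0.40, 0.35])
    employed = rng.random(n) < 0.60
    hours_per_day = np.where(employed, 8.0, 0.0)
    bdi0 = np.round(_truncated_normal(rng, 31, 8, 20, 63, n))
    stratum = np.where(bdi0 >= 29, "high", "low")
    freq_arm, therapy = _assign_cells(rng, site, stratum, config.cell_sizes)
    is_twice = (freq_arm == "twice").astype(float)

    sessions = np.round(np.clip(
        rng.normal([MEAN_SESSIONS[a] for a in freq_arm], 2.2), 0, 20))

    baseline = pd.DataFrame({
        "id": ids, "frequency_arm": freq_arm, "therapy": therapy, "site": site,
        "severity_stratum": stratum, "age": age, "gender": gender,
        "education": education, "employed": employed.astype(int),
        "hours_per_day": hours_per_day, "sessions_attended": sessions,
    })

    # -- clinical trajectories ---------------------------------------------
    n_tp = len(tp)
    u_bdi = rng.normal(0, 5.0, size=n)        # participant random effect
    bdi = (bdi0[:, None]
           + np.asarray(CONTROL_BDI_CHANGE)[None, :]
           + is_twice[:, None] * np.asarray(config.true_effect_bdi)[None, :]
           + u_bdi[:, None] * (tp > 0)[None, :]
           + rng.normal(0, 5.0, size=(n, n_tp)) * (tp > 0)[None, :])
    bdi = np.clip(np.round(bdi), 0, 63)
    bdi[:, 0] = bdi0

    states = None
    if with_states:
        # anxiety/depression level tracks BDI; other dimensions milder
        probs_other = np.array([0.45, 0.30, 0.15, 0.07, 0.03])
        ad_level = np.clip(np.round(bdi / 14.0 + rng.normal(0, 0.6, size=bdi.shape)), 1, 5)
        digits = rng.choice([1, 2, 3, 4, 5], size=(n, n_tp, 4), p=probs_other)
        profiles = np.empty((n, n_tp), dtype=object)
        utility = np.empty((n, n_tp))
        for i in range(n):
            for j in range(n_tp):
                d = digits[i, j]
                s = f"{d[0]}{d[1]}{d[2]}{d[3]}{int(ad_level[i, j])}"
                # profile order: mobility, self-care, usual activities, pain, anxiety
                profiles[i, j] = s
                utility[i, j] = utility_from_state(s, vs)
        states = pd.DataFrame({
            "id": np.repeat(ids, n_tp), "month": np.tile(tp, n),
            "state": profiles.ravel(),
        })
    else:
        # Utility tracks BDI net of the arm effect, so the configured
        # per-timepoint utility difference is the *total* arm difference
        # (the symptom-mediated channel is not double counted) while the
        # negative utility-BDI correlation is preserved.
        v_u = rng.normal(0, 0.06, size=n)
        bdi_net = bdi - is_twice[:, None] * np.asarray(config.true_effect_bdi)[None, :]
        utility = (0.97 - 0.0135 * bdi_net
                   + is_twice[:, None] * np.asarray(config.true_effect_utility)[None, :]
                   + v_u[:, None] + rng.normal(0, 0.05, size=(n, n_tp)))
        utility = np.round(np.clip(utility, vs.minimum_utility, 1.0), 4)

    pfs = np.clip(np.round(86 - 0.9 * bdi + rng.normal(0, 8, size=(n, n_tp)), 1), 0, 100)
    sfs = np.clip(np.round(92 - 1.4 * bdi + rng.normal(0, 9, size=(n, n_tp)), 1), 0, 100)

    # -- resource use (heavy-tailed, frailty-driven, BDI-independent) ------
    frailty = rng.lognormal(mean=-0.32, sigma=0.8, size=n)       # mean ~1
    gp = rng.poisson(1.0 * frailty[:, None], size=(n, n_tp)).astype(float)
    psychiatrist = rng.poisson(0.6 * frailty[:, None], size=(n, n_tp)).astype(float)
    # The configured annual societal cost difference is loaded onto
    # additional psychologist contacts (unit cost EUR 100), net of the
    # intervention-cost difference implied by the extra attended sessions
    # (1.8 sessions at the reference session cost of EUR 100), so that
    # the total arm-wise annual societal means differ by true_cost_diff.
    session_diff_cost = (MEAN_SESSIONS["twice"] - MEAN_SESSIONS["once"]) * 100.0
    extra = ((config.true_cost_diff - session_diff_cost) / (n_tp - 1)) / 100.0
    psy_rate = 1.2 * frailty[:, None] + np.maximum(extra, 0) * is_twice[:, None] * (tp > 0)[None, :]
    psychologist = rng.poisson(psy_rate, size=(n, n_tp)).astype(float)
    if extra < 0:  # negative configured difference: load onto the once-weekly arm
        psy_rate = 1.2 * frailty[:, None] - extra * (1 - is_twice)[:, None] * (tp > 0)[None, :]
        psychologist = rng.poisson(psy_rate, size=(n, n_tp)).astype(float)
    hospital = np.zeros((n, n_tp))
    if n_tp > 1:
        is_outlier = rng.random(n) < config.outlier_rate
        outlier_period = rng.integers(1, n_tp, size=n)
        hospital[np.arange(n), outlier_period] = np.where(
            is_outlier, rng.poisson(12, size=n) + 3, 0)
    med_user = rng.random(n) < 0.5
    antidep = np.where(med_user[:, None], rng.poisson(88, size=(n, n_tp)), 0).astype(float)
    informal = np.round(rng.exponential(14, size=(n, n_tp)) * (rng.random((n, n_tp)) < 0.4), 1)

    # -- productivity losses ------------------------------------------------
    absence_days = np.zeros((n, n_tp))
    episode_id = np.full((n, n_tp), None, dtype=object)
    # pre-treatment absence (month 0 recall period)
    pre_abs = (rng.random(n) < 0.30) & employed
    absence_days[:, 0] = np.where(pre_abs, np.minimum(
        np.round(rng.lognormal(2.0, 1.0, size=n)), 60), 0)
    for i in np.where(pre_abs)[0]:
        episode_id[i, 0] = f"{ids[i]}-e0"
    # one in-trial episode for some employed participants, possibly long
    has_ep = (rng.random(n) < 0.45) & employed
    ep_start = rng.uniform(0, 11, size=n)                       # month
    ep_days = np.round(rng.lognormal(2.6, 1.1, size=n))         # working days, heavy tail
    months = np.asarray(config.timepoints)
    for i in np.where(has_ep)[0]:
        start_m, dur_m = ep_start[i], ep_days[i] / WORKING_DAYS_PER_MONTH
        end_m = min(start_m + dur_m, months[-1])
        for j in range(1, n_tp):
            lo, hi = months[j - 1], months[j]
            overlap = max(0.0, min(end_m, hi) - max(start_m, lo))
            if overlap > 0:
                absence_days[i, j] += round(overlap * WORKING_DAYS_PER_MONTH)
                episode_id[i, j] = f"{ids[i]}-e1"
    complaints = np.where(employed[:, None], rng.poisson(5, size=(n, n_tp)), 0).astype(float)
    efficiency = np.where(employed[:, None],
                          np.round(1.0 - 0.6 * rng.beta(2, 6, size=(n, n_tp)), 3), 1.0)
    unpaid = np.round(rng.exponential(8, size=(n, n_tp)), 1)

    long = pd.DataFrame({
        "id": np.repeat(ids, n_tp),
        "month": np.tile(tp, n),
        "bdi": bdi.ravel(), "utility": np.asarray(utility).ravel(),
        "pfs": pfs.ravel(), "sfs": sfs.ravel(),
        "gp_visits": gp.ravel(), "psychiatrist_visits": psychiatrist.ravel(),
        "psychologist_visits": psychologist.ravel(),
        "psych_hospital_days": hospital.ravel(),
        "antidepressant_ddd": antidep.ravel(),
        "informal_care_hours": informal.ravel(),
        "absence_days": absence_days.ravel(),
        "absence_episode_id": episode_id.ravel(),
        "days_with_complaints": complaints.ravel(),
        "efficiency": efficiency.ravel(),
        "unpaid_hours_lost": unpaid.ravel(),
    })[LONG_COLUMNS]

    return TrialDataset(baseline=baseline, long=long,
                        timepoints=config.timepoints, eq5d_states=states)


def inject_missingness(data: TrialDataset, config: TrialConfig,
                       edu_coef: float = EDU_COEF, pfs_coef: float = PFS_COEF,
                       item_rate: float = ITEM_MISSING_RATE) -> TrialDataset:
    """Apply MAR follow-up loss to a fully observed dataset.

    Whole assessments go missing with a logistic probability depending
    on education and baseline physical functioning (plus a participant
    frailty shared across timepoints, making dropout monotone-tending);
    per timepoint the intercept is calibrated so the expected observed
    fraction matches ``config.dropout_targets``.  A little independent
    item-level missingness is added on top; month 0 stays complete.
    """
    out = data.copy()
    long = out.long
    if long[OUTCOME_COLUMNS + RESOURCE_COLUMNS].isna().any().any():
        raise ValueError("inject_missingness expects a fully observed dataset")
    rng = np.random.default_rng([config.seed, 1])
    base = out.baseline.set_index("id")
    ids = base.index.to_numpy()

    edu = base["education"].to_numpy(dtype=float)
    pfs0 = long[long["month"] == 0].set_index("id")["pfs"].reindex(ids).to_numpy(dtype=float)
    z_edu = (edu - edu.mean()) / (edu.std() or 1.0)
    z_pfs = (pfs0 - pfs0.mean()) / (pfs0.std() or 1.0)
    frail = rng.normal(0, 1.0, size=len(ids))
    score = edu_coef * z_edu + pfs_coef * z_pfs + frail   # higher => more likely missing

    missing_cols = OUTCOME_COLUMNS + RESOURCE_COLUMNS + [
        "absence_days", "absence_episode_id", "days_with_complaints",
        "efficiency", "unpaid_hours_lost"]
    keep = 1.0 - item_rate
    for t, target in zip(config.timepoints, config.dropout_targets):
        if t == 0:
            continue
        # whole-assessment observation probability, calibrated so that the
        # expected observed fraction (net of item-level loss) hits the target
        goal = min(target / keep, 1.0)
        if goal >= 1.0:
            p_obs = np.ones(len(ids))
        else:
            def mean_obs(a):
                return expit(a - score).mean() - goal
            a_t = brentq(mean_obs, -20, 20)
            p_obs = expit(a_t - score)
        dropped = rng.random(len(ids)) > p_obs
        rows = long["month"] == t
        drop_rows = rows & long["id"].isin(ids[dropped])
        long.loc[drop_rows, missing_cols] = np.nan
        # item-level gaps among still-observed assessments
        obs_rows = long.index[rows & ~long["id"].isin(ids[dropped])]
        for col in missing_cols:
            if col == "absence_episode_id":
                continue
            hit = obs_rows[rng.random(len(obs_rows)) < item_rate]
            long.loc[hit, col] = np.nan
            if col == "absence_days":
                long.loc[hit, "absence_episode_id"] = np.nan
    return out


def make_trial(config: TrialConfig, with_missingness: bool = True, **kwargs) -> TrialDataset:
    """Generate a trial and (optionally) apply the MAR missingness mechanism."""
    data = generate_trial(config, **kwargs)
    return inject_missingness(data, config) if with_missingness else data
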