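import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialcea.imputation import ImputationSpec, mice_pmm
from trialcea.inference import (InferenceError, adjusted_difference,
                                bca_bootstrap, _bca_interval,
                                longitudinal_effect, mi_bootstrap,
                                stratified_indices)


def _two_arm_frame(n=300, delta=3.0, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    arm = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    therapy = rng.integers(0, 2, size=n).astype(float)
    y = 10.0 + delta * arm + 0.5 * therapy + rng.normal(scale=noise, size=n)
    return pd.DataFrame({"arm": arm, "therapy": therapy, "y": y})


class TestAdjustedDifference:
    def test_constant_outcome_gives_zero_difference(self):
        df = _two_arm_frame(n=60, seed=1)
        df["y"] = 7.0
        est = adjusted_difference(df, "y")
        assert est.estimate == pytest.approx(0.0, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_recovers_built_in_difference(self):
        df = _two_arm_frame(n=4000, delta=3.0, seed=2)
        est = adjusted_difference(df, "y")
        se = est.se
        assert est.estimate == pytest.approx(3.0, abs=4 * se)

    def test_orthogonal_balanced_adjuster_leaves_estimate_unchanged(self):
        df = _two_arm_frame(n=200, delta=2.0, seed=3)
        # an adjuster perfectly balanced within arm: orthogonal to arm
        df = df.sort_values("arm").reset_index(drop=True)
        df["balanced"] = np.tile([0.0, 1.0], len(df) // 2)
        base = adjusted_difference(df, "y", adjusters=())
        adj = adjusted_difference(df, "y", adjusters=("balanced",))
        assert adj.estimate == pytest.approx(base.estimate, abs=1e-8)

    def test_single_arm_rejected(self):
        df = _two_arm_frame(n=40, seed=4)
        with pytest.raises(InferenceError):
            adjusted_difference(df[df["arm"] == 1.0], "y")

    def test_aliased_column_named(self):
        df = _two_arm_frame(n=40, seed=5)
        df["copy_of_arm"] = df["arm"]
        with pytest.raises(InferenceError, match="copy_of_arm"):
            adjusted_difference(df, "y", adjusters=("therapy", "copy_of_arm"))

    def test_missing_outcome_rejected(self):
        df = _two_arm_frame(n=40, seed=6)
        df.loc[0, "y"] = np.nan
        with pytest.raises(InferenceError):
            adjusted_difference(df, "y")


def _long_frame(n=120, delta=-2.0, seed=0, noise=4.0, u_sd=3.0):
    rng = np.random.default_rng(seed)
    arm = np.repeat([0.0, 1.0], n // 2)
    therapy = rng.integers(0, 2, size=n).astype(float)
    base = rng.normal(30, 6, size=n)
    u = rng.normal(0, u_sd, size=n)
    rows = []
    for t in (3, 6, 9, 12):
        y = base - 8 + delta * arm + 0.3 * therapy + u + rng.normal(0, noise, n)
        rows.append(pd.DataFrame({
            "id": np.arange(n), "month": t, "bdi": y, "bdi_baseline": base,
            "arm": arm, "therapy": therapy}))
    return pd.concat(rows, ignore_index=True)


class TestLongitudinalEffect:
    def test_identical_trajectories_give_zero(self):
        long = _long_frame(n=80, delta=0.0, seed=7, noise=0.0, u_sd=0.0)
        est = longitudinal_effect(long)
        assert est.estimate == pytest.approx(0.0, abs=1e-8)

    def test_recovers_constant_arm_difference(self):
        long = _long_frame(n=2000, delta=-2.0, seed=8)
        est = longitudinal_effect(long)
        assert est.estimate == pytest.approx(-2.0, abs=4 * est.se)

    def test_more_noise_widens_interval(self):
        quiet = longitudinal_effect(_long_frame(n=200, seed=9, noise=2.0))
        loud = longitudinal_effect(_long_frame(n=200, seed=9, noise=8.0))
        assert (loud.ci_high - loud.ci_low) > (quiet.ci_high - quiet.ci_low)

    def test_single_timepoint_rejected(self):
        long = _long_frame(n=40, seed=10)
        with pytest.raises(InferenceError):
            longitudinal_effect(long[long["month"] == 3])


class TestBcaBootstrap:
    def test_degenerate_sample_collapses_to_point(self):
        theta, ci, _ = bca_bootstrap(np.full(20, 4.2), np.mean,
                                     b_replications=200, seed=0)
        assert theta == pytest.approx(4.2)
        assert ci == (pytest.approx(4.2), pytest.approx(4.2))

    def test_matches_percentile_on_symmetric_data(self):
        """With symmetric data z0 ~ 0 and a ~ 0, so BCa ~ plain percentile."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        theta, ci, reps = bca_bootstrap(x, np.mean, b_replications=2000, seed=12)
        lo, hi = np.quantile(reps, [0.025, 0.975])
        sd = x.std()
        assert abs(ci[0] - lo) < 0.05 * sd
        assert abs(ci[1] - hi) < 0.05 * sd

    def test_matches_exhaustive_enumeration_at_tiny_n(self):
        """Oracle: the exact bootstrap distribution over all n^n resamples."""
        x = np.array([1.0, 3.0, 4.0, 7.0, 11.0])
        n = len(x)
        exact = np.array([np.mean(x[list(c)])
                          for c in itertools.product(range(n), repeat=n)])
        theta = x.mean()
        prop = np.mean(exact < theta) + 0.5 * np.mean(exact == theta)
        z0 = stats.norm.ppf(prop)
        jack = np.array([np.mean(np.delete(x, i)) for i in range(n)])
        d = jack.mean() - jack
        a = (d ** 3).sum() / (6 * ((d ** 2).sum()) ** 1.5)
        zlo, zhi = stats.norm.ppf([0.025, 0.975])
        a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
        a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
        lo_exact, hi_exact = np.quantile(exact, [a1, a2])

        _, ci, _ = bca_bootstrap(x, np.mean, b_replications=20000, seed=13)
        assert ci[0] == pytest.approx(lo_exact, abs=0.25)
        assert ci[1] == pytest.approx(hi_exact, abs=0.25)

    def test_acceleration_switch_changes_skewed_interval(self):
        rng = np.random.default_rng(14)
        x = rng.lognormal(size=200)
        _, bca_ci, _ = bca_bootstrap(x, np.mean, 2000, seed=14, acceleration=True)
        _, bc_ci, _ = bca_bootstrap(x, np.mean, 2000, seed=14, acceleration=False)
        assert bca_ci != bc_ci

    def test_percentile_ci_approaches_normal_theory(self):
        rng = np.random.default_rng(15)
        x = rng.normal(loc=2.0, size=1000)
        _, _, reps = bca_bootstrap(x, np.mean, 2000, seed=15, acceleration=False)
        lo, hi = np.quantile(reps, [0.025, 0.975])
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert lo == pytest.approx(x.mean() - 1.96 * se, abs=0.25 * se * 1.96)
        assert hi == pytest.approx(x.mean() + 1.96 * se, abs=0.25 * se * 1.96)

    def test_too_few_replications_rejected(self):
        with pytest.raises(InferenceError):
            bca_bootstrap(np.arange(10.0), np.mean, b_replications=10, seed=0)


def _cost_effect_frame(n=200, seed=0, rho=0.4):
    rng = np.random.default_rng(seed)
    arm = np.repeat([0.0, 1.0], n // 2)
    therapy = rng.integers(0, 2, n).astype(float)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    ce = rng.multivariate_normal([0, 0], cov, size=n)
    cost = 5000 + 1500 * arm + 2000 * ce[:, 0]
    effect = 0.6 + 0.03 * arm + 0.1 * ce[:, 1]
    return pd.DataFrame({"arm": arm, "therapy": therapy,
                         "annual_cost": cost, "qaly": effect})


class TestMiBootstrap:
    def test_cloud_size_is_m_times_b(self):
        frames = [_cost_effect_frame(seed=s) for s in range(3)]
        cloud, _ = mi_bootstrap(frames, "annual_cost", "qaly",
                                b_per_dataset=150, seed=1, acceleration=False)
        assert cloud.n_pairs == 3 * 150
        assert set(cloud.imputation) == {0, 1, 2}

    def test_single_imputation_reduces_to_plain_bootstrap_point(self):
        df = _cost_effect_frame(seed=2)
        cloud, pooled = mi_bootstrap([df], "annual_cost", "qaly",
                                     b_per_dataset=300, seed=2)
        est = adjusted_difference(df, "annual_cost")
        assert pooled["delta_cost"].estimate == pytest.approx(est.estimate)
        assert pooled["delta_cost"].between == 0.0

    def test_joint_resampling_preserves_correlation(self):
        df = _cost_effect_frame(n=400, seed=3, rho=0.6)
        cloud, _ = mi_bootstrap([df], "annual_cost", "qaly",
                                b_per_dataset=1500, seed=3, acceleration=False)
        r_cloud = np.corrcoef(cloud.delta_cost, cloud.delta_effect)[0, 1]
        # the participant-level cost-effect correlation within arm
        resid_c = df["annual_cost"] - df.groupby("arm")["annual_cost"].transform("mean")
        resid_e = df["qaly"] - df.groupby("arm")["qaly"].transform("mean")
        r_data = np.corrcoef(resid_c, resid_e)[0, 1]
        assert r_cloud == pytest.approx(r_data, abs=0.12)

    def test_pooled_interval_contains_pooled_point(self):
        frames = [_cost_effect_frame(seed=s) for s in range(3)]
        _, pooled = mi_bootstrap(frames, "annual_cost", "qaly",
                                 b_per_dataset=200, seed=4)
        for key in ("delta_cost", "delta_effect"):
            p = pooled[key]
            assert p.ci_low <= p.estimate <= p.ci_high

    def test_stratified_resampling_preserves_arm_sizes(self):
        arm = np.repeat([0, 1], [60, 40]).astype(float)
        rng = np.random.default_rng(5)
        idx = stratified_indices(arm, rng)
        assert (arm[idx] == 0).sum() == 60
        assert (arm[idx] == 1).sum() == 40

    def test_null_generator_cloud_centred_at_origin(self):
        df = _cost_effect_frame(n=600, seed=6)
        df["annual_cost"] -= 1500 * df["arm"]
        df["qaly"] -= 0.03 * df["arm"]
        cloud, _ = mi_bootstrap([df], "annual_cost", "qaly",
                                b_per_dataset=800, seed=6, acceleration=False)
        se_c = cloud.delta_cost.std()
        se_e = cloud.delta_effect.std()
        assert abs(cloud.delta_cost.mean()) < 4 * se_c / np.sqrt(1)
        assert abs(cloud.delta_effect.mean()) < 4 * se_e
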