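import numpy as np
import pandas as pd
import pytest

from trialcea.imputation import (ImputationError, ImputationSpec, adapt_m,
                                 mice_pmm, pool_analyses, rubin_pool)


def _mar_frame(n=200, miss_frac=0.3, seed=0, mechanism="mar"):
    """One outcome y with predictors; missingness MAR via x1 or MCAR."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 2.0 + 1.5 * x1 - 0.8 * x2 + rng.normal(scale=1.0, size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
    if mechanism == "mar":
        from scipy.special import expit
        p_miss = expit(np.quantile(x1, 1 - miss_frac) * 0 + 1.2 * (x1 - x1.mean()))
        p_miss = miss_frac * p_miss / p_miss.mean()
        mask = rng.random(n) < np.clip(p_miss, 0, 1)
    else:
        mask = rng.random(n) < miss_frac
    masked = df.copy()
    masked.loc[mask, "y"] = np.nan
    return df, masked


class TestRubinPool:
    def test_hand_worked_example(self):
        # estimates (1,2,3), variances (1,1,1): Qbar=2, W=1, B=1, T=1+4/3
        p = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert p.estimate == pytest.approx(2.0)
        assert p.within == pytest.approx(1.0)
        assert p.between == pytest.approx(1.0)
        assert p.total == pytest.approx(7.0 / 3.0)
        assert p.m == 3

    def test_identical_estimates_have_no_between_variance(self):
        p = rubin_pool([1.3] * 4, [0.5] * 4)
        assert p.between == 0.0
        assert p.total == pytest.approx(p.within)
        assert p.fmi == 0.0

    def test_single_imputation_passes_through(self):
        p = rubin_pool([2.5], [0.49])
        assert p.estimate == 2.5
        assert p.total == pytest.approx(0.49)
        assert p.fmi == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ImputationError):
            rubin_pool([1.0, 2.0], [1.0])

    def test_ci_width_nondecreasing_in_between_variance(self):
        # same W and m, increasingly spread estimates
        widths = []
        for spread in (0.0, 0.5, 1.0, 2.0):
            p = rubin_pool([2 - spread, 2.0, 2 + spread], [1.0, 1.0, 1.0])
            widths.append(p.ci_high - p.ci_low)
        assert all(b >= a - 1e-12 for a, b in zip(widths, widths[1:]))

    def test_invariants(self):
        p = rubin_pool([1.0, 1.4, 0.7, 2.2], [0.2, 0.3, 0.25, 0.22])
        assert p.total >= p.within
        assert p.between >= 0
        assert 0 <= p.fmi < 1
        assert p.ci_low <= p.estimate <= p.ci_high


class TestMicePmm:
    def test_complete_data_returns_identical_copies(self):
        df, _ = _mar_frame(n=60, seed=1)
        spec = ImputationSpec(variables=("y",), m_initial=3, seed=1)
        out = mice_pmm(df, spec, m=3)
        assert out.m == 3
        for completed in out.datasets:
            pd.testing.assert_frame_equal(completed, df)

    def test_donor_property_every_imputed_cell(self):
        df, masked = _mar_frame(n=150, seed=2)
        spec = ImputationSpec(variables=("y",), m_initial=4, seed=2)
        out = mice_pmm(masked, spec, m=4)
        observed = set(masked["y"].dropna())
        miss_idx = masked.index[masked["y"].isna()]
        for completed in out.datasets:
            assert completed["y"].notna().all()
            assert set(completed.loc[miss_idx, "y"]).issubset(observed)

    def test_observed_cells_never_modified(self):
        df, masked = _mar_frame(n=150, seed=3)
        spec = ImputationSpec(variables=("y",), m_initial=3, seed=3)
        out = mice_pmm(masked, spec, m=3)
        obs_idx = masked.index[masked["y"].notna()]
        for completed in out.datasets:
            assert np.allclose(completed.loc[obs_idx, "y"], masked.loc[obs_idx, "y"])
            assert np.allclose(completed["x1"], masked["x1"])

    def test_same_seed_reproduces_imputations(self):
        _, masked = _mar_frame(n=100, seed=4)
        spec = ImputationSpec(variables=("y",), m_initial=3, seed=4)
        a = mice_pmm(masked, spec, m=3)
        b = mice_pmm(masked, spec, m=3)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_extending_m_preserves_earlier_imputations(self):
        _, masked = _mar_frame(n=100, seed=5)
        spec = ImputationSpec(variables=("y",), m_initial=2, seed=5)
        first = mice_pmm(masked, spec, m=2)
        more = mice_pmm(masked, spec, m=4)
        for da, db in zip(first.datasets, more.datasets[:2]):
            pd.testing.assert_frame_equal(da, db)

    def test_mar_recovery_of_complete_mean(self):
        """Pooled mean of the imputed variable tracks the pre-masking truth."""
        biases = []
        for s in range(15):
            full, masked = _mar_frame(n=200, seed=100 + s)
            spec = ImputationSpec(variables=("y",), m_initial=5, seed=100 + s)
            out = mice_pmm(masked, spec, m=5)
            pooled_mean = np.mean([c["y"].mean() for c in out.datasets])
            biases.append(pooled_mean - full["y"].mean())
        mc_se = np.std(biases) / np.sqrt(len(biases))
        assert abs(np.mean(biases)) < 4 * mc_se + 0.01

    def test_all_missing_variable_rejected(self):
        _, masked = _mar_frame(n=50, seed=6)
        masked["y"] = np.nan
        spec = ImputationSpec(variables=("y",), seed=6)
        with pytest.raises(ImputationError):
            mice_pmm(masked, spec, m=2)

    def test_stratified_chains_keep_strata_separate(self):
        _, masked = _mar_frame(n=120, seed=7)
        masked["arm"] = np.repeat([0.0, 1.0], 60)
        masked["y"] = masked["y"] + 5 * masked["arm"]
        spec = ImputationSpec(variables=("y",), stratify_by="arm", seed=7)
        out = mice_pmm(masked, spec, m=2)
        for completed in out.datasets:
            # donors come from the participant's own arm
            arm0_vals = set(masked.loc[(masked["arm"] == 0) & masked["y"].notna(), "y"])
            imputed0 = completed.loc[(masked["arm"] == 0) & masked["y"].isna(), "y"]
            assert set(imputed0).issubset(arm0_vals)


class TestAdaptM:
    @staticmethod
    def _mean_analysis(completed):
        y = completed["y"]
        return {"mean_y": (float(y.mean()), float(y.var(ddof=1) / len(y)))}

    def test_complete_data_stops_at_m_initial_with_zero_fmi(self):
        df, _ = _mar_frame(n=80, seed=8)
        spec = ImputationSpec(variables=("y",), m_initial=2, m_max=16, seed=8)
        out = adapt_m(df, spec, self._mean_analysis)
        assert out.m == 2
        assert max(out.fmi.values()) == 0.0

    def test_vacuous_threshold_stops_immediately(self):
        _, masked = _mar_frame(n=80, miss_frac=0.5, seed=9)
        spec = ImputationSpec(variables=("y",), m_initial=2, m_max=32,
                              fmi_threshold=1.0, seed=9)
        out = adapt_m(masked, spec, self._mean_analysis)
        assert out.m == 2

    def test_heavier_missingness_needs_more_imputations(self):
        # averaged over seeds: FMI estimates at small m are noisy
        finals = {0.02: [], 0.6: []}
        for frac in finals:
            for seed in (10, 11, 12):
                _, masked = _mar_frame(n=300, miss_frac=frac, seed=seed,
                                       mechanism="mcar")
                spec = ImputationSpec(variables=("y",), m_initial=4, m_max=64,
                                      fmi_threshold=0.15, seed=seed)
                out = adapt_m(masked, spec, self._mean_analysis)
                finals[frac].append(out.m)
        assert np.mean(finals[0.6]) > np.mean(finals[0.02])

    def test_m_max_reached_warns_not_fails(self):
        _, masked = _mar_frame(n=100, miss_frac=0.5, seed=11)
        spec = ImputationSpec(variables=("y",), m_initial=2, m_max=4,
                              fmi_threshold=0.001, seed=11)
        with pytest.warns(UserWarning, match="FMI"):
            out = adapt_m(masked, spec, self._mean_analysis)
        assert out.m == 4
        assert not out.converged


class TestMcarEquivalence:
    def test_mi_agrees_with_complete_case_under_mcar(self):
        """Under MCAR both estimators are unbiased; MI variance >= full-data."""
        mi_est, cc_est, full_var, mi_var = [], [], [], []
        for s in range(12):
            full, masked = _mar_frame(n=200, miss_frac=0.2, seed=300 + s,
                                      mechanism="mcar")
            spec = ImputationSpec(variables=("y",), m_initial=5, seed=300 + s)
            out = mice_pmm(masked, spec, m=5)
            pooled = pool_analyses(out, self_analysis)
            mi_est.append(pooled["mean_y"].estimate)
            mi_var.append(pooled["mean_y"].total)
            cc_est.append(masked["y"].dropna().mean())
            full_var.append(full["y"].var(ddof=1) / len(full))
        gap = np.asarray(mi_est) - np.asarray(cc_est)
        assert abs(gap.mean()) < 4 * gap.std() / np.sqrt(len(gap)) + 0.01
        assert np.mean(mi_var) >= np.mean(full_var)


def self_analysis(completed):
    y = completed["y"]
    return {"mean_y": (float(y.mean()), float(y.var(ddof=1) / len(y)))}
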