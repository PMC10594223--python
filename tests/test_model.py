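import json

import numpy as np
import pandas as pd
import pytest

import trialcea as tc


@pytest.fixture(scope="module")
def fast_analysis_config():
    return tc.AnalysisConfig(b_replications=120, m_initial=3, m_max=3, seed=13)


@pytest.fixture(scope="module")
def fitted(small_masked, fast_analysis_config):
    model = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config)
    return model.fit()


class TestFit:
    def test_every_configured_outcome_reported_once(self, fitted):
        assert set(fitted.ce_results) == {"bdi", "qaly", "pfs", "sfs"}
        assert set(fitted.effects) == {"bdi", "qaly", "pfs", "sfs", "cost"}

    def test_intention_to_treat_counts(self, fitted, small_masked):
        # every completed dataset carries all randomised participants
        n = small_masked.n_participants
        for completed in fitted.imputed.datasets:
            assert len(completed) == n
            assert completed.notna().all().all()

    def test_cloud_bookkeeping(self, fitted, fast_analysis_config):
        for cloud in fitted.clouds.values():
            assert cloud.n_pairs == fitted.imputed.m * fast_analysis_config.b_replications

    def test_quadrants_and_ceac_are_coherent(self, fitted):
        for ce in fitted.ce_results.values():
            assert sum(ce.quadrants.values()) == pytest.approx(1.0)
            p = np.asarray(ce.ceac.probabilities)
            assert ((p >= 0) & (p <= 1)).all()
            # the cloud curve's extremes agree with the quadrant masses
            q = ce.quadrants
            assert ce.ceac_cloud.probabilities[0] == pytest.approx(q["SE"] + q["SW"])

    def test_icer_consistent_with_pooled_differences(self, fitted):
        ce = fitted.ce_results["qaly"]
        assert ce.icer.value == pytest.approx(
            fitted.effects["cost"].estimate / fitted.effects["qaly"].estimate)

    def test_determinism_end_to_end(self, small_masked, fast_analysis_config):
        a = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config).fit()
        b = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config).fit()
        assert json.dumps(a.report_dict(), default=float, sort_keys=True) == \
               json.dumps(b.report_dict(), default=float, sort_keys=True)

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "QALY" in text and "ICER" in text and "BDI-II" in text

    def test_save_writes_report_files(self, fitted, tmp_path):
        fitted.save(tmp_path, plots=False)
        report = json.loads((tmp_path / "report.json").read_text())
        assert set(report["cea"]) == {"bdi", "qaly", "pfs", "sfs"}
        assert (tmp_path / "effects.csv").exists()
        assert (tmp_path / "ceac_qaly.csv").exists()

    def test_saved_report_is_reproducible(self, fitted, tmp_path):
        fitted.save(tmp_path / "a", plots=False)
        fitted.save(tmp_path / "b", plots=False)
        assert (tmp_path / "a/report.json").read_text() == \
               (tmp_path / "b/report.json").read_text()


class TestSensitivityAnalyses:
    def test_vacuous_outlier_threshold_matches_main(self, small_masked,
                                                    fast_analysis_config):
        main = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config)
        cfg = tc.AnalysisConfig(**{**fast_analysis_config.to_dict(),
                                   "outlier_rule": True, "outlier_threshold": 1e12})
        variant = tc.CostEffectivenessModel(small_masked, config=cfg)
        wa = main.build_wide()
        wb = variant.build_wide()
        pd.testing.assert_frame_equal(wa, wb)

    def test_outlier_rule_recodes_expensive_periods(self, small_masked,
                                                    fast_analysis_config):
        cfg = tc.AnalysisConfig(**{**fast_analysis_config.to_dict(),
                                   "outlier_rule": True, "outlier_threshold": 4000.0})
        model = tc.CostEffectivenessModel(small_masked, config=cfg)
        plain = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config)
        wide_rule = model.build_wide()
        wide_plain = plain.build_wide()
        assert wide_rule.isna().sum().sum() > wide_plain.isna().sum().sum()
        # recoded participants lose all their period costs
        tot = sum(wide_plain[f"cost_hc_{t:g}"].fillna(0)
                  + wide_plain[f"cost_oth_{t:g}"].fillna(0) for t in (3, 6, 9, 12))
        flagged = wide_plain.index[
            pd.concat([(wide_plain[f"cost_hc_{t:g}"] + wide_plain[f"cost_oth_{t:g}"])
                       >= 4000.0 for t in (3, 6, 9, 12)], axis=1).any(axis=1)]
        assert len(flagged) > 0
        assert wide_rule.loc[flagged, [c for c in wide_rule if c.startswith("cost_")]] \
            .isna().all().all()

    def test_healthcare_perspective_totals_are_smaller(self, small_masked,
                                                       fast_analysis_config):
        model = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config)
        wide = model.build_wide()
        completed = wide.fillna(wide.mean(numeric_only=True))
        soc = model._annual_cost(completed, "societal")
        hc = model._annual_cost(completed, "healthcare")
        assert (hc <= soc + 1e-9).all()

    def test_human_capital_raises_cost_difference_with_one_armed_long_absence(
            self, unit_costs, wages):
        """Removing the friction cap must raise costs where the long episodes sit."""
        from tests_support_absence import build_absence_concentrated_trial

        data = build_absence_concentrated_trial()
        fr = tc.aggregate_costs(data, unit_costs, wages, approach="friction")
        hc = tc.aggregate_costs(data, unit_costs, wages, approach="human_capital")
        base = data.baseline.set_index("id")

        def arm_diff(bd):
            ann = bd.annual["societal_total"]
            arm = base["frequency_arm"]
            return ann[arm == "twice"].mean() - ann[arm == "once"].mean()

        assert arm_diff(hc) > arm_diff(fr)

    def test_baseline_adjustment_with_balanced_baseline_is_negligible(
            self, small_masked, fast_analysis_config):
        model = tc.CostEffectivenessModel(small_masked, config=fast_analysis_config)
        wide = model.build_wide()
        completed = wide.fillna(wide.mean(numeric_only=True))
        frame = model._analysis_frame(completed)
        from trialcea.inference import adjusted_difference
        plain = adjusted_difference(frame, "annual_cost", ("therapy",))
        adj = adjusted_difference(frame, "annual_cost", ("therapy", "baseline_cost"))
        # baseline costs are generated independently of the arm
        assert adj.estimate == pytest.approx(plain.estimate, abs=2.5 * plain.se)

    def test_variant_config_changes_exactly_one_stage(self, fast_analysis_config):
        base = fast_analysis_config.to_dict()
        for which, key, value in [
                ("healthcare", "perspective", "healthcare"),
                ("human_capital", "approach", "human_capital"),
                ("outliers", "outlier_rule", True),
                ("baseline_adjust", "baseline_cost_adjust", True)]:
            variant = fast_analysis_config.variant(which).to_dict()
            assert variant[key] == value
            changed = {k for k in base if variant[k] != base[k]}
            assert changed == {key}

    def test_unknown_variant_rejected(self, fast_analysis_config):
        with pytest.raises(tc.ConfigurationError):
            fast_analysis_config.variant("bonferroni")


class TestPipeline:
    def test_run_main_from_synthetic_config(self, tmp_path):
        tcfg = tc.TrialConfig(cell_sizes=(10, 10, 10, 10), n_sites=2, seed=41)
        acfg = tc.AnalysisConfig(b_replications=120, m_initial=2, m_max=2, seed=41)
        res = tc.run_main(trial_config=tcfg, analysis_config=acfg,
                          outdir=tmp_path / "run")
        assert (tmp_path / "run" / "report.json").exists()
        assert res.metadata["n_participants"] == 40

    def test_run_sensitivity_switches_stage(self):
        tcfg = tc.TrialConfig(cell_sizes=(10, 10, 10, 10), n_sites=2, seed=42)
        acfg = tc.AnalysisConfig(b_replications=120, m_initial=2, m_max=2, seed=42)
        res = tc.run_sensitivity("healthcare", trial_config=tcfg, analysis_config=acfg)
        assert res.metadata["perspective"] == "healthcare"

    def test_requires_exactly_one_data_source(self):
        with pytest.raises(ValueError):
            tc.pipeline.build_model()
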