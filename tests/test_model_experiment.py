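"""Trial extraction and the mixed-effects type x friction analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import strikelab as sl
from strikelab import model_experiment as me
from strikelab.errors import ModelFitError, ValidationError
from strikelab.synthetic_data import (
    DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS, full_factorial_design,
    generate_model_study,
)


def _noise_free_study(sample_sd=0.0, seed=0):
    return generate_model_study(full_factorial_design(
        DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS,
        n_samples_per_type=2, n_repeats=3,
        sample_log_force_sd=sample_sd, sample_speed_sd=sample_sd,
        log_force_sd=0.0, speed_sd=0.0, seed=seed))


class TestTrialExtraction:
    def test_max_force_constructed_ramp(self):
        trial = sl.ModelTrial(
            atr_type="atrH", friction="H", sample_id="atrH1", repeat=0,
            force_t=np.arange(6) / 10.0,
            force_f=np.array([0.0, 10.0, 22.38, 0.5, 0.1, 0.0]),
            coords=np.zeros((5, 2)), fps=1000.0, scale=0.2, video_t0=0.0)
        assert me.trial_max_force(trial) == 22.38

    def test_flat_trace_warns_and_returns_zero(self):
        trial = sl.ModelTrial(
            atr_type="atrH", friction="H", sample_id="atrH1", repeat=0,
            force_t=np.arange(5) / 10.0, force_f=np.zeros(5),
            coords=np.zeros((5, 2)), fps=1000.0, scale=0.2, video_t0=0.0)
        with pytest.warns(UserWarning, match="no release"):
            assert me.trial_max_force(trial) == 0.0

    def test_noise_free_generator_force_exact(self):
        scn = sl.ModelTrialScenario(true_release_force=18.63,
                                    log_force_sd=0.0, speed_sd=0.0)
        trial, = generate_model_study([scn])
        assert me.trial_max_force(trial) == pytest.approx(18.63, abs=1e-12)

    def test_constructed_velocity_arithmetic(self):
        """0.205 mm per frame at 1000 fps is 0.205 m/s with scale 1 mm/px."""
        n = 30
        coords = np.zeros((n, 2))
        coords[10:, 0] = 0.205 * np.arange(1, n - 9)  # px; scale 1 mm/px
        force_t = np.arange(20) / 100.0
        force_f = np.concatenate([np.linspace(0, 5, 10), np.zeros(10)])
        trial = sl.ModelTrial(
            atr_type="atrS", friction="H", sample_id="atrS1", repeat=0,
            force_t=force_t, force_f=force_f, coords=coords, fps=1000.0,
            scale=1.0, video_t0=force_t[10] - 10 / 1000.0)
        assert me.trial_max_velocity(trial) == pytest.approx(0.205, rel=1e-9)

    def test_noise_free_generator_velocity(self):
        scn = sl.ModelTrialScenario(post_release_peak_speed=0.205,
                                    log_force_sd=0.0, speed_sd=0.0)
        trial, = generate_model_study([scn])
        assert me.trial_max_velocity(trial) == pytest.approx(0.205, rel=1e-6)

    def test_tracking_gap_rejected(self):
        scn = sl.ModelTrialScenario(log_force_sd=0.0, speed_sd=0.0)
        trial, = generate_model_study([scn])
        trial.coords[25, 0] = np.nan
        with pytest.raises(ModelFitError, match="gap"):
            me.trial_max_velocity(trial)


class TestMixedModels:
    def test_qualitative_study_structure(self):
        """On the stated-world generator the fits reproduce the study's
        qualitative findings: friction drives force (no interaction on the
        log scale); velocity shows a type-specific friction response."""
        design = full_factorial_design(DEFAULT_FORCE_MEANS,
                                       DEFAULT_SPEED_MEANS, seed=11)
        df = me.summarize_trials(generate_model_study(design))
        force_res, vel_res = me.fit_trial_models(df)
        f_anova = force_res.anova.set_index("term")
        assert f_anova.loc["friction", "significant"]
        v_anova = vel_res.anova.set_index("term")
        assert v_anova.loc["type:friction", "significant"]
        contr = vel_res.contrasts.set_index("atr_type")
        assert contr.loc["atrS", "significant"]
        assert not contr.loc["atrH", "significant"]

    def test_zero_random_variance_matches_ols(self):
        """With no sample-level variance the mixed model's fixed effects
        equal an ordinary two-way sum-coded fit to <=1e-6."""
        df = me.summarize_trials(_noise_free_study(sample_sd=0.0))
        # add tiny residual noise so the fit is non-degenerate
        rng = np.random.default_rng(5)
        df["max_velocity"] = df["max_velocity"] + rng.normal(0, 1e-3, len(df))
        _, vel_res = me.fit_trial_models(df)
        data = df.copy()
        data["_t"] = np.where(data["atr_type"] == "atrH", 1.0, -1.0)
        data["_f"] = np.where(data["friction"] == "H", 1.0, -1.0)
        data["_tf"] = data["_t"] * data["_f"]
        ols = smf.ols("max_velocity ~ _t + _f + _tf", data).fit()
        got = vel_res.params["estimate"].to_numpy()
        np.testing.assert_allclose(got, ols.params.to_numpy(), atol=1e-6)

    def test_velocity_shift_moves_only_intercept(self):
        df = me.summarize_trials(generate_model_study(full_factorial_design(
            DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS, seed=2)))
        _, base = me.fit_trial_models(df)
        shifted = df.copy()
        shifted["max_velocity"] = shifted["max_velocity"] + 3.0
        _, moved = me.fit_trial_models(shifted)
        b0 = base.params.set_index("term")["estimate"]
        m0 = moved.params.set_index("term")["estimate"]
        assert m0["(Intercept)"] == pytest.approx(b0["(Intercept)"] + 3.0,
                                                  abs=1e-6)
        for term in ("type", "friction", "type:friction"):
            assert m0[term] == pytest.approx(b0[term], abs=1e-6)
        np.testing.assert_allclose(moved.contrasts["estimate"],
                                   base.contrasts["estimate"], atol=1e-6)

    def test_row_order_invariance(self):
        df = me.summarize_trials(generate_model_study(full_factorial_design(
            DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS, seed=4)))
        a, _ = me.fit_trial_models(df)
        b, _ = me.fit_trial_models(df.iloc[::-1].reset_index(drop=True))
        np.testing.assert_allclose(a.anova["chi2"], b.anova["chi2"],
                                   rtol=1e-6)

    def test_constant_response_gives_null_effects(self):
        df = me.summarize_trials(_noise_free_study())
        df["max_velocity"] = 0.1
        df["max_force"] = 2.0
        force_res, vel_res = me.fit_trial_models(df)
        np.testing.assert_allclose(
            vel_res.params["estimate"].to_numpy()[1:], 0.0, atol=1e-12)
        assert not vel_res.anova["significant"].any()
        assert not vel_res.contrasts["significant"].any()

    def test_missing_cell_names_cell(self):
        df = me.summarize_trials(_noise_free_study())
        df = df[~((df.atr_type == "atrS") & (df.friction == "L"))]
        with pytest.raises(ModelFitError, match=r"\(atrS, L\)"):
            me.fit_trial_models(df)

    def test_single_sample_per_type_rejected(self):
        df = me.summarize_trials(_noise_free_study())
        df = df[df.sample_id.isin(["atrH1", "atrS1"])]
        with pytest.raises(ModelFitError, match="samples per type"):
            me.fit_trial_models(df)

    def test_log_transform_bookkeeping_lossless(self):
        """With constant forces per cell, exponentiating the log-scale EMMs
        returns the cell forces exactly."""
        df = me.summarize_trials(_noise_free_study())
        rng = np.random.default_rng(9)
        df["max_velocity"] = df["max_velocity"] + rng.normal(0, 1e-3, len(df))
        force_res, _ = me.fit_trial_models(df)
        for _, row in force_res.emm.iterrows():
            cell = DEFAULT_FORCE_MEANS[(row.atr_type, row.friction)]
            assert np.exp(row.emm) == pytest.approx(cell, rel=1e-6)


class TestReport:
    def test_tables_round_trip_csv(self, tmp_path):
        df = me.summarize_trials(generate_model_study(full_factorial_design(
            DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS, seed=6)))
        results = me.fit_trial_models(df)
        report = me.model_report(results, out_dir=tmp_path)
        for name, tbl in report["tables"].items():
            back = pd.read_csv(tmp_path / f"{name}.csv")
            assert list(back.columns) == list(tbl.columns)
            num = tbl.select_dtypes("number")
            np.testing.assert_allclose(back[num.columns].to_numpy(float),
                                       num.to_numpy(float), rtol=1e-9)

    def test_p_value_formatting_fixed(self, tmp_path):
        df = me.summarize_trials(generate_model_study(full_factorial_design(
            DEFAULT_FORCE_MEANS, DEFAULT_SPEED_MEANS, seed=6)))
        report = me.model_report(me.fit_trial_models(df), out_dir=tmp_path)
        text = (tmp_path / "model_report.txt").read_text()
        assert "<0.001" in text
        for chunk in text.split("p = ")[1:]:
            pfield = chunk.split(",")[0].split()[0]
            assert "e" not in pfield.lower(), pfield

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            me.model_report([])
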