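import numpy as np
import pandas as pd
import pytest

from hgmod.cohort import generate_patient_schedules
from hgmod.epoching import percent_change
from hgmod.windows import (WindowDef, default_windows, detectable_effect_size,
                           extract_window_values, fit_window_lmm,
                           studentized_bootstrap_contrast)
from tests.test_epoching import flat_band


@pytest.fixture
def schedules():
    rng = np.random.default_rng(0)
    return generate_patient_schedules("P01", rng, n_per_type=3)


class TestWindowDefs:
    def test_default_set_has_eleven_100ms_windows(self):
        wins = default_windows()
        assert len(wins) == 11
        assert all(w.end_ms - w.start_ms == 100.0 for w in wins)
        labels = {w.label for w in wins}
        assert "1a" not in labels and {"1b", "2b", "2d", "3d"} <= labels

    def test_non_100ms_window_rejected(self):
        with pytest.raises(ValueError, match="100 ms"):
            WindowDef("x", "p1_onset", 0.0, 150.0)


class TestExtractWindowValues:
    def test_constant_trace(self, schedules):
        tr = percent_change(flat_band(schedules), schedules)
        tr.continuous[:] = 7.0
        w = WindowDef("2b", "p2_onset", 0.0, 100.0)
        np.testing.assert_allclose(extract_window_values(tr, w), 7.0)

    def test_linear_ramp_mean(self, schedules):
        """A 0-100 ms ramp from 0 to 10% averages to ~5% less half a bin
        (bin-center quadrature over ten half-open bins)."""
        tr = percent_change(flat_band(schedules), schedules)
        step = 10
        for s in schedules:
            b0 = int(round(s.event_times["p1_onset"] / step))
            tr.continuous[:, b0:b0 + 11] = np.arange(11.0)
        w = WindowDef("1b", "p1_onset", 0.0, 100.0)
        vals = extract_window_values(tr, w)
        np.testing.assert_allclose(vals, np.mean(np.arange(10.0)))

    def test_matches_bruteforce(self, mini_recording):
        sch = mini_recording["schedules"]
        tr = percent_change(mini_recording["band"], sch)
        w = WindowDef("2b", "p2_onset", 0.0, 100.0)
        vals = extract_window_values(tr, w, sentence_type="concrete_first")
        # brute force from continuous + event bins
        sel = tr.sentence_types == "concrete_first"
        expected = []
        for e in range(len(tr.channels)):
            per_trial = []
            for k in np.flatnonzero(sel):
                b0 = tr.event_bins.loc[k, "p2_onset"]
                per_trial.append(tr.continuous[e, b0:b0 + 10].mean())
            expected.append(np.mean(per_trial))
        np.testing.assert_allclose(vals, expected, rtol=1e-9)

    def test_linearity(self, schedules):
        tr = percent_change(flat_band(schedules), schedules)
        rng = np.random.default_rng(1)
        a = rng.random(tr.continuous.shape)
        b = rng.random(tr.continuous.shape)
        w = WindowDef("2b", "p2_onset", 0.0, 100.0)
        tr.continuous = a
        va = extract_window_values(tr, w)
        tr.continuous = b
        vb = extract_window_values(tr, w)
        tr.continuous = a + b
        np.testing.assert_allclose(extract_window_values(tr, w), va + vb)


class TestStudentizedBootstrap:
    def test_identical_groups(self):
        x = np.arange(10.0)
        r = studentized_bootstrap_contrast(x, x.copy(), 500, rng_seed=0)
        assert r["mean_diff"] == 0.0
        assert r["p"] > 0.5

    def test_large_shift_detected(self):
        """Delta = 2 pooled SDs with n = 20/20 is essentially always
        significant at 1%."""
        rng = np.random.default_rng(0)
        reject = 0
        for _ in range(50):
            a = rng.standard_normal(20) + 2.0
            b = rng.standard_normal(20)
            r = studentized_bootstrap_contrast(a, b, 1000, rng)
            reject += r["p"] < 0.01
        assert reject >= 49

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(15) + 1, rng.standard_normal(15)
        r = studentized_bootstrap_contrast(a, b, 1000, rng)
        assert r["ci"][0] <= r["mean_diff"] <= r["ci"][1]
        assert np.sign(r["t_stat"]) == np.sign(r["mean_diff"])

    def test_ci_coverage_nominal_on_gaussian_groups(self):
        """95% percentile-t CI covers a true group difference at close to
        nominal rate (n = 20 per group, 300 replicates)."""
        from hgmod.validate import bootstrap_ci_coverage
        cov = bootstrap_ci_coverage(300, 20, delta=1.0, rng_seed=0)
        assert 0.92 <= cov <= 0.98

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            studentized_bootstrap_contrast([1.0], [1.0, 2.0], 100)


class TestWindowLmm:
    @staticmethod
    def simulate(rng, n_patients=8, n_elec=6, effect=5.0, u_sd=3.0, e_sd=4.0):
        rows = []
        for p in range(n_patients):
            u = rng.normal(0, u_sd)
            for _ in range(n_elec):
                for st, sh in (("concrete_first", effect), ("wh_first", 0.0)):
                    rows.append({"value": u + sh + rng.normal(0, e_sd),
                                 "sentence_type": st,
                                 "patient_id": f"P{p:02d}"})
        return pd.DataFrame(rows)

    def test_effect_recovered(self):
        rng = np.random.default_rng(0)
        fit = fit_window_lmm(self.simulate(rng))
        c = fit.sentence_type_effect
        assert c["estimate"] == pytest.approx(5.0, abs=2.0)
        assert c["ci_low"] < 5.0 < c["ci_high"]
        assert c["p"] < 0.01

    def test_zero_between_patient_variance_matches_ols(self):
        """With no between-patient variance the sentence-type estimate
        equals the ordinary regression estimate."""
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        df = self.simulate(rng, u_sd=0.0)
        fit = fit_window_lmm(df)
        x = (df["sentence_type"] == "concrete_first").astype(float)
        ols = sm.OLS(df["value"], sm.add_constant(x)).fit()
        assert fit.sentence_type_effect["estimate"] == pytest.approx(
            ols.params.iloc[1], abs=0.05)

    def test_single_patient_rejected(self):
        rng = np.random.default_rng(2)
        df = self.simulate(rng, n_patients=1)
        with pytest.raises(ValueError, match="2 patients"):
            fit_window_lmm(df)

    def test_covariates_enter_fixed_effects(self):
        from hgmod.cohort import generate_cohort
        rng = np.random.default_rng(3)
        pats, _, _ = generate_cohort(12, {"left": {"others": 2}},
                                     trial_counts=3, rng_seed=4)
        df = self.simulate(rng, n_patients=12)
        df["patient_id"] = df["patient_id"].map(
            dict(zip(sorted(df["patient_id"].unique()),
                     [p.patient_id for p in pats])))
        fit = fit_window_lmm(df, pats)
        assert "age" in fit.coefficients.index
        assert "fiq" in fit.coefficients.index


class TestDetectableEffectSize:
    def test_monotone_in_n(self):
        assert detectable_effect_size(2) > detectable_effect_size(100)

    def test_against_simulation_oracle(self):
        """n = 15, alpha 0.05, power 0.8: the analytic value matches a
        brute-force simulation of one-sample t-test power."""
        from scipy import stats
        es = detectable_effect_size(15, 0.05, 0.8)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4000, 15)) + es
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(15))
        power = np.mean(np.abs(t) > stats.t.ppf(0.975, 14))
        assert power == pytest.approx(0.8, abs=0.03)

    def test_sqrt_n_scaling(self):
        big, double = detectable_effect_size(400), detectable_effect_size(800)
        assert big / double == pytest.approx(np.sqrt(2), rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detectable_effect_size(1)
        with pytest.raises(ValueError):
            detectable_effect_size(10, alpha=1.5)
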