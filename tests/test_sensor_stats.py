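"""Sensor-space statistics against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mmn_dcm.sensor_stats import (robust_average, gradiometer_rms_gfp,
                                  mmn_amplitude, welch_t, paired_t,
                                  rm_anova_gg, icc_absolute,
                                  min_detectable_effect, EvokedSet,
                                  MMN_WINDOW_MS)
from mmn_dcm.synthetic import SensorEpochs, CONDITION_LABELS


def _epochs(rng, n_per=6, n_sens=4, n_samp=51, labels=CONDITION_LABELS):
    data = rng.normal(size=(n_per * len(labels), n_sens, n_samp))
    labs = [l for l in labels for _ in range(n_per)]
    return SensorEpochs(data, labs)


def _evoked(means, sfreq=500.0, window=(-100.0, 500.0)):
    labels = CONDITION_LABELS[:means.shape[0]]
    return EvokedSet(means, {}, labels, sfreq, window)


class TestRobustAverage:
    def test_identical_epochs_weighted_fully(self, rng):
        base = rng.normal(size=(4, 31))
        data = np.repeat(base[None], 5, axis=0)
        ep = SensorEpochs(np.tile(data, (6, 1, 1)),
                          [l for l in CONDITION_LABELS for _ in range(5)])
        ev = robust_average(ep, lowpass_hz=None)
        assert np.allclose(ev.mean("deviant"), base)
        assert np.allclose(ev.weights["deviant"], 1.0)

    def test_outlier_downweighted_vs_arithmetic_mean(self, rng):
        clean = rng.normal(size=(20, 2, 31))
        truth = clean.mean(axis=0)
        data = clean.copy()
        data[0] += 50.0                      # gross outlier epoch
        ep = SensorEpochs(data, ["deviant"] * 20)
        ev = robust_average(ep, conditions=("deviant",), lowpass_hz=None)
        robust_err = np.linalg.norm(ev.mean("deviant") - truth)
        arith_err = np.linalg.norm(data.mean(axis=0) - truth)
        assert robust_err < arith_err

    def test_conditions_averaged_independently(self, rng):
        ep = _epochs(rng)
        ev1 = robust_average(ep, lowpass_hz=None)
        # permute deviant epochs only
        data = ep.data.copy()
        idx = [i for i, l in enumerate(ep.condition_label) if l == "deviant"]
        data[idx] = data[list(reversed(idx))]
        ev2 = robust_average(SensorEpochs(data, ep.condition_label),
                             lowpass_hz=None)
        assert np.allclose(ev1.mean("rep1"), ev2.mean("rep1"))

    def test_single_epoch_condition_rejected(self, rng):
        ep = SensorEpochs(rng.normal(size=(1, 2, 10)), ["deviant"])
        with pytest.raises(ValueError):
            robust_average(ep, conditions=("deviant",))


class TestGFP:
    def test_zero_data_zero_output(self):
        out = gradiometer_rms_gfp(np.zeros((4, 10)), [(0, 1), (2, 3)])
        assert np.allclose(out, 0.0)

    def test_constant_pair_hand_value(self):
        x = np.zeros((2, 5))
        x[0], x[1] = 3.0, -3.0
        out = gradiometer_rms_gfp(x, [(0, 1)])
        assert np.allclose(out, 3.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(4, 17))
        pairs = [(0, 1), (2, 3)]
        ref = np.mean([np.sqrt((x[a]**2 + x[b]**2) / 2) for a, b in pairs],
                      axis=0)
        assert np.allclose(gradiometer_rms_gfp(x, pairs), ref, atol=1e-12)

    def test_nonnegative(self, rng):
        x = rng.normal(size=(6, 9))
        out = gradiometer_rms_gfp(x, [(0, 1), (2, 3), (4, 5)])
        assert np.all(out >= 0)

    def test_unpaired_sensor_rejected(self, rng):
        with pytest.raises(ValueError):
            gradiometer_rms_gfp(rng.normal(size=(4, 5)), [(0, 1)])


class TestMMNAmplitude:
    def _flat_evoked(self, dev_val, rep_val, n_sens=4, sfreq=500.0):
        n = 301
        means = np.zeros((6, n_sens, n))
        means[0] = dev_val
        means[1] = rep_val
        return _evoked(means, sfreq)

    def test_identical_waveforms_give_zero(self, rng):
        m = rng.normal(size=(6, 4, 301))
        m[1] = m[0]
        assert mmn_amplitude(_evoked(m), [(0, 1), (2, 3)]) == 0.0

    def test_window_holds_11_samples_at_500hz(self):
        ev = self._flat_evoked(0.0, 1.0)
        t = ev.times_ms
        m = (t >= MMN_WINDOW_MS[0]) & (t <= MMN_WINDOW_MS[1])
        assert m.sum() == 11

    def test_constant_inputs_hand_value(self):
        ev = self._flat_evoked(2.0, 1.0)
        assert mmn_amplitude(ev, [(0, 1), (2, 3)]) == pytest.approx(-1.0)

    def test_antisymmetry_under_condition_swap(self, rng):
        m = rng.normal(size=(6, 4, 301)) ** 2  # positive, keeps GFP simple
        ev = _evoked(m)
        m2 = m.copy()
        m2[[0, 1]] = m2[[1, 0]]
        ev2 = _evoked(m2)
        pairs = [(0, 1), (2, 3)]
        assert mmn_amplitude(ev, pairs) == pytest.approx(
            -mmn_amplitude(ev2, pairs))

    def test_window_outside_epoch_rejected(self, rng):
        ev = _evoked(rng.normal(size=(6, 4, 20)), window=(-100, -62))
        with pytest.raises(ValueError):
            mmn_amplitude(ev, [(0, 1), (2, 3)])


class TestWelch:
    def test_equal_groups_centered(self):
        r = welch_t(1.0, 1.0, 10, 1.0, 1.0, 10)
        assert r.statistic == 0.0
        assert r.ci[0] < 0 < r.ci[1]

    def test_study_summary_statistics(self):
        r = welch_t(65.3, 7.29, 14, 73.8, 7.32, 45)
        assert r.statistic == pytest.approx(-3.80, abs=0.01)
        assert r.ci[0] == pytest.approx(-13.1, abs=0.05)
        assert r.ci[1] == pytest.approx(-3.86, abs=0.05)
        assert r.p <= 0.001

    @given(st.integers(0, 10**6))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_matches_scipy_from_stats(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.5, 2.0, 2)
        n1, n2 = rng.integers(3, 30, 2)
        r = welch_t(m1, s1, n1, m2, s2, n2)
        ref = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                         equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestPairedT:
    def test_zero_differences(self):
        r = paired_t([0.0, 0.0, 0.0], tail="less")
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.5)

    def test_hand_computed_example(self):
        r = paired_t([1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)

    def test_zero_variance_nonzero_mean_flagged(self):
        r = paired_t([1.0, 1.0, 1.0])
        assert r.p == 0.0
        assert r.extra["zero_variance"]

    @given(st.integers(0, 10**6))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=rng.integers(3, 25))
        r = paired_t(d)
        ref = stats.ttest_1samp(d, 0.0)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestRMAnova:
    def test_two_conditions_equal_squared_paired_t(self, rng):
        y = rng.normal(size=(14, 2))
        F = rm_anova_gg(y)["condition"].statistic
        t = paired_t(y[:, 0] - y[:, 1]).statistic
        assert F == pytest.approx(t**2, abs=1e-8)

    def test_spherical_data_epsilon_near_one(self, rng):
        y = rng.normal(size=(2000, 4))
        eps = rm_anova_gg(y)["condition"].extra["epsilon"]
        assert eps > 0.99

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        y = rng.normal(size=(12, 5))
        mine = rm_anova_gg(y)["condition"]
        df = pd.DataFrame({
            "y": y.ravel(),
            "s": np.repeat(np.arange(12), 5),
            "c": np.tile(np.arange(5), 12),
        })
        ref = pg.rm_anova(data=df, dv="y", within="c", subject="s",
                          correction=True)
        assert mine.statistic == pytest.approx(float(ref["F"].iloc[0]),
                                               rel=1e-6)
        assert mine.extra["epsilon"] == pytest.approx(
            float(ref["eps"].iloc[0]), rel=1e-6)

    def test_mixed_design_interaction_detects_group_modulation(self, rng):
        n, k = 40, 4
        g = np.array(["a"] * 20 + ["b"] * 20)
        y = rng.normal(size=(n, k))
        slope = np.linspace(-1.0, 1.0, k)       # opposed group trends
        y[:20] -= slope
        y[20:] += slope
        res = rm_anova_gg(y, group=g)
        assert res["interaction"].p < 0.01

    def test_mixed_design_matches_pingouin(self, rng):
        import pingouin as pg
        n, k = 24, 3
        g = np.array(["a"] * 12 + ["b"] * 12)
        y = rng.normal(size=(n, k))
        res = rm_anova_gg(y, group=g)
        df = pd.DataFrame({"y": y.ravel(),
                           "s": np.repeat(np.arange(n), k),
                           "c": np.tile(np.arange(k), n),
                           "g": np.repeat(g, k)})
        ref = pg.mixed_anova(data=df, dv="y", within="c", subject="s",
                             between="g")
        assert res["group"].statistic == pytest.approx(
            float(ref.loc[ref.Source == "g", "F"].iloc[0]), rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            float(ref.loc[ref.Source == "Interaction", "F"].iloc[0]),
            rel=1e-6)

    def test_covariate_equals_explicit_residualization(self, rng):
        n, k = 30, 3
        cov = rng.normal(size=n)
        y = rng.normal(size=(n, k)) + np.outer(cov, np.ones(k))
        res = rm_anova_gg(y, covariate=cov)
        c = cov - cov.mean()
        beta = (c @ y) / (c @ c)
        ref = rm_anova_gg(y - np.outer(c, beta))
        assert res["condition"].statistic == pytest.approx(
            ref["condition"].statistic, rel=1e-12)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_absolute(x, x) == pytest.approx(1.0)

    def test_offset_penalized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_absolute(x, x + 1.0) < 1.0

    def test_three_subject_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0])
        r = np.array([1.5, 2.5, 2.0])
        x = np.column_stack([t, r])
        n, k = 3, 2
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1)[:, None] - x.mean(0)[None] + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        ref = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute(t, r) == pytest.approx(ref, abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        import pingouin as pg
        t = rng.normal(size=8)
        r = t + rng.normal(scale=0.3, size=8)
        df = pd.DataFrame({
            "targets": list(range(8)) * 2,
            "raters": ["t"] * 8 + ["r"] * 8,
            "y": np.r_[t, r],
        })
        ref = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="y")
        mask = ref.Type.isin(["ICC(A,1)", "ICC2"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_absolute(t, r) == pytest.approx(icc2, abs=1e-8)

    def test_affine_invariance_and_session_offset_sensitivity(self, rng):
        t = rng.normal(size=10)
        r = t + rng.normal(scale=0.2, size=10)
        base = icc_absolute(t, r)
        assert icc_absolute(3 * t + 1, 3 * r + 1) == pytest.approx(base,
                                                                   abs=1e-10)
        assert icc_absolute(t, r + 1.0) < base

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            icc_absolute([1.0, 2.0], [1.0, 2.0])


class TestPower:
    def test_study_minimum_detectable_effects(self):
        assert min_detectable_effect(14, 45, tails=1) == pytest.approx(
            0.77, abs=0.005)
        assert min_detectable_effect(32, tails=1) == pytest.approx(
            0.45, abs=0.005)

    def test_monotone_in_power(self):
        ds = [min_detectable_effect(20, 20, power=p) for p in
              (0.5, 0.7, 0.9)]
        assert ds[0] < ds[1] < ds[2]

    def test_unattainable_power_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_effect(3, alpha=0.05, power=1.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            min_detectable_effect(10, 10, alpha=1.5)
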