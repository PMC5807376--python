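import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmsway import (
    KinematicsSettings,
    ScoreKinematics,
    SubjectScores,
    compute_control_variables,
    compute_pa,
    crossing_interval_sd,
    make_score_series,
    zero_crossings,
)
from pmsway.control import (
    differentiate,
    design_fir_differentiator,
    filter_sensitivity_sweep,
    lowpass,
    spectrum,
)

FS = 240.0


def _sine_scores(freqs, duration=80.0, amp=1.0, sid="S"):
    t = np.arange(int(duration * FS)) / FS
    pp = np.stack([amp * np.sin(2 * np.pi * f * t) for f in freqs], axis=1)
    return SubjectScores(subject_id=sid, pp=pp, sample_rate=FS)


class TestSpectrum:
    def test_peak_at_signal_frequency(self):
        t = np.arange(int(20 * FS)) / FS
        f, p = spectrum(np.sin(2 * np.pi * 2.0 * t), FS)
        assert abs(f[np.argmax(p)] - 2.0) < f[1] - f[0] + 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spectrum(np.zeros(100), FS)

    def test_synthetic_mode_power_in_band(self):
        s = make_score_series(1.0, 2.5, 0.15, 40.0, FS, seed=2)
        f, p = spectrum(s, FS)
        band = (f >= 2.0) & (f <= 3.0)
        assert p[band].sum() > 0.5 * p.sum()


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(np.full(2000, 3.7), FS, KinematicsSettings())
        assert np.allclose(out, 3.7, atol=1e-9)

    def test_passband_and_stopband(self):
        # compare against the analytic squared magnitude response of the
        # forward-backward 5th-order Butterworth at 7 Hz
        t = np.arange(int(20 * FS)) / FS
        i = slice(1000, -1000)
        low = lowpass(np.sin(2 * np.pi * 1.0 * t), FS, KinematicsSettings())
        assert abs(np.max(np.abs(low[i])) - 1.0) < 0.01
        hi = lowpass(np.sin(2 * np.pi * 20.0 * t), FS, KinematicsSettings())
        expected = 1.0 / (1.0 + (20.0 / 7.0) ** (2 * 5))  # |H|^2 (two passes)
        assert np.max(np.abs(hi[i])) < max(0.05, 2 * expected)
        assert np.max(np.abs(hi[i])) < 0.05  # > 95% attenuation

    def test_zero_phase(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, FS, KinematicsSettings())
        lags = np.arange(-10, 11)
        xc = [np.dot(x[100:-100], np.roll(y, l)[100:-100]) for l in lags]
        assert lags[np.argmax(xc)] == 0

    def test_unstable_cutoff_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), FS, KinematicsSettings(cutoff_hz=150.0))


class TestDifferentiate:
    settings = KinematicsSettings()

    @pytest.mark.parametrize("f", [1.0, 2.0, 3.0])
    def test_sine_first_derivative(self, f):
        t = np.arange(int(40 * FS)) / FS
        d = differentiate(np.sin(2 * np.pi * f * t), FS, self.settings)
        true = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        i = slice(240, -240)
        rel = np.sqrt(np.mean((d[i] - true[i]) ** 2) / np.mean(true[i] ** 2))
        assert rel < 0.01

    def test_constant_derivative_is_zero(self):
        d = differentiate(np.full(2000, 5.0), FS, self.settings)
        assert np.max(np.abs(d[120:-120])) < 1e-10 * 5.0

    def test_ramp_derivative_is_constant(self):
        t = np.arange(int(10 * FS)) / FS
        d = differentiate(3.0 * t, FS, self.settings)
        assert np.max(np.abs(d[240:-240] - 3.0)) / 3.0 < 0.001

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            differentiate(np.zeros(40), FS, self.settings)

    def test_antisymmetric_linear_phase(self):
        h = design_fir_differentiator(50, 5.0, 7.0, FS)
        assert h.size == 51
        assert np.allclose(h, -h[::-1], atol=1e-15)


class TestComputePA:
    def test_sine_second_derivative(self):
        scores = _sine_scores([2.0])
        kin = compute_pa(scores)
        t = np.arange(scores.n_frames) / FS
        true = -((2 * np.pi * 2.0) ** 2) * np.sin(2 * np.pi * 2.0 * t)[120:-120]
        rel = np.sqrt(np.mean((kin.pa[:, 0] - true) ** 2) / np.mean(true**2))
        assert rel < 0.02

    def test_zero_scores_zero_pa(self):
        scores = SubjectScores("S", np.zeros((4000, 2)), FS)
        kin = compute_pa(scores)
        assert not kin.pa.any()

    def test_valid_window_arithmetic(self):
        kin = compute_pa(_sine_scores([2.0], duration=80.0))
        assert kin.pa.shape[0] == 18960
        assert kin.window_s == pytest.approx(79.0)

    def test_sklearn_transformer_equivalent(self):
        scores = _sine_scores([1.5], duration=10.0)
        a = ScoreKinematics().fit().transform(scores)
        b = compute_pa(scores, KinematicsSettings())
        assert np.array_equal(a.pa, b.pa)


class TestZeroCrossings:
    def test_pure_sine_pa_count(self):
        kin = compute_pa(_sine_scores([2.0]))
        times, n = zero_crossings(kin.pa[:, 0], FS)
        assert abs(n - 2 * 2.0 * 79.0) <= 2

    def test_strictly_positive_series(self):
        _, n = zero_crossings(np.ones(100) + 0.1, FS)
        assert n == 0

    def test_zero_sample_tie_rule(self):
        times, n = zero_crossings(np.array([1.0, 0.0, -1.0]), 1.0)
        assert n == 1 and times[0] == pytest.approx(1.0)

    def test_zero_run_same_sign_no_crossing(self):
        _, n = zero_crossings(np.array([1.0, 0.0, 0.0, 2.0]), 1.0)
        assert n == 0

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        _, n1 = zero_crossings(x, FS)
        _, n2 = zero_crossings(c * x, FS)
        assert n1 == n2


class TestCrossingIntervalSd:
    def test_equally_spaced_is_zero(self):
        assert crossing_interval_sd(np.arange(10) * 0.25) == 0.0

    def test_alternating_intervals(self):
        times = np.cumsum([0.0] + [0.4, 0.6] * 5)
        expected = np.std([0.4, 0.6] * 5, ddof=1)
        assert crossing_interval_sd(times) == pytest.approx(expected, abs=1e-9)

    def test_pure_sine_sigma_small(self):
        kin = compute_pa(_sine_scores([2.0]))
        times, _ = zero_crossings(kin.pa[:, 0], FS)
        assert crossing_interval_sd(times) < 0.002

    def test_too_few_crossings_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(crossing_interval_sd(np.array([0.1, 0.2])))

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.uniform(0.2, 0.3, size=20))
        assert crossing_interval_sd(times) == pytest.approx(
            crossing_interval_sd(times + 17.3), abs=1e-12
        )


class TestControlVariables:
    def test_jitter_free_mode_counts(self):
        tables = []
        for f in (1.0, 2.0, 3.0):
            s = make_score_series(1.0, f, 0.0, 80.0, FS, seed=1)
            kin = compute_pa(SubjectScores("S", s[:, None], FS))
            tables.append(compute_control_variables(kin))
        for f, tab in zip((1.0, 2.0, 3.0), tables):
            assert abs(tab["N"][0] - 2 * f * 79.0) <= 2

    def test_zero_amplitude_component(self):
        pp = np.stack([make_score_series(1.0, 2.0, 0.0, 10.0, FS, seed=1),
                       np.zeros(2400)], axis=1)
        kin = compute_pa(SubjectScores("S", pp, FS))
        tab = compute_control_variables(kin)
        assert tab["N"][1] == 0 and np.isnan(tab["sigma"][1])

    def test_jitter_raises_mean_sigma(self):
        # 20-subject Monte Carlo: planted jitter 0.2 vs 0
        sigmas = {0.0: [], 0.2: []}
        for jit in sigmas:
            for i in range(20):
                s = make_score_series(1.0, 2.0, jit, 20.0, FS, seed=100 + i)
                kin = compute_pa(SubjectScores("S", s[:, None], FS))
                sigmas[jit].append(compute_control_variables(kin)["sigma"][0])
        assert np.mean(sigmas[0.2]) > np.mean(sigmas[0.0])

    def test_rstd_merge(self):
        s = make_score_series(1.0, 2.0, 0.0, 10.0, FS, seed=1)
        kin = compute_pa(SubjectScores("S", s[:, None], FS))
        rstd = pd.DataFrame({"subject_id": ["S"], "k": [1], "rSTD": [100.0]})
        tab = compute_control_variables(kin, rstd)
        assert list(tab.columns) == ["subject_id", "k", "rSTD", "N", "sigma", "window_s"]


class TestSweep:
    def _cohort_scores(self, n=8):
        scores, meta = [], []
        rng = np.random.default_rng(3)
        for i in range(n):
            age = "old" if i % 2 else "young"
            gender = "male" if (i // 2) % 2 else "female"
            f = 2.0 * (0.9 if age == "old" else 1.0)
            s = make_score_series(1.0, f, 0.1, 10.0, FS, seed=int(rng.integers(2**31)))
            scores.append(SubjectScores(f"S{i}", s[:, None], FS))
            meta.append({"subject_id": f"S{i}", "age_group": age, "gender": gender})
        return scores, pd.DataFrame(meta)

    def test_single_setting_matches_single_run(self):
        from pmsway.group_stats import two_way_anova

        scores, meta = self._cohort_scores()
        table = filter_sensitivity_sweep(scores, [KinematicsSettings()], meta,
                                         variables=("N",))
        single = []
        for sc in scores:
            cv = compute_control_variables(compute_pa(sc, KinematicsSettings()))
            single.append(cv)
        merged = pd.concat(single).merge(meta, on="subject_id")
        res = two_way_anova(merged.rename(columns={"N": "value"}))
        age_row = table[(table.effect == "age") & (table.k == 1)]
        expected = res.effects.set_index("effect").loc["age"]
        assert age_row["F"].iloc[0] == pytest.approx(expected["F"], rel=1e-12)
        assert age_row["p"].iloc[0] == pytest.approx(expected["p"], rel=1e-12)

    def test_empty_grid_rejected(self):
        scores, meta = self._cohort_scores()
        with pytest.raises(ValueError):
            filter_sensitivity_sweep(scores, [], meta)

    def test_invalid_entry_skipped(self):
        scores, meta = self._cohort_scores()
        grid = [KinematicsSettings(), KinematicsSettings(cutoff_hz=500.0)]
        with pytest.warns(UserWarning):
            table = filter_sensitivity_sweep(scores, grid, meta, variables=("N",))
        assert set(table["cutoff_hz"]) == {7.0}
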