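import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f as fdist

from pmsway.group_stats import (
    full_report,
    levene,
    normality_tests,
    observed_power,
    percent_change,
    posthoc_simple_effects,
    sidak,
    two_way_anova,
)


def anova_oracle(df):
    """Brute-force Type III ANOVA: effect-coded least squares, model comparison."""
    a = np.where(df["age_group"] == sorted(df["age_group"].unique())[0], 1.0, -1.0)
    b = np.where(df["gender"] == sorted(df["gender"].unique())[0], 1.0, -1.0)
    y = df["value"].to_numpy()
    X = np.column_stack([np.ones_like(a), a, b, a * b])

    def rss(mat):
        beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
        r = y - mat @ beta
        return r @ r

    rss_full = rss(X)
    df2 = len(y) - 4
    out = {}
    for name, col in [("age", 1), ("gender", 2), ("age:gender", 3)]:
        ss = rss(np.delete(X, col, axis=1)) - rss_full
        F = ss / (rss_full / df2)
        out[name] = {
            "F": F,
            "p": fdist.sf(F, 1, df2),
            "partial_eta_sq": ss / (ss + rss_full),
        }
    return out


def _random_table(rng, sizes=None):
    if sizes is None:
        sizes = {(a, g): int(rng.integers(3, 10))
                 for a in ("young", "old") for g in ("female", "male")}
    rows = []
    for (a, g), n in sizes.items():
        shift = rng.normal(0, 1)
        rows.append(pd.DataFrame({
            "age_group": a, "gender": g,
            "value": rng.normal(shift, 1.0, size=n),
        }))
    return pd.concat(rows, ignore_index=True)


class TestNormality:
    def test_normal_samples_mostly_pass_shapiro(self):
        rng = np.random.default_rng(0)
        passed = 0
        for _ in range(100):
            res = normality_tests({"c": rng.normal(size=1000)})
            passed += res["sw_p"][0] > 0.05
        assert passed >= 90

    def test_lognormal_samples_mostly_fail_shapiro(self):
        rng = np.random.default_rng(1)
        rejected = 0
        for _ in range(100):
            res = normality_tests({"c": np.exp(rng.normal(size=50))})
            rejected += res["sw_p"][0] < 0.05
        assert rejected >= 90

    def test_constant_sample_flagged(self):
        res = normality_tests({"c": np.full(10, 3.0)})
        assert res["degenerate"][0]

    def test_tiny_sample_warns_nan(self):
        with pytest.warns(UserWarning):
            res = normality_tests({"c": np.array([1.0, 2.0])})
        assert np.isnan(res["sw_p"][0])


class TestLevene:
    def test_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(200):
            cells = {c: rng.normal(size=50) for c in "abcd"}
            _, p = levene(cells)
            rejections += p < 0.05
        assert 0.01 <= rejections / 200 <= 0.10

    def test_detects_variance_ratio(self):
        rng = np.random.default_rng(3)
        rejected = 0
        for _ in range(100):
            cells = {"a": rng.normal(size=50), "b": rng.normal(scale=10.0, size=50)}
            _, p = levene(cells)
            rejected += p < 0.05
        assert rejected >= 90

    def test_identical_cells_statistic_zero(self):
        x = np.arange(10.0)
        stat, _ = levene({"a": x, "b": x.copy()})
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_cells_rejected(self):
        with pytest.raises(ValueError):
            levene({"a": np.array([1.0])})


class TestTwoWayAnova:
    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for rep in range(100):
            sizes = None
            if rep % 3 == 0:  # the unbalanced 17 F / 8 M design
                sizes = {("young", "female"): 17, ("young", "male"): 8,
                         ("old", "female"): 17, ("old", "male"): 8}
            df = _random_table(rng, sizes)
            res = two_way_anova(df, check_assumptions=False)
            oracle = anova_oracle(df)
            for _, row in res.effects.iterrows():
                exp = oracle[row["effect"]]
                assert row["F"] == pytest.approx(exp["F"], abs=1e-8, rel=1e-8)
                assert row["p"] == pytest.approx(exp["p"], abs=1e-8)
                assert row["partial_eta_sq"] == pytest.approx(
                    exp["partial_eta_sq"], abs=1e-8
                )

    def test_additive_effect_has_zero_interaction(self):
        rows = []
        for a, delta in (("young", 0.0), ("old", 2.0)):
            for g in ("female", "male"):
                for v in (1.0, 2.0, 3.0):
                    rows.append({"age_group": a, "gender": g, "value": v + delta})
        res = two_way_anova(pd.DataFrame(rows), check_assumptions=False)
        inter = res.effects.set_index("effect").loc["age:gender"]
        assert inter["F"] == pytest.approx(0.0, abs=1e-20)

    def test_balanced_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(5)
        df = _random_table(rng, sizes={(a, g): 10 for a in ("young", "old")
                                       for g in ("female", "male")})
        res = two_way_anova(df, check_assumptions=False)
        y = df["value"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        ss_err = res.mse * res.df_resid
        ss_effects = sum(
            row["partial_eta_sq"] / (1 - row["partial_eta_sq"]) * ss_err
            for _, row in res.effects.iterrows()
        )
        assert ss_effects + ss_err == pytest.approx(ss_total, rel=1e-10)

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({
            "age_group": ["young"] * 4 + ["old"] * 2,
            "gender": ["female", "female", "male", "male", "female", "female"],
            "value": np.arange(6.0),
        })
        with pytest.raises(ValueError):
            two_way_anova(df)


class TestEffectSizeAndPower:
    def test_partial_eta_consistent_with_F(self):
        # eta_p^2 = SS_e/(SS_e+SS_err) and F = (SS_e/df1)/(SS_err/df2) imply
        # eta_p^2 = F*df1 / (F*df1 + df2)
        rng = np.random.default_rng(10)
        res = two_way_anova(_random_table(rng), check_assumptions=False)
        for _, row in res.effects.iterrows():
            implied = row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"])
            assert row["partial_eta_sq"] == pytest.approx(implied, rel=1e-10)

    def test_power_tends_to_one(self):
        assert observed_power(1000.0, 1, 46) > 0.9999
        assert observed_power(0.0, 1, 46) < 0.1

    def test_power_monotone_in_F(self):
        powers = [observed_power(F, 1, 46) for F in (0.5, 2.0, 8.0, 20.0)]
        assert all(p1 < p2 for p1, p2 in zip(powers, powers[1:]))


class TestSidakAndPercentChange:
    def test_sidak_values(self):
        assert sidak(0.05, 1) == pytest.approx(0.05)
        assert sidak(0.01, 3) == pytest.approx(0.029701)
        assert sidak(1.0, 5) == 1.0

    @given(st.floats(0.0, 1.0), st.integers(1, 20), st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_sidak_monotone(self, p, m1, m2):
        if m1 <= m2:
            assert sidak(p, m1) <= sidak(p, m2) + 1e-15
        assert sidak(p, m1) >= p - 1e-15

    def test_percent_change(self):
        assert percent_change(10.0, 9.08) == pytest.approx(-9.2)
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(10.0, 14.6) == pytest.approx(46.0)
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestPosthoc:
    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(6)
        df = _random_table(rng)
        res = two_way_anova(df, check_assumptions=False)
        ph = posthoc_simple_effects(df, res)
        assert len(ph) == 4
        assert (ph["p_sidak"] >= ph["p_raw"] - 1e-15).all()


class TestFullReport:
    def _control_and_meta(self, rng, n_components=2):
        sizes = {("young", "female"): 17, ("young", "male"): 8,
                 ("old", "female"): 17, ("old", "male"): 8}
        control, meta = [], []
        i = 0
        for (a, g), n in sizes.items():
            for _ in range(n):
                sid = f"S{i:02d}"
                i += 1
                meta.append({"subject_id": sid, "age_group": a, "gender": g})
                for k in range(1, n_components + 1):
                    control.append({
                        "subject_id": sid, "k": k,
                        "rSTD": rng.uniform(10, 50),
                        "N": rng.normal(300, 10),
                        "sigma": rng.uniform(0.02, 0.05),
                        "window_s": 79.0,
                    })
        return pd.DataFrame(control), pd.DataFrame(meta)

    def test_error_df_for_50_subjects(self):
        rng = np.random.default_rng(7)
        control, meta = self._control_and_meta(rng)
        anova, _ = full_report(control, meta)
        assert (anova["df2"] == 46).all()
        assert (anova["n"] == 50).all()

    def test_cell_count_three_variables_times_components(self):
        rng = np.random.default_rng(8)
        control, meta = self._control_and_meta(rng, n_components=3)
        anova, _ = full_report(control, meta)
        assert len(anova) == 3 * 3 * 3  # variables x components x effects
        assert set(anova["variable"]) == {"rSTD", "N", "sigma"}

    def test_missing_values_excluded_casewise(self):
        rng = np.random.default_rng(9)
        control, meta = self._control_and_meta(rng)
        control.loc[control.index[0], "sigma"] = np.nan  # subject S00, k=1
        with pytest.warns(UserWarning):
            anova, _ = full_report(control, meta, variables=("sigma",))
        assert (anova.loc[anova["k"] == 1, "df2"] == 45).all()
        assert (anova.loc[anova["k"] == 1, "n"] == 49).all()
        assert (anova.loc[anova["k"] == 2, "df2"] == 46).all()
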