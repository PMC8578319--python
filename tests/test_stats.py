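"""Statistics layer: correlations, fits, Welch test, wall sampling,
subject-table summaries — all checked against brute-force formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventmech import stats
from ventmech.synthetic import table1_fixture
from ventmech.markers import WallProfile


# ------------------------- brute-force oracles -----------------------------

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    from scipy.stats import t as tdist

    tstat = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return r, p


def ols_oracle(z, y):
    z, y = np.asarray(z, float), np.asarray(y, float)
    a = np.sum((z - z.mean()) * (y - y.mean())) / np.sum((z - z.mean()) ** 2)
    b = y.mean() - a * z.mean()
    yhat = a * z + b
    r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    return a, b, r2


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestPearson:
    def test_reference_correlations_of_subject_table(self):
        """Ventricle volume and lesion volume correlate with the severity
        score at the printed strengths."""
        df = table1_fixture()
        r, p = stats.pearson(df["vLV"], df["FS"])
        assert round(r, 2) == 0.77
        assert round(p, 3) == 0.026
        r2, p2 = stats.pearson(df["vWMH"], df["FS"])
        assert round(r2, 2) == 0.95
        assert p2 < 0.001

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = stats.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            r, p = stats.pearson(x, y)
            ro, po = pearson_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-12)
            assert p == pytest.approx(po, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5), c=st.floats(0.1, 10), d=st.floats(-5, 5)
    )
    def test_invariant_under_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + x
        r1, _ = stats.pearson(x, y)
        r2, _ = stats.pearson(a * x + b, c * y + d)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.pearson([1, 1, 1, 1], [1, 2, 3, 4])


class TestFits:
    def test_exact_reciprocal_recovery(self):
        r = np.array([0.8, 1.2, 1.7, 2.5, 3.0])
        y = 0.09 / r + 1.04
        fit = stats.fit_reciprocal(r, y)
        assert fit.coefficients[0] == pytest.approx(0.09, abs=1e-12)
        assert fit.coefficients[1] == pytest.approx(1.04, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_reciprocal_recovery_within_confidence(self):
        rng = np.random.default_rng(21)
        r = rng.uniform(0.8, 3.5, 60)
        sd = 0.005
        y = 0.09 / r + 1.04 + rng.normal(0, sd, 60)
        fit = stats.fit_reciprocal(r, y)
        z = 1.0 / r
        se_a = sd / np.sqrt(np.sum((z - z.mean()) ** 2))
        assert abs(fit.coefficients[0] - 0.09) < 4 * se_a

    def test_constant_response_gives_zero_slope(self):
        fit = stats.fit_reciprocal([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_exact_line_r_squared_one(self):
        x = np.arange(8.0)
        fit = stats.fit_linear(x, 2.16 * x + 2.24)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx((2.16, 2.24))

    def test_linear_fit_matches_closed_form_on_subject_table(self):
        df = table1_fixture()
        fit = stats.fit_linear(df["vCSF"], df["vLV"])
        a, b, r2 = ols_oracle(df["vCSF"], df["vLV"])
        assert fit.coefficients == pytest.approx((a, b), rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_ols_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            fit = stats.fit_linear(x, y)
            a, b, r2 = ols_oracle(x, y)
            assert fit.coefficients == pytest.approx((a, b), rel=1e-9, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = stats.welch_ttest(a, a.copy())
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(5, 50)))
            b = rng.normal(0.3, 2, int(rng.integers(5, 50)))
            res = stats.welch_ttest(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.t_statistic == pytest.approx(t, rel=1e-10)
            assert res.df == pytest.approx(df, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_unbalanced_groups_use_welch_not_pooled_df(self):
        """With group sizes 41 and 199 and unequal variances the degrees of
        freedom must be far below the pooled value of 238."""
        rng = np.random.default_rng(51)
        a = rng.normal(2.0, 1.5, 41)
        b = rng.normal(0.0, 0.5, 199)
        res = stats.welch_ttest(a, b)
        assert res.df < 100
        assert res.p_value < 0.05  # 2-sigma shift: high power

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_ttest([1.0, 1.0], [2.0, 2.0])


class TestWallSampling:
    def make_profile(self, n=300, radius=30 / (2 * np.pi)):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        coords = np.c_[radius * np.cos(t), radius * np.sin(t)]
        return WallProfile(
            arclength=radius * t,
            lambda_t=1.0 + 0.01 * np.cos(t),
            lambda_c=np.ones(n),
            coords=coords,
            n0=coords / radius,
            t0=np.c_[-np.sin(t), np.cos(t)],
            total_length=2 * np.pi * radius,
        )

    def test_thirty_equidistant_points_on_30mm_loop(self):
        prof = self.make_profile()
        vals, flags = stats.sample_wall_points(prof, np.zeros(300, bool), 30)
        assert len(vals) == 30
        # spacing 1 mm by construction of the loop length
        assert prof.total_length == pytest.approx(30.0)

    def test_empty_lesion_mask_gives_all_negative(self):
        prof = self.make_profile()
        _, flags = stats.sample_wall_points(prof, np.zeros(300, bool), 30)
        assert not flags.any()

    def test_flags_inherited_from_nearest_node(self):
        prof = self.make_profile()
        lesions = np.zeros(300, bool)
        lesions[:30] = True  # first ~3 mm of the wall
        _, flags = stats.sample_wall_points(prof, lesions, 30)
        assert flags[:3].sum() >= 2 and not flags[10:].any()


class TestTableSummary:
    def test_printed_summary_statistics(self):
        out = stats.summarize_table1(table1_fixture())
        assert round(out["vLV"]["mean"], 1) == 45.7
        assert round(out["vLV"]["sd"], 1) == 16.2
        assert round(out["vWMH"]["mean"], 2) == 8.55
        assert round(out["vWMH"]["sd"], 1) == 6.6
        assert round(out["age"]["mean"], 1) == 73.4
        assert round(out["age"]["sd"], 1) == 5.9
        assert out["vWMH_male_mean"] == pytest.approx(9.4, abs=0.051)
        assert out["vWMH_female_mean"] == pytest.approx(7.8, abs=0.051)
        assert out["vWMH_male_female_ratio"] == pytest.approx(1.2, abs=0.051)
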