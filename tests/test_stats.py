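"""Statistics layer, cross-checked against independent oracles:
normal equations for OLS, brute-force rank enumeration for Mann-Whitney,
and the two-group F = t-squared identity for ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pdpredict.stats import (
    Descriptives,
    diagnosis_regression,
    fit_ols,
    group_descriptives,
    mann_whitney,
    one_way_anova,
    per_strategy_regressions,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def ols_normal_equations(y, X):
    """Textbook OLS via the normal equations, with classical inference."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), n - k)
    # overall F for all non-intercept terms
    ss_res = resid @ resid
    ss_tot = np.sum((y - y.mean()) ** 2)
    df1, df2 = k - 1, n - k
    F = ((ss_tot - ss_res) / df1) / (ss_res / df2)
    return beta, se, t, p, F


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


class TestFitOls:
    def test_exact_linear_relationship(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        res = fit_ols(y, X)
        assert res.coefficients == pytest.approx([2.0, 3.0])
        assert res.r_squared == pytest.approx(1.0)

    def test_five_point_toy_matches_normal_equations(self):
        X = np.column_stack([np.ones(5), [1.0, 2, 3, 4, 5], [2.0, 1, 4, 3, 5]])
        y = np.array([1.2, 1.9, 3.4, 3.9, 5.3])
        res = fit_ols(y, X)
        beta, se, t, p, F = ols_normal_equations(y, X)
        assert res.coefficients == pytest.approx(beta, rel=1e-10)
        assert res.standard_errors == pytest.approx(se, rel=1e-10)
        assert res.t_values == pytest.approx(t, rel=1e-10)
        assert res.p_values == pytest.approx(p, rel=1e-10)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.df == (2, 2)

    def test_random_problems_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = rng.integers(8, 40)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            res = fit_ols(y, X)
            beta, se, _, _, F = ols_normal_equations(y, X)
            np.testing.assert_allclose(res.coefficients, beta, rtol=1e-8)
            np.testing.assert_allclose(res.standard_errors, se, rtol=1e-8)
            assert res.F == pytest.approx(F, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(np.arange(6.0), X)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_ols([1.0, 2.0], np.column_stack([np.ones(2), [1.0, 2.0]]))


def make_frame(n_per_group=30, seed=0, confound_iq=False):
    """Toy summaries frame with a known diagnosis effect on the metric."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, effect in (("autism", -5.0), ("control", 0.0)):
        for i in range(n_per_group):
            if confound_iq:
                iq = rng.normal(100 if group == "autism" else 115, 5)
            else:
                iq = rng.normal(108, 10)
            metric = 35 + effect + 0.2 * (iq - 108) + rng.normal(0, 3)
            rows.append(
                {
                    "participant_id": f"{group[0]}{i}",
                    "group": group,
                    "iq": iq,
                    "metric": metric,
                }
            )
    return pd.DataFrame(rows)


class TestDiagnosisRegression:
    def test_recovers_injected_effect(self):
        frame = make_frame(n_per_group=200, seed=1)
        res = diagnosis_regression(frame, "metric")
        assert res.terms == ("intercept", "diagnosis", "iq")
        assert res.coef("diagnosis") == pytest.approx(-5.0, abs=0.8)
        assert res.df == (2, 397)

    def test_coding_flip_negates_beta(self):
        frame = make_frame(seed=2)
        r1 = diagnosis_regression(frame, "metric", coding="autism1")
        r2 = diagnosis_regression(frame, "metric", coding="control1")
        assert r1.coef("diagnosis") == pytest.approx(-r2.coef("diagnosis"))
        assert r1.F == pytest.approx(r2.F)

    def test_omitting_iq_shifts_beta_when_confounded(self):
        frame = make_frame(n_per_group=200, seed=3, confound_iq=True)
        adjusted = diagnosis_regression(frame, "metric")
        X = np.column_stack(
            [np.ones(len(frame)), (frame["group"] == "autism").astype(float)]
        )
        unadjusted, *_ = ols_normal_equations(frame["metric"].to_numpy(), X)
        # IQ differs by group and drives the metric, so leaving it out biases
        # the diagnosis coefficient
        assert abs(unadjusted[1] - adjusted.coef("diagnosis")) > 1.0

    def test_f_invariant_under_affine_iq_rescale(self):
        frame = make_frame(seed=4)
        r1 = diagnosis_regression(frame, "metric")
        rescaled = frame.assign(iq=3.0 * frame["iq"] - 50.0)
        r2 = diagnosis_regression(rescaled, "metric")
        assert r1.F == pytest.approx(r2.F, rel=1e-10)
        # diagnosis beta also invariant under pure centering
        centered = frame.assign(iq=frame["iq"] - frame["iq"].mean())
        r3 = diagnosis_regression(centered, "metric")
        assert r3.coef("diagnosis") == pytest.approx(r1.coef("diagnosis"), rel=1e-10)

    def test_constant_metric_rejected(self):
        frame = make_frame(seed=5).assign(metric=1.0)
        with pytest.raises(ValueError, match="constant"):
            diagnosis_regression(frame, "metric")

    def test_unknown_coding_and_metric_rejected(self):
        frame = make_frame(seed=6)
        with pytest.raises(ValueError):
            diagnosis_regression(frame, "metric", coding="weird")
        with pytest.raises(ValueError):
            diagnosis_regression(frame, "nope")


def test_per_strategy_regressions_shape(small_cohort):
    from pdpredict.metrics import summaries_frame

    participants, sessions = small_cohort
    frame = summaries_frame(participants, sessions)
    table = per_strategy_regressions(frame)
    assert len(table) == 20  # 4 strategies x 5 metrics
    assert set(table["strategy"]) == {"TFT", "WSLS", "AC", "AD"}


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


class TestDescriptives:
    def test_linear_interpolation_quartiles(self):
        frame = pd.DataFrame(
            {"group": ["g"] * 5, "m": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        out = group_descriptives(frame, metrics=["m"])
        row = out.iloc[0]
        # hand computation under the linear-interpolation rule
        assert (row["median"], row["q1"], row["q3"]) == (3.0, 2.0, 4.0)
        assert row["mean"] == 3.0

    def test_constant_vector(self):
        frame = pd.DataFrame({"group": ["g"] * 4, "m": [7.0] * 4})
        row = group_descriptives(frame, metrics=["m"]).iloc[0]
        assert row["mean"] == row["median"] == row["q1"] == row["q3"] == 7.0

    def test_descriptives_ordering_enforced(self):
        with pytest.raises(ValueError):
            Descriptives(mean=1.0, median=2.0, q1=3.0, q3=1.0)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_full_separation_gives_zero_u(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_identical_samples_give_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p >= 0.99

    @pytest.mark.parametrize("seed", range(6))
    def test_small_samples_match_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(3, 6), rng.integers(3, 9)
        # distinct values so no ties
        pooled = rng.permutation(np.arange(n_a + n_b, dtype=float))
        a, b = pooled[:n_a], pooled[n_a:]
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mann_whitney_enumeration(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_eight(self):
        rng = np.random.default_rng(12)
        pooled = rng.permutation(np.arange(16, dtype=float))
        a, b = pooled[:8], pooled[8:]
        _, p_exact = mann_whitney(a, b)  # min(n) <= 8, no ties -> exact path
        z_res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        assert abs(p_exact - z_res.pvalue) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestOneWayAnova:
    def test_identical_means_give_zero_f(self):
        f, p = one_way_anova([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        f, p_f = one_way_anova(a, b)
        t, p_t = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_detects_shift_alternative(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 200), rng.normal(0.5, 1, 200)
        _, p = one_way_anova(a, b)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 1.0], [1.0, 1.0])
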