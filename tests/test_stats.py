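"""Tests of group-level inference: residualization, FDR, effect sizes,
AUC_I, mixed-model contrasts, and PLSC with permutation/bootstrap."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from capdyn import (
    auc_increase,
    benjamini_hochberg,
    cohens_d,
    fit_group_state_model,
    plsc_bootstrap,
    plsc_fit,
    plsc_permutation_test,
    residualize,
)


class TestResidualize:
    def test_intercept_only_is_mean_centring(self, rng):
        y = rng.standard_normal(20) + 5
        assert np.allclose(residualize(y), y - y.mean())

    def test_value_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(30)
        assert np.allclose(residualize(3 * x + 1, x), 0.0, atol=1e-10)

    def test_matches_projector_oracle(self, rng):
        y = rng.standard_normal(40)
        C = rng.standard_normal((40, 3))
        X = np.column_stack([np.ones(40), C])
        P = np.eye(40) - X @ np.linalg.inv(X.T @ X) @ X.T
        assert np.allclose(residualize(y, C), P @ y, atol=1e-8)

    def test_collinear_covariates_dropped(self, rng):
        x = rng.standard_normal(25)
        C = np.column_stack([x, x * 2])
        with pytest.warns(UserWarning):
            r = residualize(rng.standard_normal(25), C)
        assert r.shape == (25,)


class TestBenjaminiHochberg:
    def test_worked_examples(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(benjamini_hochberg([0.001, 0.04, 0.9]), [0.003, 0.06, 0.9])

    def test_monotone_and_bounded(self, rng):
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_fuzz_matches_statsmodels_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestCohensD:
    def test_identical_groups_zero(self, rng):
        x = rng.standard_normal(10)
        assert cohens_d(x, x) == pytest.approx(0.0)

    def test_unit_gap_is_one(self, rng):
        a = np.array([0.0, 1.0, 2.0])
        b = a + 1.0
        assert cohens_d(b, a) == pytest.approx(1.0)

    def test_matches_hand_formula(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(17) + 0.4
        pooled = np.sqrt(
            ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
            / (len(a) + len(b) - 2)
        )
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-10)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(3), np.ones(4))


class TestAucIncrease:
    def test_constant_profile_zero(self):
        assert auc_increase([3.0] * 5) == pytest.approx(0.0)

    def test_linear_profile(self):
        assert auc_increase([0, 1, 2, 3, 4]) == pytest.approx(120.0)

    def test_rise_and_fall(self):
        assert auc_increase([2, 3, 4, 3, 2]) == pytest.approx(60.0)

    def test_missing_sample_undefined(self):
        assert np.isnan(auc_increase([2, np.nan, 4, 3, 2]))


def _balanced_metrics(rng, n_per_group=15, k=3, group_shift=0.0):
    rows = []
    for g, group in enumerate(("control", "patient")):
        for i in range(n_per_group):
            sid = f"{group}{i}"
            for cap in range(1, k + 1):
                value = rng.standard_normal() + (group_shift if group == "patient" and cap == 1 else 0.0)
                for metric in ("entries",):
                    rows.append(
                        {"subject": sid, "group": group, "cap": cap,
                         "metric": metric, "value": value, "n_retained": 60}
                    )
    metrics = pd.DataFrame(rows)
    design = metrics[["subject", "group"]].drop_duplicates().reset_index(drop=True)
    return metrics, design


class TestGroupStateModel:
    def test_contrasts_match_per_state_ols_oracle(self, rng):
        # independent rows (zero between-subject variance), balanced design:
        # the contrast equals the control-minus-patient cell mean difference
        metrics, design = _balanced_metrics(rng)
        table = fit_group_state_model(metrics, design, "entries", covariates=())
        for cap in (1, 2, 3):
            df = metrics[metrics.cap == cap]
            expected = (
                df[df.group == "control"]["value"].mean()
                - df[df.group == "patient"]["value"].mean()
            )
            est = table.loc[table.cap == cap, "estimate"].iloc[0]
            assert est == pytest.approx(expected, abs=1e-6)

    def test_planted_shift_detected_with_correct_sign(self, rng):
        metrics, design = _balanced_metrics(rng, n_per_group=30, group_shift=-1.5)
        table = fit_group_state_model(metrics, design, "entries", covariates=())
        row = table[table.cap == 1].iloc[0]
        assert row["estimate"] > 0  # control minus patient
        assert row["p"] < 0.01

    def test_missing_cells_dropped(self, rng):
        metrics, design = _balanced_metrics(rng)
        metrics.loc[metrics.index[:3], "value"] = np.nan
        table = fit_group_state_model(metrics, design, "entries", covariates=())
        assert np.isfinite(table["p"]).all()


class TestPlscFit:
    def test_perfect_correlation_single_pair(self, rng):
        z = rng.standard_normal(10)
        fit = plsc_fit(z, z, ["g"] * 10)
        assert fit.singular_values[0] == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.behaviour_saliences[0, 0]) == pytest.approx(1.0)
        assert fit.behaviour_saliences[0, 0] > 0  # sign convention

    def test_independent_data_null_limit(self, rng):
        n = 2000
        fit = plsc_fit(rng.standard_normal(n), rng.standard_normal(n), ["g"] * n)
        assert fit.singular_values[0] < 2.0 / np.sqrt(n)

    def test_rank_one_recovery(self, rng):
        n, p, q = 500, 5, 4
        u = rng.standard_normal(p)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(q)
        v /= np.linalg.norm(v)
        s = rng.standard_normal(n)
        X = np.outer(s, u) + 0.5 * rng.standard_normal((n, p))
        Y = np.outer(s, v) + 0.5 * rng.standard_normal((n, q))
        fit = plsc_fit(X, Y, ["g"] * n)
        assert abs(np.corrcoef(fit.behaviour_saliences[:, 0], u)[0, 1]) > 0.9
        assert abs(np.corrcoef(fit.brain_saliences[:, 0], v)[0, 1]) > 0.9

    def test_saliences_unit_norm(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 5))
        g = ["a"] * 20 + ["b"] * 20
        fit = plsc_fit(X, Y, g)
        assert np.allclose(np.linalg.norm(fit.behaviour_saliences, axis=0), 1.0, atol=1e-8)
        assert np.allclose(np.linalg.norm(fit.brain_saliences, axis=0), 1.0, atol=1e-8)

    def test_zero_variance_column_named(self, rng):
        X = rng.standard_normal((20, 2))
        X[:, 1] = 3.0
        with pytest.raises(ValueError, match="column 1"):
            plsc_fit(X, rng.standard_normal(20), ["g"] * 20)

    def test_column_order_invariance(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 3))
        g = ["a"] * 15 + ["b"] * 15
        s1 = plsc_fit(X, Y, g).singular_values
        s2 = plsc_fit(X[:, ::-1], Y[:, [2, 0, 1]], g).singular_values
        assert np.allclose(s1, s2, atol=1e-10)


class TestPlscInference:
    def test_perfect_pair_minimum_p(self, rng):
        z = rng.standard_normal(40)
        p = plsc_permutation_test(z, z, ["g"] * 40, n_permutations=99, rng=rng)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_reproducible_with_fixed_rng(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        g = ["a"] * 15 + ["b"] * 15
        p1 = plsc_permutation_test(X, Y, g, 100, np.random.default_rng(5))
        p2 = plsc_permutation_test(X, Y, g, 100, np.random.default_rng(5))
        assert np.array_equal(p1, p2)

    def test_noiseless_bootstrap_degenerate_interval(self, rng):
        z = rng.standard_normal(12)
        intervals, stable = plsc_bootstrap(z, z, ["g"] * 12, n_boot=50, rng=rng)
        lo, hi = intervals["behaviour"][0, 0, 0], intervals["behaviour"][1, 0, 0]
        assert lo == pytest.approx(1.0, abs=1e-10)
        assert hi == pytest.approx(1.0, abs=1e-10)
        assert stable["behaviour"][0, 0]

    def test_pure_noise_saliences_unstable(self):
        unstable_cases = 0
        n_sims = 30
        for i in range(n_sims):
            r = np.random.default_rng(100 + i)
            X = r.standard_normal((30, 3))
            Y = r.standard_normal((30, 3))
            _, stable = plsc_bootstrap(X, Y, ["g"] * 30, n_boot=60, rng=r)
            # component 1 saliences should mostly straddle zero
            unstable_cases += not stable["behaviour"][:, 0].all()
        assert unstable_cases >= 0.9 * n_sims

    def test_bootstrap_interval_covers_planted_salience(self):
        # nominal 5th-95th percentile interval holds the planted behaviour
        # salience in roughly 90 % of replicates
        u = np.array([0.8, 0.6])
        v = np.array([1.0])
        sigma = 0.6
        # population salience: first left singular vector of the analytic
        # cross-correlation matrix of the standardized columns
        R_pop = np.outer(
            u / np.sqrt(u**2 + sigma**2), v / np.sqrt(v**2 + sigma**2)
        )
        target = np.linalg.svd(R_pop)[0][0, 0]
        target = abs(target)
        covered = 0
        n_rep = 100
        for i in range(n_rep):
            r = np.random.default_rng(2000 + i)
            s = r.standard_normal(80)
            X = np.outer(s, u) + sigma * r.standard_normal((80, 2))
            Y = np.outer(s, v) + sigma * r.standard_normal((80, 1))
            intervals, _ = plsc_bootstrap(X, Y, ["g"] * 80, n_boot=100, rng=r)
            lo, hi = intervals["behaviour"][0, 0, 0], intervals["behaviour"][1, 0, 0]
            covered += lo <= target <= hi
        assert 0.75 <= covered / n_rep <= 1.0
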