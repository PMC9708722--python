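"""Statistical layer: printed-table reproduction, oracles, and calibration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alpsnet import stats
from alpsnet import synthcohort as sc


class TestPooledT:
    @pytest.mark.parametrize(
        "summary, expected",
        [
            # (m1, s1, n1, m2, s2, n2) from the two-group cognition table
            ((26.38, 1.60, 77, 16.10, 4.93, 79), 17.42),  # MoCA
            ((6.69, 3.65, 77, 10.46, 4.30, 79), -5.90),  # FSRP
            ((60.48, 4.51, 77, 61.65, 5.35, 79), -1.47),  # age
        ],
    )
    def test_reproduces_printed_statistics(self, summary, expected):
        assert stats.t_from_summary(*summary)["t"] == pytest.approx(expected, abs=0.005)

    def test_identical_groups_give_zero(self):
        res = stats.t_from_summary(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stats.t_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(0.5, 1.2, size=40)
        ours = stats.t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert ours["t"] == pytest.approx(ref.statistic, abs=1e-12)
        assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-12)


class TestChi2:
    @pytest.mark.parametrize(
        "table, expected_chi2",
        [
            ((56, 23, 32, 45), 13.64),  # hypertension VCI/NC
            ((47, 32, 25, 52), 11.46),  # smoking
            ((32, 47, 46, 31), 5.77),  # hyperlipemia
            ((35, 44, 22, 55), 4.16),  # diabetes
            ((20, 59, 25, 52), 0.97),  # female
        ],
    )
    def test_reproduces_printed_statistics(self, table, expected_chi2):
        assert stats.chi2_2x2(*table)["chi2"] == pytest.approx(expected_chi2, abs=0.005)

    def test_hypertension_odds_ratio(self):
        res = stats.chi2_2x2(56, 23, 32, 45)
        assert res["odds_ratio"] == pytest.approx(56 * 45 / (23 * 32), abs=1e-12)
        assert res["odds_ratio"] == pytest.approx(3.42, abs=0.005)

    def test_balanced_table(self):
        res = stats.chi2_2x2(10, 10, 10, 10)
        assert res["chi2"] == 0.0 and res["odds_ratio"] == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            stats.chi2_2x2(0, 5, 0, 7)

    @settings(deadline=None, max_examples=50)
    @given(*(st.integers(min_value=1, max_value=60) for _ in range(4)))
    def test_transposition_and_label_swap_invariance(self, a, b, c, d):
        base = stats.chi2_2x2(a, b, c, d)["chi2"]
        assert stats.chi2_2x2(a, c, b, d)["chi2"] == pytest.approx(base, rel=1e-12)
        assert stats.chi2_2x2(d, c, b, a)["chi2"] == pytest.approx(base, rel=1e-12)

    def test_matches_scipy_uncorrected(self):
        ref = sps.chi2_contingency([[56, 23], [32, 45]], correction=False)
        assert stats.chi2_2x2(56, 23, 32, 45)["chi2"] == pytest.approx(
            ref.statistic, abs=1e-12
        )


class TestMannWhitney:
    def test_identical_samples_z_zero(self):
        x = [1.0, 2.0, 3.0]
        res = stats.mann_whitney(x, x)
        assert res["Z"] == 0.0

    def test_fully_separated_samples(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6, 7])
        assert res["U"] == 0.0  # every y exceeds every x
        res_rev = stats.mann_whitney([4, 5, 6, 7], [1, 2, 3])
        assert res_rev["U"] == 12.0  # n1 * n2

    def test_tied_data_matches_permutation_enumeration_oracle(self):
        """The tie-corrected normal variance equals the exact permutation
        variance of U, so enumerating all group assignments is an
        independent oracle for Z."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        n1 = len(x)
        us = []
        for subset in combinations(range(len(combined)), n1):
            r1 = ranks[list(subset)].sum()
            us.append(r1 - n1 * (n1 + 1) / 2.0)
        us = np.array(us)
        res = stats.mann_whitney(x, y)
        z_oracle = (res["U"] - us.mean()) / us.std(ddof=0)
        assert res["Z"] == pytest.approx(z_oracle, abs=1e-12)

    def test_all_tied_returns_zero_with_warning(self, caplog):
        res = stats.mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res["Z"] == 0.0 and res["p"] == 1.0


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert stats.correlate(x, 2 * x + 1)["r"] == pytest.approx(1.0)

    def test_rank_reversal_spearman(self):
        x = np.array([1.0, 5.0, 3.0, 9.0, 7.0])
        y = -x
        assert stats.correlate(x, y, "spearman")["r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(20, 20), seed=12))
        x = df.mean_alps.to_numpy()
        y = df.Eg.to_numpy()
        r = stats.correlate(x, y)["r"]
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogistic:
    def test_single_binary_predictor_reproduces_closed_form_or(self):
        """Saturated logistic on a 2x2 table: OR = ad/bc (here 3.42)."""
        a, b, c, d = 56, 23, 32, 45  # exposed yes/no, unexposed yes/no
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        table = stats.logistic_fit(pd.DataFrame({"exposed": x}), y)
        assert table.loc["exposed", "OR"] == pytest.approx(
            a * d / (b * c), abs=1e-8
        )

    def test_constant_predictor_rejected(self):
        X = pd.DataFrame({"x": np.ones(30)})
        y = np.r_[np.ones(15), np.zeros(15)]
        with pytest.raises(ValueError, match="rank-deficient"):
            stats.logistic_fit(X, y)

    def test_complete_separation_rejected(self):
        x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
        y = (x > 0).astype(float)
        with pytest.raises(stats.SeparationError):
            stats.logistic_fit(pd.DataFrame({"x": x}), y)

    def test_percent_scaled_parameter_recovery(self):
        """True log-OR -0.10 per ALPS percentage point recovered within 3 SE
        at n = 5000."""
        rng = np.random.default_rng(77)
        n = 5000
        alps = rng.normal(1.875, 0.15, n)
        logit = -0.10 * (alps * 100 - 187.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        table = stats.logistic_fit(
            pd.DataFrame({"mean_alps": alps}), y, percent="mean_alps"
        )
        est, se = table.loc["mean_alps", "coef"], table.loc["mean_alps", "se"]
        assert abs(est - (-0.10)) < 3 * se
        assert table.loc["mean_alps", "ci_low"] < np.exp(est) < table.loc[
            "mean_alps", "ci_high"
        ]


class TestLinearStandardized:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "c1": np.cos(2 * np.pi * t / n),
                "s1": np.sin(2 * np.pi * t / n),
                "c2": np.cos(4 * np.pi * t / n),
            }
        )
        y = X.c1 + 0.5 * X.s1 + np.random.default_rng(1).normal(0, 0.1, n)
        table = stats.linear_fit_standardized(X, y)
        assert np.allclose(table.VIF, 1.0, atol=1e-9)

    def test_duplicated_predictor_raises_collinearity_error(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x1": x, "x2": x})
        with pytest.raises(stats.CollinearityError) as exc:
            stats.linear_fit_standardized(X, rng.normal(size=50))
        assert np.isinf(exc.value.vif_table).any()

    def test_vif_closed_form_at_r2_075(self):
        """x2 = x1 + e with var(e) = 1/3 gives R^2 = 0.75, VIF = 4."""
        rng = np.random.default_rng(9)
        n = 10_000
        x1 = rng.normal(0, 1, n)
        x2 = x1 + rng.normal(0, np.sqrt(1.0 / 3.0), n)
        y = x1 - x2 + rng.normal(0, 1, n)
        table = stats.linear_fit_standardized(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert table.VIF.loc["x1"] == pytest.approx(4.0, abs=0.25)
        assert table.VIF.loc["x2"] == pytest.approx(4.0, abs=0.25)

    def test_standardized_betas_match_statsmodels_convention(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["u", "v"])
        y = 3 * X.u - X.v + rng.normal(size=200)
        table = stats.linear_fit_standardized(X, y)
        # standardized beta = raw beta * sd(x)/sd(y)
        import statsmodels.api as sm

        raw = sm.OLS(y, sm.add_constant(X)).fit()
        for col in X:
            expected = raw.params[col] * X[col].std(ddof=1) / y.std(ddof=1)
            assert table.loc[col, "beta_std"] == pytest.approx(expected, abs=1e-10)


class TestMediate:
    @staticmethod
    def _exact_frame(n=40, a=0.05, b=100.0):
        """Mediator deviation constructed orthogonal to [1, X] so the fitted
        a (hence indirect = a*b) is exact."""
        rng = np.random.default_rng(5)
        x = np.linspace(1.5, 2.3, n)
        d = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), x])
        d -= basis @ np.linalg.lstsq(basis, d, rcond=None)[0]
        m = 0.10 + a * x + 0.01 * d
        y = b * m  # c' = 0: the effect is fully mediated
        return pd.DataFrame({"mean_alps": x, "Eg": m, "MoCA": y})

    def test_fully_mediated_noise_free_recovery_is_exact(self):
        df = self._exact_frame()
        res = stats.mediate(df, covariates=(), n_boot=1000, seed=0)
        assert res.indirect == pytest.approx(5.0, abs=1e-8)
        assert res.c_prime == pytest.approx(0.0, abs=1e-8)
        assert res.mediation_ratio == pytest.approx(1.0, abs=1e-10)

    def test_ols_identity_c_equals_cprime_plus_ab(self):
        for seed in range(5):
            df = sc.simulate_cohort(sc.CohortParams(n=(40, 40), seed=seed))
            res = stats.mediate(df, n_boot=1000, seed=seed)
            assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-10)
            assert res.ci[0] <= res.indirect <= res.ci[1]

    def test_bootstrap_bitwise_reproducible_and_stable(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(60, 60), seed=8))
        r1 = stats.mediate(df, n_boot=2000, seed=99)
        r2 = stats.mediate(df, n_boot=2000, seed=99)
        assert r1.ci == r2.ci
        r3 = stats.mediate(df, n_boot=8000, seed=99)
        w_small = r1.ci[1] - r1.ci[0]
        w_large = r3.ci[1] - r3.ci[0]
        assert abs(w_large - w_small) / w_small < 0.2  # converged within MC error

    def test_ratio_definitions(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(60, 60), seed=4))
        tot = stats.mediate(df, n_boot=1000, seed=1)
        comp = stats.mediate(
            df, n_boot=1000, seed=1, ratio_definition="indirect_over_components"
        )
        assert tot.mediation_ratio == pytest.approx(tot.indirect / tot.c)
        assert comp.mediation_ratio == pytest.approx(
            comp.indirect / (abs(comp.c_prime) + abs(comp.indirect))
        )

    def test_zero_variance_mediator_rejected(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(20, 20), seed=2))
        df["Eg"] = 0.2
        with pytest.raises(ValueError, match="zero variance"):
            stats.mediate(df, n_boot=1000, seed=0)

    def test_too_few_cases_rejected(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(3, 3), seed=2))
        with pytest.raises(ValueError, match="complete cases"):
            stats.mediate(df.head(6), n_boot=1000)


class TestGroupCompare:
    def test_alps_difference_detected_at_cohort_scale(self):
        """At n = 2000/group the 1.95 vs 1.80 ALPS separation is certain."""
        df = sc.simulate_cohort(sc.CohortParams(n=(2000, 2000), seed=31))
        table = stats.group_compare_table(df).set_index("variable")
        assert table.loc["mean_alps", "p"] < 0.001
        assert table.loc["mean_alps", "test"] == "t"
        assert table.loc["lacune_count", "test"] == "mw"
        assert table.loc["hypertension", "test"] == "chi2"

    def test_single_group_rejected(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(30, 30), seed=1))
        with pytest.raises(ValueError, match="two groups"):
            stats.group_compare_table(df[df.group == "NC"])

    def test_constant_variable_reported_as_na(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(20, 20), seed=6))
        df["Eg"] = 0.2
        table = stats.group_compare_table(df).set_index("variable")
        assert np.isnan(table.loc["Eg", "p"])
        assert "constant" in table.loc["Eg", "note"]

    def test_text_rendering(self):
        df = sc.simulate_cohort(sc.CohortParams(n=(20, 20), seed=6))
        txt = stats.table_to_text(stats.group_compare_table(df))
        assert "mean_alps" in txt and "statistic" in txt
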