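"""Association fitters against independent closed-form / enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ecgfactors as ef
from ecgfactors.association import multiple_testing_plan


def ols_oracle(y, X):
    """Normal equations + classical SEs: beta, se, sigma2, adjusted R^2."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    adj = 1 - (1 - r2) * (n - 1) / (n - p)
    return beta, se, adj


class TestCorrelate:
    def test_copied_column_has_unit_correlation(self, rng):
        x = rng.normal(size=(50, 3))
        out = ef.correlate(x, x[:, [1]])
        assert out.iloc[1, 0] == pytest.approx(1.0)

    def test_matches_hand_computed_covariance_on_small_table(self):
        lat = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0],
                        [4.0, 2.0], [5.0, 7.0]])
        par = np.array([[2.0], [4.0], [5.0], [4.0], [9.0]])
        out = ef.correlate(lat, par)
        for j in range(2):
            x, y = lat[:, j], par[:, 0]
            r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert out.iloc[j, 0] == pytest.approx(r, rel=1e-12)

    def test_independent_columns_near_zero(self, rng):
        a = rng.normal(size=(10_000, 2))
        b = rng.normal(size=(10_000, 2))
        assert np.abs(ef.correlate(a, b).to_numpy()).max() < 0.05

    def test_zero_variance_column_flagged_nan(self, rng):
        lat = rng.normal(size=(20, 2))
        par = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ef.correlate(lat, par)
        assert out.iloc[:, 0].isna().all()
        assert out.iloc[:, 1].notna().all()

    def test_requires_three_rows(self, rng):
        with pytest.raises(ValueError, match="3"):
            ef.correlate(rng.normal(size=(2, 2)), rng.normal(size=(2, 1)))


class TestLinearModel:
    def test_exact_linear_outcome_perfectly_explained(self, rng):
        lat = rng.normal(size=(50, 3))
        age = rng.uniform(40, 80, 50)
        sex = rng.integers(0, 2, 50).astype(float)
        y = 2.0 * lat[:, 0] - 1.5 * lat[:, 2] + 0.1 * age + 0.5 * sex + 3.0
        fit = ef.fit_continuous(y, lat, age, sex)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)
        # per-SD coefficient of the z-scaled latent
        assert fit.table.loc["f1", "coef"] == pytest.approx(
            2.0 * lat[:, 0].std(ddof=0), rel=1e-9)

    def test_matches_normal_equations_oracle_on_fixture(self, rng):
        n = 20
        lat = rng.normal(size=(n, 3))
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = lat @ [0.5, -0.2, 0.0] + 0.05 * age + rng.normal(size=n)
        fit = ef.fit_continuous(y, lat, age, sex)
        latz = (lat - lat.mean(0)) / lat.std(0, ddof=0)
        X = np.column_stack([np.ones(n), latz, age, sex])
        beta, se, adj = ols_oracle(y, X)
        np.testing.assert_allclose(fit.table["coef"].to_numpy(), beta,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.table["se"].to_numpy(), se, atol=1e-8)
        assert fit.adj_r2 == pytest.approx(adj, abs=1e-8)

    def test_pure_noise_gives_near_zero_adjusted_r2(self, rng):
        lat = rng.normal(size=(1000, 32))
        age = rng.uniform(40, 80, 1000)
        sex = rng.integers(0, 2, 1000).astype(float)
        y = rng.normal(size=1000)
        fit = ef.fit_continuous(y, lat, age, sex)
        assert abs(fit.adj_r2) < 0.05

    def test_rank_deficiency_reported_with_columns(self, rng):
        lat = rng.normal(size=(30, 2))
        lat = np.column_stack([lat, lat[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="rank deficient"):
            ef.fit_continuous(rng.normal(size=30), lat)

    def test_compare_models_identical_predictors_tie(self, rng):
        lat = rng.normal(size=(60, 3))
        y = lat @ [1.0, 0.5, -0.5] + rng.normal(size=60)
        out = ef.compare_models(y, lat, lat)
        assert out["difference"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_compare_models_extra_signal_column_wins(self, rng):
        base = rng.normal(size=(200, 2))
        signal = rng.normal(size=200)
        y = signal * 2.0 + rng.normal(size=200)
        out = ef.compare_models(y, np.column_stack([base, signal]), base)
        assert out["difference"].iloc[0] > 0


class TestLogisticModel:
    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            ef.fit_binary(np.ones(40), rng.normal(size=(40, 2)))

    def test_planted_log_odds_recovered_within_two_se(self, rng):
        n = 5000
        lat = rng.normal(size=(n, 4))
        lp = 0.5 * lat[:, 2] - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        fit = ef.fit_binary(y, lat)
        row = fit.table.loc["f3"]
        # predictor z-scaled; truth on the z scale is 0.5 * sd
        truth = 0.5 * lat[:, 2].std(ddof=0)
        assert abs(row["coef"] - truth) < 2 * row["se"]

    def test_matches_direct_likelihood_maximum_on_fixture(self, rng):
        n = 40
        x = rng.normal(size=(n, 1))
        y = (rng.random(n) < 1 / (1 + np.exp(-x[:, 0]))).astype(float)
        fit = ef.fit_binary(y, x)
        xz = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=0)
        X = np.column_stack([np.ones(n), xz])

        def nll(b):
            lp = X @ b
            return np.sum(np.log1p(np.exp(lp)) - y * lp)

        opt = optimize.minimize(nll, np.zeros(2), method="BFGS",
                                options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.table["coef"].to_numpy(), opt.x,
                                   atol=1e-6)

    def test_perfect_separation_detected_and_reported(self):
        x = np.concatenate([np.linspace(-3, -1, 20),
                            np.linspace(1, 3, 20)])[:, None]
        y = (x[:, 0] > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            ef.fit_binary(y, x)

    def test_significance_flag_uses_supplied_threshold(self, rng):
        n = 2000
        lat = rng.normal(size=(n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * lat[:, 0]))).astype(float)
        fit = ef.fit_binary(y, lat, threshold=1e-4)
        assert bool(fit.table.loc["f1", "significant"])
        assert "significant" in fit.table.columns


class TestCoxModel:
    def test_toy_fit_matches_enumerated_partial_likelihood(self):
        # 5 subjects, 3 events, distinct times -> Breslow = Efron here
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 0])
        x = np.array([[0.5], [-0.2], [0.8], [-1.0], [0.1]])
        res = ef.fit_survival(time, event, x, z_scale=False, prefix="x")
        xv = x[:, 0]

        def neg_pl(b):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = time >= time[i]
                ll += b * xv[i] - np.log(np.sum(np.exp(b * xv[risk])))
            return -ll

        opt = optimize.minimize_scalar(neg_pl, bounds=(-5, 5),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        coef = res.table.loc["x1", "coef"]
        # partial likelihood at the fit agrees with the enumerated optimum;
        # the likelihood is flat so the coefficient itself is looser
        assert neg_pl(coef) == pytest.approx(neg_pl(opt.x), abs=1e-6)
        assert coef == pytest.approx(opt.x, abs=1e-2)
        assert res.n_events == 3

    def test_null_predictor_hr_interval_covers_one(self, rng):
        n = 500
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1.0, n)
        c = rng.uniform(0.5, 2.0, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        res = ef.fit_survival(time, event, x)
        row = res.table.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]

    def test_input_validation(self, rng):
        x = rng.normal(size=(10, 1))
        with pytest.raises(ValueError, match="event"):
            ef.fit_survival(np.ones(10), np.zeros(10), x)
        with pytest.raises(ValueError, match="positive"):
            ef.fit_survival(np.zeros(10), np.ones(10), x)


class TestEffectiveTests:
    def test_identity_correlation_counts_every_factor(self):
        assert ef.effective_tests(np.eye(32)) == pytest.approx(32.0)

    def test_rank_one_matrix_counts_one(self):
        corr = np.ones((32, 32))
        assert ef.effective_tests(corr) == pytest.approx(1.0)

    def test_two_perfect_blocks_count_two(self):
        corr = np.kron(np.eye(2), np.ones((16, 16)))
        assert ef.effective_tests(corr) == pytest.approx(2.0)

    def test_data_matrix_input_equivalent_to_its_correlation(self, rng):
        x = rng.normal(size=(200, 6))
        x[:, 3] = x[:, 0] * 0.9 + 0.1 * rng.normal(size=200)
        direct = ef.effective_tests(x)
        via_corr = ef.effective_tests(np.corrcoef(x, rowvar=False))
        assert direct == pytest.approx(via_corr, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bounds_on_random_correlation_matrices(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(60, 8))
        m = ef.effective_tests(a)
        assert 1.0 <= m <= 8.0

    def test_plan_threshold_uses_rounded_m_eff(self, rng):
        x = rng.normal(size=(500, 10))
        plan = multiple_testing_plan(x, alpha=0.05)
        assert plan.threshold == pytest.approx(0.05 / round(plan.m_eff))
        assert 1 <= plan.m_eff <= 10


class TestBonferroni:
    def test_identity_divisor(self):
        assert ef.bonferroni(0.05, 1).threshold == 0.05

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ef.bonferroni(0.05, 0.5)
        with pytest.raises(ValueError):
            ef.bonferroni(1.5, 10)

    def test_printed_value_has_three_significant_figures(self):
        out = ef.bonferroni(0.05, 496)
        assert out.printed == 1.01e-4
        assert out.threshold == pytest.approx(0.05 / 496, rel=1e-15)


class TestVariantScan:
    def _cohort(self, rng, n=300, m=4):
        lat = rng.normal(size=(n, 3))
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        return lat, dos, age, sex

    def test_collinear_dosage_recovers_scaling_with_null_p(self, rng):
        lat = rng.normal(size=(100, 2))
        dos = np.column_stack([lat[:, 0] * 2.0])
        scan = ef.variant_scan(lat, dos)
        row = scan[(scan["variant"] == "var1") & (scan["factor"] == "f1")]
        assert row["beta"].iloc[0] == pytest.approx(0.5, rel=1e-9)
        assert row["p"].iloc[0] < 1e-200

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        lat, dos, age, sex = self._cohort(rng)
        scan = ef.variant_scan(lat, dos, age, sex)
        for vj in range(dos.shape[1]):
            for fk in range(lat.shape[1]):
                X = sm.add_constant(np.column_stack([dos[:, vj], age, sex]))
                fit = sm.OLS(lat[:, fk], X).fit()
                row = scan[(scan["variant"] == f"var{vj + 1}")
                           & (scan["factor"] == f"f{fk + 1}")].iloc[0]
                assert row["beta"] == pytest.approx(fit.params[1], abs=1e-10)
                assert row["se"] == pytest.approx(fit.bse[1], abs=1e-10)
                assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_p_values_invariant_to_affine_dosage_rescaling(self, rng):
        lat, dos, age, sex = self._cohort(rng)
        a = ef.variant_scan(lat, dos, age, sex)
        b = ef.variant_scan(lat, dos * 3.0 + 1.0, age, sex)
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy(),
                                   atol=1e-12)

    def test_monomorphic_variant_flagged_and_skipped(self, rng):
        lat, dos, age, sex = self._cohort(rng)
        dos[:, 2] = 0.0
        scan = ef.variant_scan(lat, dos, age, sex)
        rows = scan[scan["variant"] == "var3"]
        assert rows["skipped"].all()
        assert rows["beta"].isna().all()

    def test_genotype_matrix_input_and_tsv_output(self, rng, tmp_path):
        lat = rng.normal(size=(50, 2))
        g = ef.simulate_genotypes(50, 3, [0.2, 0.3, 0.4], seed=1)
        scan = ef.variant_scan(lat, g)
        assert set(scan["variant"]) == set(g.variant_ids)
        out = tmp_path / "scan.tsv"
        ef.scan_to_tsv(scan, out)
        back = pd.read_csv(out, sep="\t")
        assert len(back) == len(scan)


class TestDisentanglementReport:
    def test_unit_variance_factors_unflagged(self, rng):
        lat = rng.normal(size=(500, 5))
        rep = ef.disentanglement_report(lat)
        assert not rep["subtle_morphology"].any()

    def test_single_shrunken_factor_flagged(self, rng):
        lat = rng.normal(size=(500, 5))
        lat[:, 2] *= 1e-3
        rep = ef.disentanglement_report(lat)
        assert rep["subtle_morphology"].sum() == 1
        assert rep.loc[2, "subtle_morphology"]

    def test_flags_partition_all_factors(self, rng):
        lat = rng.normal(size=(100, 7))
        lat[:, :3] *= 1e-3
        rep = ef.disentanglement_report(lat)
        assert len(rep) == 7
        assert rep["subtle_morphology"].sum() + \
            (~rep["subtle_morphology"]).sum() == 7
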