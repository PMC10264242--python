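import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ribostat as rs
from ribostat.io import DataError
from ribostat.ter import TranslationEfficiencyTester

from conftest import make_count_matrix


def fit_pair(rpf1, rna1, rpf2, rna2, **kw):
    rpf = make_count_matrix([[rpf1, rpf2]], read_type="RPF")
    rna = make_count_matrix([[rna1, rna2]], read_type="RNA")
    design = rs.DesignMatrix(
        pd.DataFrame({"group": [0.0, 1.0]}, index=["s0", "s1"])
    )
    kw.setdefault("min_total", 0.0)
    return TranslationEfficiencyTester(**kw).fit(rpf, rna, design)


class TestSaturatedTwoSample:
    def test_beta_equals_log_odds_ratio(self):
        fit = fit_pair(100, 100, 200, 100)
        beta = fit.results_.set_index("term").loc["group", "beta"]
        assert beta == pytest.approx(np.log(2.0), abs=1e-8)

    def test_identical_samples_give_null_ter(self):
        fit = fit_pair(150, 150, 150, 150)
        tbl = fit.summary("group")
        assert tbl["logTER"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert tbl["TER"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_zero_rpf_group_flags_separation(self):
        fit = fit_pair(0, 100, 50, 100, pseudocount=0.0)
        assert fit.fits_["t0"].status == "separated"
        # LRT fallback still yields a finite, significant p
        p = fit.results_.set_index("term").loc["group", "p"]
        assert np.isfinite(p) and p < 0.01

    def test_auto_pseudocount_restores_finite_estimate(self):
        fit = fit_pair(0, 10, 10, 10, pseudocount="auto")
        beta = fit.results_.set_index("term").loc["group", "beta"]
        assert beta == pytest.approx(np.log(21.0), abs=1e-6)  # Haldane oracle

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        # beta equals the log odds ratio for any positive table
        rpf1, rna1, rpf2, rna2 = rng.integers(5, 500, 4)
        fit = fit_pair(rpf1, rna1, rpf2, rna2)
        log_or, _, _ = rs.ter_2x2_oracle(rpf1, rna1, rpf2, rna2)
        row = fit.results_.set_index("term").loc["group"]
        assert row["beta"] == pytest.approx(log_or, abs=1e-6)
        # p-value comparison in the regime where both asymptotic tests are
        # valid (moderate effects); far-tail p-values of the two references
        # diverge for any implementation
        n1, n2 = rng.integers(200, 800, 2)
        r1 = rng.binomial(n1, 0.5)
        r2 = rng.binomial(n2, 0.55)
        fit = fit_pair(r1, n1 - r1, r2, n2 - r2)
        log_or, chi2_p, _ = rs.ter_2x2_oracle(r1, n1 - r1, r2, n2 - r2)
        row = fit.results_.set_index("term").loc["group"]
        assert row["beta"] == pytest.approx(log_or, abs=1e-6)
        ratio = row["p"] / chi2_p
        assert 0.5 <= ratio <= 2.0


class Test2x2Oracle:
    def test_symmetric_table(self):
        log_or, chi2_p, fisher_p = rs.ter_2x2_oracle(50, 50, 50, 50)
        assert log_or == 0.0
        assert fisher_p == pytest.approx(1.0)

    def test_zero_margin_gives_na_without_pseudocount(self):
        log_or, _, _ = rs.ter_2x2_oracle(0, 10, 10, 10)
        assert np.isnan(log_or)

    def test_haldane_example(self):
        log_or, _, _ = rs.ter_2x2_oracle(0, 10, 10, 10, pseudocount=0.5)
        assert log_or == pytest.approx(np.log(21.0))


class TestAdjustPvalues:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            rs.adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_edge_cases(self):
        np.testing.assert_allclose(rs.adjust_pvalues([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(rs.adjust_pvalues([0.2]), [0.2])

    def test_na_propagates_and_m_excludes_na(self):
        out = rs.adjust_pvalues([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(
            rs.adjust_pvalues(p), multipletests(p, method="fdr_bh")[1]
        )


class TestReplicatedFit:
    def make_replicated(self, rpf, rna):
        n = len(rpf)
        design = rs.DesignMatrix(
            pd.DataFrame(
                {"group": [0.0] * (n // 2) + [1.0] * (n - n // 2)},
                index=[f"s{i}" for i in range(n)],
            )
        )
        return (
            make_count_matrix([rpf], read_type="RPF"),
            make_count_matrix([rna], read_type="RNA"),
            design,
        )

    def test_matches_statsmodels_binomial_glm(self):
        """Dual route: our Newton vs statsmodels GLM with freq weights."""
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        rpf = rng.poisson(120, 6).astype(float)
        rna = rng.poisson(100, 6).astype(float)
        rpf[3:] *= 1.7
        m_rpf, m_rna, design = self.make_replicated(rpf, rna)
        fit = TranslationEfficiencyTester(min_total=0).fit(m_rpf, m_rna, design)
        X = design.matrix([f"s{i}" for i in range(6)])
        ref = sm.GLM(
            rpf / (rpf + rna), X, family=sm.families.Binomial(),
            freq_weights=rpf + rna,
        ).fit()
        ours = fit.results_["beta"].to_numpy()
        np.testing.assert_allclose(ours, ref.params, atol=1e-7)
        np.testing.assert_allclose(
            fit.results_["se"].to_numpy(), ref.bse, rtol=1e-5
        )

    def test_fractional_counts_accepted_and_consistent(self):
        # scaling all counts by 2 halves SEs but leaves beta unchanged
        rpf = np.array([50.3, 61.7, 45.2, 90.9, 88.1, 101.4])
        rna = np.array([60.1, 55.5, 63.3, 58.8, 61.2, 59.9])
        m1 = self.make_replicated(rpf, rna)
        m2 = self.make_replicated(rpf * 2, rna * 2)
        f1 = TranslationEfficiencyTester(min_total=0).fit(*m1)
        f2 = TranslationEfficiencyTester(min_total=0).fit(*m2)
        np.testing.assert_allclose(
            f1.results_["beta"], f2.results_["beta"], atol=1e-8
        )
        assert (
            f2.results_["se"].to_numpy() < f1.results_["se"].to_numpy()
        ).all()

    def test_min_total_marks_low_transcripts_untestable(self):
        rpf = make_count_matrix([[2, 3], [100, 120]], read_type="RPF")
        rna = make_count_matrix([[3, 2], [100, 90]], read_type="RNA")
        design = rs.DesignMatrix(
            pd.DataFrame({"group": [0.0, 1.0]}, index=["s0", "s1"])
        )
        fit = TranslationEfficiencyTester(min_total=10).fit(rpf, rna, design)
        assert fit.fits_["t0"].status == "low_count"
        assert np.isnan(fit.summary("group")["p"].iloc[0])
        assert fit.fits_["t1"].status == "ok"

    def test_monotonicity_in_group_rpf(self):
        base = np.array([100.0, 110, 95, 100, 110, 95])
        rna = np.full(6, 100.0)
        betas = []
        for mult in (1.0, 1.3, 1.8):
            rpf = base.copy()
            rpf[3:] *= mult
            fit = TranslationEfficiencyTester(min_total=0).fit(
                *self.make_replicated(rpf, rna)
            )
            betas.append(fit.results_.set_index("term").loc["group", "beta"])
        assert betas[0] < betas[1] < betas[2]

    def test_dispersion_flag_never_shrinks_se(self):
        rng = np.random.default_rng(10)
        rpf = rng.poisson(200, 6).astype(float) * rng.uniform(0.5, 2.0, 6)
        rna = rng.poisson(200, 6).astype(float)
        args = self.make_replicated(rpf, rna)
        plain = TranslationEfficiencyTester(min_total=0).fit(*args)
        quasi = TranslationEfficiencyTester(min_total=0, dispersion=True).fit(*args)
        assert (
            quasi.results_["se"].to_numpy()
            >= plain.results_["se"].to_numpy() - 1e-12
        ).all()


class TestPredict:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(2)
        rpf = make_count_matrix(rng.poisson(150, (3, 4)), read_type="RPF")
        rna = make_count_matrix(rng.poisson(150, (3, 4)), read_type="RNA")
        design = rs.DesignMatrix(
            pd.DataFrame(
                {"group": [0.0, 0.0, 1.0, 1.0], "batch": [0.0, 1.0, 0.0, 1.0]},
                index=[f"s{i}" for i in range(4)],
            )
        )
        return TranslationEfficiencyTester(min_total=0).fit(rpf, rna, design)

    def test_equal_settings_give_unit_ter(self, fitted):
        out = fitted.predict_ter({"group": 1.0}, {"group": 1.0})
        np.testing.assert_allclose(out["TER"], 1.0)

    def test_direct_substitution(self, fitted):
        out = fitted.predict_ter({"group": 0.0}, {"group": 1.0})
        beta = fitted.fits_["t0"].coef.loc["group", "beta"]
        assert out.loc["t0", "TER"] == pytest.approx(np.exp(beta))

    def test_two_covariate_cancellation(self, fitted):
        # contrast moving both covariates: logTER = beta_g + beta_b
        out = fitted.predict_ter({}, {"group": 1.0, "batch": 1.0})
        coef = fitted.fits_["t1"].coef
        assert out.loc["t1", "logTER"] == pytest.approx(
            coef.loc["group", "beta"] + coef.loc["batch", "beta"]
        )

    def test_unknown_column_rejected(self, fitted):
        with pytest.raises(DataError, match="unknown design column"):
            fitted.predict_ter({"nope": 1.0}, {})


def test_recovery_on_simulated_effects(small_ribo):
    """Planted logTER = ln 2 recovered without systematic bias."""
    rna = rs.normalize(small_ribo["rna"])
    rpf = rs.normalize(small_ribo["rpf"])
    fit = rs.fit_ter(rpf, rna, small_ribo["design"])
    tbl = fit.summary("group").set_index("transcript_id")
    truth = small_ribo["truth"]
    est = tbl.loc[truth.index[truth["is_effect"]], "logTER"].dropna()
    assert len(est) >= 10
    assert est.mean() == pytest.approx(np.log(2.0), abs=0.12)
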