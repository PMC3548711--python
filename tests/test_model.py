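"""Design construction, REML estimation, tests, BLUPs and fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aeusurv.io import ValidationError
from aeusurv.model import (
    AEU_FULL,
    EXON_COMMON,
    SINGLE_EXON,
    DesignBundle,
    build_design,
    exon_slopes,
    fit_reml,
    fold_change,
)
from aeusurv.model import test_aeu as aeu_test
from aeusurv.model import test_survival as survival_test
from aeusurv.simulate import GeneConfig, simulate_gene

from conftest import make_gene


def reml_loglik_dense(y, X, Z_blocks, components):
    """Brute-force restricted Gaussian likelihood with an explicit dense V."""
    N, p = X.shape
    V = components["resid"] * np.eye(N)
    for name, Z in Z_blocks.items():
        V += components[name] * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtVinvX)
    return -0.5 * (ld_V + ld_X + r @ Vinv @ r + (N - p) * np.log(2 * np.pi))


class TestBuildDesign:
    def test_dimensions_and_blocks(self, tiny_clinical):
        expr = pd.DataFrame(np.arange(18, dtype=float).reshape(3, 6),
                            index=["e1", "e2", "e3"],
                            columns=tiny_clinical["patient_id"])
        d = build_design(expr, tiny_clinical, AEU_FULL)
        assert d.y.shape == (18,)
        assert d.X.shape == (18, 8)
        assert d.Z_blocks["exon"].shape == (18, 3)
        assert d.Z_blocks["patient"].shape == (18, 6)
        assert d.fixed_names == [
            "intercept", "gender[male]", "race[caucasian]", "therapy[CRT]",
            "therapy[CRnT]", "therapy[OTHER]", "therapy[R]", "survival",
        ]

    def test_survival_exon_block_entries(self, tiny_clinical):
        expr = pd.DataFrame(np.zeros((2, 6)), index=["e1", "e2"],
                            columns=tiny_clinical["patient_id"])
        d = build_design(expr, tiny_clinical, AEU_FULL)
        Zsx = d.Z_blocks["survival_exon"]
        surv = tiny_clinical["survival_months"].to_numpy()
        # row for exon 2, patient 0 carries S in column 1, zero in column 0
        assert Zsx[6, 1] == surv[0]
        assert Zsx[6, 0] == 0.0
        assert Zsx[0, 0] == surv[0]

    def test_single_exon_has_no_random_blocks(self, tiny_clinical):
        expr = pd.DataFrame(np.ones((1, 6)), index=["e1"],
                            columns=tiny_clinical["patient_id"])
        d = build_design(expr, tiny_clinical, SINGLE_EXON)
        assert d.Z_blocks == {}
        assert d.X.shape == (6, 8)

    def test_bad_level_rejected(self, tiny_clinical):
        clin = tiny_clinical.copy()
        clin.loc[0, "therapy"] = "CHEMO"
        expr = pd.DataFrame(np.ones((2, 6)), index=["e1", "e2"],
                            columns=clin["patient_id"])
        with pytest.raises(ValidationError, match="therapy"):
            build_design(expr, clin, AEU_FULL)

    def test_constant_covariate_column_dropped(self, tiny_clinical):
        clin = tiny_clinical.copy()
        clin["gender"] = "male"
        expr = pd.DataFrame(np.ones((2, 6)), index=["e1", "e2"],
                            columns=clin["patient_id"])
        d = build_design(expr, clin, AEU_FULL)
        assert "gender[male]" not in d.fixed_names

    def test_spec_exon_count_preconditions(self, tiny_clinical):
        one = pd.DataFrame(np.ones((1, 6)), index=["e1"],
                           columns=tiny_clinical["patient_id"])
        with pytest.raises(ValidationError):
            build_design(one, tiny_clinical, AEU_FULL)
        two = pd.DataFrame(np.ones((2, 6)), index=["e1", "e2"],
                           columns=tiny_clinical["patient_id"])
        with pytest.raises(ValidationError):
            build_design(two, tiny_clinical, SINGLE_EXON)


class TestREML:
    def test_degenerate_no_variance_matches_ols(self, small_cohort):
        """All random variances 0: components hit the boundary, beta = OLS."""
        expr, _ = make_gene(small_cohort, gene_id="flat", n_exons=4,
                            sigma2_exon=0.0, sigma2_patient=0.0,
                            sigma2_resid=0.25, b=0.0)
        d = build_design(expr, small_cohort, AEU_FULL)
        fit = fit_reml(d)
        assert fit.components["exon"] <= 0.05
        assert fit.components["survival_exon"] <= 1e-4
        assert fit.components["patient"] <= 0.05
        beta_ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=2e-2)

    def test_balanced_one_way_matches_anova_closed_form(self, rng):
        """REML on a balanced one-way random-effects layout reproduces the
        classical ANOVA estimators MSE and (MSB - MSE)/n."""
        n_groups, n_per = 12, 6
        y = (rng.normal(0, 1.0, size=n_groups).repeat(n_per)
             + rng.normal(0, 0.5, size=n_groups * n_per) + 5.0)
        X = np.ones((y.size, 1))
        Z = np.kron(np.eye(n_groups), np.ones((n_per, 1)))
        d = DesignBundle(y=y, X=X, Z_blocks={"patient": Z}, fixed_names=["intercept"],
                         exon_ids=[], patient_ids=[f"g{i}" for i in range(n_groups)],
                         survival=np.zeros(n_groups), spec=EXON_COMMON, gene_id="anova")
        fit = fit_reml(d)
        groups = y.reshape(n_groups, n_per)
        mse = np.sum((groups - groups.mean(axis=1, keepdims=True)) ** 2) / (
            n_groups * (n_per - 1))
        msb = n_per * np.sum((groups.mean(axis=1) - y.mean()) ** 2) / (n_groups - 1)
        assert fit.components["resid"] == pytest.approx(mse, abs=1e-8)
        assert fit.components["patient"] == pytest.approx((msb - mse) / n_per, abs=1e-8)

    def test_loglik_matches_dense_oracle_on_small_instances(self, rng):
        """Restricted loglik at the fitted components equals a brute-force
        dense-covariance evaluation, over 20 random instances <= 30 obs."""
        n_checked = 0
        while n_checked < 20:
            n_exon = int(rng.integers(2, 4))
            n_pat = int(rng.integers(4, 30 // n_exon + 1))
            clin = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n_pat)],
                "gender": rng.choice(["male", "female"], n_pat),
                "race": rng.choice(["caucasian", "other"], n_pat),
                "therapy": rng.choice(["NONE", "R"], n_pat),
                "survival_months": rng.uniform(1, 60, n_pat),
            })
            expr = pd.DataFrame(rng.normal(7, 1, size=(n_exon, n_pat)),
                                index=[f"e{m}" for m in range(n_exon)],
                                columns=clin["patient_id"])
            d = build_design(expr, clin, AEU_FULL)
            if d.n_obs - d.X.shape[1] < 3:
                continue
            try:
                fit = fit_reml(d)
            except ValidationError:  # chance-collinear tiny design
                continue
            oracle = reml_loglik_dense(d.y, d.X, d.Z_blocks, fit.components)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)
            n_checked += 1

    def test_shift_invariance(self, small_cohort):
        """Adding a constant to all expression changes only the intercept."""
        expr, _ = make_gene(small_cohort, gene_id="shift", n_exons=5,
                            sigma2_slope=1e-4, b=0.01)
        d1 = build_design(expr, small_cohort, AEU_FULL)
        d2 = build_design(expr + 10.0, small_cohort, AEU_FULL)
        f1, f2 = fit_reml(d1), fit_reml(d2)
        for name in ("exon", "survival_exon", "patient", "resid"):
            assert f1.components[name] == pytest.approx(f2.components[name], rel=1e-3, abs=1e-8)
        assert f2.beta["intercept"] - f1.beta["intercept"] == pytest.approx(10.0, abs=1e-4)
        assert f2.beta["survival"] == pytest.approx(f1.beta["survival"], abs=1e-6)

    def test_singular_fixed_design_rejected(self, tiny_clinical):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                            index=["e1", "e2"], columns=tiny_clinical["patient_id"])
        d = build_design(expr, tiny_clinical, AEU_FULL)
        d.X = np.hstack([d.X, d.X[:, [1]]])  # duplicate column
        d.fixed_names = d.fixed_names + ["dup"]
        with pytest.raises(ValidationError, match="singular"):
            fit_reml(d)


class TestAEUTest:
    def _fit_pair(self, expr, clinical):
        fr = fit_reml(build_design(expr, clinical, EXON_COMMON))
        g = np.array([fr.components["exon"] / fr.components["resid"], 0.0,
                      fr.components["patient"] / fr.components["resid"]])
        ff = fit_reml(build_design(expr, clinical, AEU_FULL), starts=[g])
        return ff, fr

    def test_identical_logliks_give_p_one(self, small_cohort):
        expr, _ = make_gene(small_cohort, gene_id="idn", n_exons=3)
        ff, fr = self._fit_pair(expr, small_cohort)
        fr2 = fr.__class__(**{**vars(fr), "loglik": ff.loglik})
        assert aeu_test(ff, fr2) == 1.0

    def test_chi_bar_square_reference_value(self, small_cohort):
        """q = 3.841 (the 0.95 quantile of chi2_1) must give p ~ 0.025."""
        expr, _ = make_gene(small_cohort, gene_id="ref", n_exons=3)
        ff, fr = self._fit_pair(expr, small_cohort)
        fr3 = fr.__class__(**{**vars(fr), "loglik": ff.loglik - 3.841 / 2})
        assert aeu_test(ff, fr3) == pytest.approx(0.5 * 0.05, abs=2e-4)

    def test_full_never_below_reduced(self, small_cohort):
        """Nesting: the reduced optimum is feasible for the full model."""
        for seed in range(5):
            expr, _ = make_gene(small_cohort, gene_id=f"nest{seed}", n_exons=4,
                                seed=seed + 100)
            ff, fr = self._fit_pair(expr, small_cohort)
            assert ff.loglik >= fr.loglik - 1e-6

    def test_wald_alternative_runs(self, small_cohort):
        expr, _ = make_gene(small_cohort, gene_id="wald", n_exons=6,
                            sigma2_slope=4e-4, b=0.0)
        fr = fit_reml(build_design(expr, small_cohort, EXON_COMMON))
        ff = fit_reml(build_design(expr, small_cohort, AEU_FULL),
                      compute_component_se=True)
        p = aeu_test(ff, fr, method="wald")
        assert 0.0 <= p <= 1.0


class TestSurvivalTest:
    def test_zero_slope_gives_p_one(self, small_cohort):
        expr, _ = make_gene(small_cohort, gene_id="z", n_exons=3)
        fit = fit_reml(build_design(expr, small_cohort, EXON_COMMON))
        fit.beta["survival"] = 0.0
        assert survival_test(fit) == pytest.approx(1.0)

    def test_known_z_score_normal_limit(self, small_cohort):
        expr, _ = make_gene(small_cohort, gene_id="z2", n_exons=3)
        fit = fit_reml(build_design(expr, small_cohort, EXON_COMMON))
        se = float(fit.se_beta["survival"])
        fit.beta["survival"] = 1.96 * se
        assert survival_test(fit) == pytest.approx(0.05, abs=5e-3)

    def test_null_rejection_rate_near_alpha(self, small_cohort):
        """Simulated b = 0 genes reject at roughly the nominal level."""
        ps = []
        for i in range(120):
            expr, _ = make_gene(small_cohort, gene_id=f"null{i}", n_exons=3,
                                seed=i + 500, b=0.0)
            fit = fit_reml(build_design(expr, small_cohort, EXON_COMMON))
            ps.append(survival_test(fit))
        rate = np.mean(np.array(ps) < 0.05)
        se = np.sqrt(0.05 * 0.95 / 120)
        assert rate <= 0.05 + 3 * se + 1e-9


class TestExonSlopes:
    def test_boundary_variance_gives_common_slope(self, small_cohort):
        expr, _ = make_gene(small_cohort, gene_id="com", n_exons=4,
                            sigma2_slope=0.0, b=0.02)
        fit = fit_reml(build_design(expr, small_cohort, AEU_FULL))
        if fit.components["survival_exon"] == 0.0:
            slopes = exon_slopes(fit)
            np.testing.assert_allclose(slopes["slope"], fit.beta["survival"])
            np.testing.assert_allclose(slopes["se"], fit.se_beta["survival"])

    def test_blup_shrinkage_vs_per_exon_ols(self, medium_cohort):
        """|BLUP slope deviation| never exceeds the per-exon OLS deviation."""
        expr, _ = make_gene(medium_cohort, gene_id="shrink", n_exons=6,
                            sigma2_slope=2e-4, b=0.01, seed=7)
        fit = fit_reml(build_design(expr, medium_cohort, AEU_FULL))
        from aeusurv.model import encode_fixed

        Xp = encode_fixed(medium_cohort).to_numpy()
        j = list(encode_fixed(medium_cohort).columns).index("survival")
        ols = []
        for m in range(6):
            y = expr.iloc[m].to_numpy()
            coef, *_ = np.linalg.lstsq(Xp, y, rcond=None)
            ols.append(coef[j])
        ols_dev = np.array(ols) - np.mean(ols)
        blup_dev = fit.blups["survival_exon"].to_numpy()
        assert np.all(np.abs(blup_dev) <= np.abs(ols_dev) + 1e-3)

    def test_slope_rank_recovery(self, medium_cohort):
        """Estimated per-exon slopes track the simulated truth (rank > 0.9)."""
        cfg = GeneConfig(gene_id="rank", n_exons=20, sigma2_slope=1e-4, b=0.01)
        expr, truth = simulate_gene(medium_cohort, cfg, seed=42)
        fit = fit_reml(build_design(expr, medium_cohort, AEU_FULL))
        est = exon_slopes(fit)["slope"].to_numpy()
        true = np.array([float(v) for v in truth["true_slopes"].split(";")])
        rho = stats.spearmanr(est, true).statistic
        assert rho > 0.9


class TestFoldChange:
    @pytest.mark.parametrize(
        "slope,expected",
        [(0.0337, 1.0236), (-0.0256, 0.9824), (0.0, 1.0), (0.0118, 1.0082)],
    )
    def test_printed_pairs(self, slope, expected):
        assert round(float(fold_change(slope)), 4) == expected

    def test_reciprocal_symmetry(self, rng):
        s = rng.normal(size=20)
        np.testing.assert_allclose(fold_change(s) * fold_change(-s), 1.0, rtol=1e-12)
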