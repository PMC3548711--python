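"""Cross-cohort prediction, R² and slope-correlation checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from aeusurv.io import ValidationError
from aeusurv.model import AEU_FULL, EXON_COMMON, build_design, fit_reml
from aeusurv.simulate import (
    GeneConfig,
    TRAIN_COHORT,
    VALID_COHORT,
    simulate_cohort,
    simulate_gene,
)
from aeusurv.validation import (
    compare_cohorts,
    predict_expression,
    r_squared,
    summarize_reports,
)


@pytest.fixture(scope="module")
def cohorts():
    train = simulate_cohort(dataclasses.replace(TRAIN_COHORT, n_patients=120),
                            seed=21, prefix="T")
    valid = simulate_cohort(dataclasses.replace(VALID_COHORT, n_patients=120),
                            seed=21, prefix="V")
    return train, valid


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_prediction_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_worse_than_mean_is_negative(self):
        assert r_squared([1, 2, 3], [3, 1, 5]) < 0


class TestPredictExpression:
    def test_survival_zero_ignores_slope_blups(self, cohorts):
        train, _ = cohorts
        expr, _ = simulate_gene(train, GeneConfig(gene_id="g", n_exons=4,
                                                  sigma2_slope=1e-4, b=0.01), seed=31)
        fit = fit_reml(build_design(expr, train, AEU_FULL))
        clin = train.iloc[:5].copy()
        clin["survival_months"] = 1e-12  # effectively S = 0
        pred = predict_expression(fit, clin)
        # slope BLUPs contribute slope * S ~ 0: rows differ only by exon BLUP
        diff = pred.to_numpy() - pred.to_numpy()[0]
        expected = (fit.blups["exon"].to_numpy() - fit.blups["exon"].to_numpy()[0])
        np.testing.assert_allclose(diff[:, 0], expected, atol=1e-9)

    def test_training_prediction_plus_patient_blups_beats_fixed_only(self, cohorts):
        train, _ = cohorts
        expr, _ = simulate_gene(train, GeneConfig(gene_id="g2", n_exons=5,
                                                  sigma2_slope=1e-4, b=0.01), seed=32)
        fit = fit_reml(build_design(expr, train, AEU_FULL))
        pred_no = predict_expression(fit, train)
        pred_with = predict_expression(fit, train, include_patient_blups=True)
        r2_no = r_squared(expr.to_numpy(), pred_no.to_numpy())
        r2_with = r_squared(expr.to_numpy(), pred_with.to_numpy())
        assert r2_with >= r2_no

    def test_unseen_level_rejected_by_name(self, cohorts):
        train, _ = cohorts
        clin = train.copy()
        clin["therapy"] = "NONE"  # training with a single therapy level
        expr, _ = simulate_gene(clin, GeneConfig(gene_id="g3", n_exons=3), seed=33)
        fit = fit_reml(build_design(expr, clin, AEU_FULL))
        new = train.iloc[:4].copy()
        new["therapy"] = ["CRT", "NONE", "NONE", "NONE"]
        with pytest.raises(ValidationError, match="CRT"):
            predict_expression(fit, new)

    def test_prediction_error_variance_matches_unexplained_components(self, cohorts):
        """For a fresh cohort the prediction error variance approaches
        sigma2_patient + sigma2_resid (patient effects unpredictable)."""
        train, valid = cohorts
        errs = []
        for i in range(15):
            cfg = GeneConfig(gene_id=f"pv{i}", n_exons=6, sigma2_slope=1e-4,
                             b=0.01, sigma2_patient=0.25, sigma2_resid=0.25)
            expr_t, _ = simulate_gene(train, cfg, seed=40)
            expr_v, _ = simulate_gene(valid, cfg, seed=40)
            fit = fit_reml(build_design(expr_t, train, AEU_FULL))
            pred = predict_expression(fit, valid)
            errs.append(np.var(expr_v.to_numpy() - pred.to_numpy()))
        assert np.mean(errs) == pytest.approx(0.50, rel=0.2)


class TestCompareCohorts:
    def _fit(self, expr, clin):
        return fit_reml(build_design(expr, clin, AEU_FULL))

    def test_identical_fits_perfect_agreement(self, cohorts):
        train, _ = cohorts
        expr, _ = simulate_gene(train, GeneConfig(gene_id="id", n_exons=5,
                                                  sigma2_slope=2e-4, b=0.01), seed=50)
        fit = self._fit(expr, train)
        rep = compare_cohorts(fit, fit, obs_train=expr, clinical_train=train,
                              obs_valid=expr, clinical_valid=train)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.spearman == pytest.approx(1.0)
        assert rep.relative_r2_diff == pytest.approx(0.0, abs=1e-12)

    def test_negated_slopes_give_minus_one(self, cohorts):
        train, _ = cohorts
        expr, _ = simulate_gene(train, GeneConfig(gene_id="neg", n_exons=5,
                                                  sigma2_slope=2e-4, b=0.0), seed=51)
        fit = self._fit(expr, train)
        flipped = dataclasses.replace(
            fit,
            beta=-fit.beta,
            blups={k: -v for k, v in fit.blups.items()},
        )
        rep = compare_cohorts(fit, flipped)
        assert rep.pearson == pytest.approx(-1.0)

    def test_correlation_symmetric_under_cohort_swap(self, cohorts):
        train, valid = cohorts
        cfg = GeneConfig(gene_id="sym", n_exons=6, sigma2_slope=2e-4, b=0.01)
        expr_t, _ = simulate_gene(train, cfg, seed=52)
        expr_v, _ = simulate_gene(valid, cfg, seed=52)
        ft, fv = self._fit(expr_t, train), self._fit(expr_v, valid)
        ab = compare_cohorts(ft, fv)
        ba = compare_cohorts(fv, ft)
        assert ab.pearson == pytest.approx(ba.pearson, rel=1e-9)
        assert ab.spearman == pytest.approx(ba.spearman, rel=1e-9)

    def test_too_few_exons_gives_nan_correlations(self, cohorts):
        train, _ = cohorts
        expr, _ = simulate_gene(train, GeneConfig(gene_id="few", n_exons=2), seed=53)
        fit = self._fit(expr, train)
        rep = compare_cohorts(fit, fit)
        assert np.isnan(rep.pearson) and np.isnan(rep.spearman)

    def test_strong_aeu_genes_replicate_across_cohorts(self, cohorts):
        """Median Pearson across genes simulated from one truth is high."""
        train, valid = cohorts
        reports = []
        for i in range(12):
            cfg = GeneConfig(gene_id=f"rep{i}", n_exons=8,
                             cassette=(2 + i % 4, 3, 0.02), b=0.0)
            expr_t, _ = simulate_gene(train, cfg, seed=60)
            expr_v, _ = simulate_gene(valid, cfg, seed=60)
            reports.append(compare_cohorts(
                self._fit(expr_t, train), self._fit(expr_v, valid),
                obs_train=expr_t, clinical_train=train,
                obs_valid=expr_v, clinical_valid=valid,
            ))
        summary = summarize_reports(reports)
        assert summary["median_pearson"] > 0.8
        assert np.isfinite(summary["median_r2_valid"])
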