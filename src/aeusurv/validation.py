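"""Train→validation assessment of the per-gene fits.

Training parameter estimates (fixed effects plus exon-level BLUPs) predict
exon expression for new patients; agreement is scored by R² and by the
Pearson/Spearman correlation of per-exon survival slopes between
independently fitted cohorts.  Patient effects are excluded from
cross-cohort predictions (a new patient's effect has expectation zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .model import GeneFit, encode_fixed, exon_slopes

__all__ = [
    "ValidationReport",
    "predict_expression",
    "r_squared",
    "compare_cohorts",
    "summarize_reports",
]


@dataclass
class ValidationReport:
    """Per-gene cross-cohort agreement metrics."""

    gene_id: str
    r2_train: float
    r2_valid: float
    r2_valid_refit: float
    relative_r2_diff: float  # (r2_train - r2_valid) / r2_train, NaN if r2_train <= 0
    pearson: float
    spearman: float
    negative_r2: bool


def predict_expression(
    fit_train: GeneFit,
    clinical: pd.DataFrame,
    include_patient_blups: bool = False,
) -> pd.DataFrame:
    """Predicted exon expression for a cohort from training estimates.

    prediction = X beta_hat + exon intercept BLUP + exon slope BLUP * S.
    ``include_patient_blups`` adds the fitted patient effects and is only
    meaningful on the training cohort itself.
    """
    Xp = encode_fixed(clinical, keep_columns=list(fit_train.beta.index))
    fixed = Xp.to_numpy(float) @ fit_train.beta.to_numpy()
    surv = Xp["survival"].to_numpy(float)
    n_exon = fit_train.n_exons
    pred = np.tile(fixed, (n_exon, 1))
    if "exon" in fit_train.blups:
        pred += fit_train.blups["exon"].to_numpy()[:, None]
    if "survival_exon" in fit_train.blups:
        pred += fit_train.blups["survival_exon"].to_numpy()[:, None] * surv[None, :]
    if include_patient_blups:
        if "patient" not in fit_train.blups:
            raise ValidationError("fit has no patient BLUPs")
        pat = fit_train.blups["patient"].reindex(clinical["patient_id"])
        if pat.isna().any():
            raise ValidationError("patient BLUPs requested for unseen patients")
        pred += pat.to_numpy()[None, :]
    return pd.DataFrame(pred, index=fit_train.exon_ids, columns=clinical["patient_id"])


def r_squared(observed, predicted) -> float:
    """1 - SS_res / SS_tot about the observed mean (may be negative)."""
    obs = np.asarray(observed, dtype=float).ravel()
    pre = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pre.size or obs.size < 2:
        raise ValidationError("observed/predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("zero total variance in observed values")
    ss_res = float(np.sum((obs - pre) ** 2))
    return 1.0 - ss_res / ss_tot


def compare_cohorts(
    fit_train: GeneFit,
    fit_valid: GeneFit,
    obs_train: pd.DataFrame | None = None,
    clinical_train: pd.DataFrame | None = None,
    obs_valid: pd.DataFrame | None = None,
    clinical_valid: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-cohort agreement for one gene.

    Slope correlations use the per-exon slopes (b + t_m) of the two fits;
    genes with < 3 exons get NaN correlations.  R² values are computed when
    the corresponding observations and clinical tables are supplied:
    ``r2_train`` from the training fit's own (patient-free) predictions,
    ``r2_valid`` from training estimates applied to validation covariates,
    and ``r2_valid_refit`` from the validation fit's own predictions.
    """
    if fit_train.exon_ids != fit_valid.exon_ids:
        raise ValidationError("cohort fits cover different exon sets")
    s_train = exon_slopes(fit_train)["slope"].to_numpy()
    s_valid = exon_slopes(fit_valid)["slope"].to_numpy()
    if len(s_train) >= 3 and np.std(s_train) > 0 and np.std(s_valid) > 0:
        pearson = float(stats.pearsonr(s_train, s_valid).statistic)
        spearman = float(stats.spearmanr(s_train, s_valid).statistic)
    else:
        pearson = spearman = float("nan")

    r2_train = r2_valid = r2_valid_refit = float("nan")
    if obs_train is not None and clinical_train is not None:
        pred = predict_expression(fit_train, clinical_train)
        r2_train = r_squared(obs_train.to_numpy(), pred.to_numpy())
    if obs_valid is not None and clinical_valid is not None:
        pred = predict_expression(fit_train, clinical_valid)
        r2_valid = r_squared(obs_valid.to_numpy(), pred.to_numpy())
        pred_refit = predict_expression(fit_valid, clinical_valid)
        r2_valid_refit = r_squared(obs_valid.to_numpy(), pred_refit.to_numpy())

    rel = float("nan")
    if np.isfinite(r2_train) and r2_train > 0 and np.isfinite(r2_valid):
        rel = (r2_train - r2_valid) / r2_train
    return ValidationReport(
        gene_id=fit_train.gene_id,
        r2_train=r2_train,
        r2_valid=r2_valid,
        r2_valid_refit=r2_valid_refit,
        relative_r2_diff=rel,
        pearson=pearson,
        spearman=spearman,
        negative_r2=bool(np.isfinite(r2_valid) and r2_valid < 0),
    )


def summarize_reports(reports: list[ValidationReport]) -> dict[str, float]:
    """Cohort-level medians across genes (NaN-aware)."""
    df = pd.DataFrame([vars(r) for r in reports])
    out = {}
    for col in ("r2_train", "r2_valid", "r2_valid_refit", "relative_r2_diff",
                "pearson", "spearman"):
        out[f"median_{col}"] = float(np.nanmedian(df[col])) if len(df) else float("nan")
    return out
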