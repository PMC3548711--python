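"""End-to-end orchestration: fit every gene, call groups, validate, enrich.

This is the programmatic surface behind the command-line interface.  All
outputs are deterministic given the inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, caller, enrichment, validation
from .io import ExonExpressionSet, ValidationError
from .model import (
    AEU_FULL,
    EXON_COMMON,
    SINGLE_EXON,
    GeneFit,
    build_design,
    exon_slopes,
    fit_reml,
    test_aeu,
    test_survival,
)

__all__ = ["RunConfig", "GeneResult", "fit_gene", "fit_all_genes",
           "run_fit", "run_validate", "run_enrich"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and toggles for a pipeline run."""

    alpha: float = caller.DEFAULT_ALPHA
    fdr_multi: float = caller.DEFAULT_FDR_MULTI
    fdr_single: float = caller.DEFAULT_FDR_SINGLE
    fc_low: float = caller.DEFAULT_FC_LOW
    fc_high: float = caller.DEFAULT_FC_HIGH
    min_run: int = caller.DEFAULT_MIN_RUN
    window: int = caller.DEFAULT_WINDOW
    test_method: str = "lrt"  # "lrt" | "wald"
    center_survival: bool = False
    seed: int = 0
    max_nonconverged_frac: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.fdr_multi < 1 and 0 < self.fdr_single < 1):
            raise ValidationError("thresholds must lie in (0, 1)")
        if not (0 < self.fc_low <= 1 <= self.fc_high):
            raise ValidationError("fold-change bounds must bracket 1")
        if self.min_run < 1 or self.window < 1:
            raise ValidationError("min_run and window must be >= 1")
        if self.test_method not in ("lrt", "wald"):
            raise ValidationError(f"unknown test method {self.test_method!r}")


@dataclass
class GeneResult:
    """Fits and test p-values for one gene."""

    gene_id: str
    n_exons: int
    fit_full: GeneFit | None  # AEU model (multi-exon only)
    fit_reduced: GeneFit  # exon-common model, or the single-exon OLS fit
    p_aeu: float  # NaN for single-exon genes
    p_survival: float
    slopes: pd.DataFrame = field(repr=False)


def fit_gene(
    gene_id: str,
    gene_expr: pd.DataFrame,
    clinical: pd.DataFrame,
    config: RunConfig | None = None,
) -> GeneResult:
    """Fit the appropriate nested model pair for one gene and test it."""
    config = config or RunConfig()
    n_exons = gene_expr.shape[0]
    if n_exons == 1:
        design = build_design(gene_expr, clinical, SINGLE_EXON,
                              center_survival=config.center_survival, gene_id=gene_id)
        fit = fit_reml(design)
        slopes = exon_slopes(fit)
        slopes.insert(0, "gene_id", gene_id)
        return GeneResult(gene_id, 1, None, fit, float("nan"),
                          test_survival(fit), slopes)

    d_red = build_design(gene_expr, clinical, EXON_COMMON,
                         center_survival=config.center_survival, gene_id=gene_id)
    fit_red = fit_reml(d_red)
    d_full = build_design(gene_expr, clinical, AEU_FULL,
                          center_survival=config.center_survival, gene_id=gene_id)
    # seed the full fit with the reduced optimum so the LRT is never negative
    g_red = np.array([
        fit_red.components["exon"] / fit_red.components["resid"],
        0.0,
        fit_red.components["patient"] / fit_red.components["resid"],
    ])
    fit_full = fit_reml(d_full, starts=[g_red],
                        compute_component_se=(config.test_method == "wald"))
    p_aeu = test_aeu(fit_full, fit_red, method=config.test_method)
    p_surv = test_survival(fit_red)
    slopes = exon_slopes(fit_full)
    slopes.insert(0, "gene_id", gene_id)
    return GeneResult(gene_id, n_exons, fit_full, fit_red, p_aeu, p_surv, slopes)


def fit_all_genes(
    eset: ExonExpressionSet,
    clinical: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GeneResult], list[str]]:
    """Fit every gene in the expression set.

    Returns (per-gene results table, per-exon slopes table, fits by gene,
    excluded gene log).  Genes whose fit fails or does not converge are
    excluded with a logged reason.
    """
    config = config or RunConfig()
    records, slope_parts, fits, excluded = [], [], {}, []
    for gene_id in eset.gene_ids:
        expr = eset.gene_slice(gene_id)
        try:
            gr = fit_gene(gene_id, expr, clinical, config)
        except (ValidationError, np.linalg.LinAlgError) as exc:
            excluded.append(f"{gene_id}: {exc}")
            log.warning("excluding gene %s: %s", gene_id, exc)
            continue
        conv = gr.fit_reduced.converged and (gr.fit_full is None or gr.fit_full.converged)
        if not conv:
            excluded.append(f"{gene_id}: non-convergence")
            log.warning("excluding gene %s: non-convergence", gene_id)
            continue
        fits[gene_id] = gr
        fit_for_comp = gr.fit_full if gr.fit_full is not None else gr.fit_reduced
        records.append({
            "gene_id": gene_id,
            "n_exons": gr.n_exons,
            "spec": fit_for_comp.spec.kind,
            "b": float(gr.fit_reduced.beta["survival"]),
            "se_b": float(gr.fit_reduced.se_beta["survival"]),
            "p_aeu": gr.p_aeu,
            "p_survival": gr.p_survival,
            "sigma2_exon": fit_for_comp.components.get("exon", 0.0),
            "sigma2_slope": fit_for_comp.components.get("survival_exon", 0.0),
            "sigma2_patient": fit_for_comp.components.get("patient", 0.0),
            "sigma2_resid": fit_for_comp.components["resid"],
            "loglik": fit_for_comp.loglik,
            "converged": conv,
        })
        slope_parts.append(gr.slopes)
    results = pd.DataFrame(records)
    slopes = (
        pd.concat(slope_parts, ignore_index=True)
        if slope_parts
        else pd.DataFrame(columns=["gene_id", "exon_id", "order", "slope",
                                   "se", "p_exon", "fold_change"])
    )
    return results, slopes, fits, excluded


def run_fit(
    eset: ExonExpressionSet,
    clinical: pd.DataFrame,
    out_dir: Path,
    config: RunConfig | None = None,
) -> dict:
    """Fit + classify and write gene_results.tsv, exon_slopes.tsv,
    aeu_calls.tsv and a run manifest.  Returns the result bundle."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results, slopes, fits, excluded = fit_all_genes(eset, clinical, config)
    if len(results) == 0:
        raise ValidationError("no gene could be fitted")
    calls = caller.classify_genes(
        results, slopes,
        alpha=config.alpha, fdr_multi=config.fdr_multi, fdr_single=config.fdr_single,
        fc_low=config.fc_low, fc_high=config.fc_high,
        min_run=config.min_run, window=config.window,
    )
    results.to_csv(out_dir / "gene_results.tsv", sep="\t", index=False,
                   float_format="%.6g")
    slopes.to_csv(out_dir / "exon_slopes.tsv", sep="\t", index=False,
                  float_format="%.6g")
    calls.to_csv(out_dir / "aeu_calls.tsv", sep="\t", index=False,
                 float_format="%.4g")
    cfg_hash = hashlib.sha256(
        json.dumps(vars(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config": vars(config),
        "config_hash": cfg_hash,
        "n_genes_fit": int(len(results)),
        "n_excluded": len(excluded),
        "excluded": excluded,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"results": results, "slopes": slopes, "calls": calls,
            "fits": fits, "excluded": excluded, "manifest": manifest}


def run_validate(
    fits_train: dict[str, GeneResult],
    eset_train: ExonExpressionSet,
    clinical_train: pd.DataFrame,
    eset_valid: ExonExpressionSet,
    clinical_valid: pd.DataFrame,
    out_dir: Path,
    config: RunConfig | None = None,
    gene_ids: list[str] | None = None,
) -> dict:
    """Refit each gene on the validation cohort under its training spec and
    score cross-cohort agreement; writes validation.tsv plus a summary."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    for gene_id in (gene_ids if gene_ids is not None else list(fits_train)):
        gr = fits_train.get(gene_id)
        if gr is None:
            continue
        expr_v = eset_valid.gene_slice(gene_id)
        try:
            gr_v = fit_gene(gene_id, expr_v, clinical_valid, config)
        except (ValidationError, np.linalg.LinAlgError) as exc:
            log.warning("validation refit failed for %s: %s", gene_id, exc)
            continue
        ft = gr.fit_full if gr.fit_full is not None else gr.fit_reduced
        fv = gr_v.fit_full if gr_v.fit_full is not None else gr_v.fit_reduced
        reports.append(validation.compare_cohorts(
            ft, fv,
            obs_train=eset_train.gene_slice(gene_id), clinical_train=clinical_train,
            obs_valid=expr_v, clinical_valid=clinical_valid,
        ))
    df = pd.DataFrame([vars(r) for r in reports])
    df.to_csv(out_dir / "validation.tsv", sep="\t", index=False, float_format="%.6g")
    summary = validation.summarize_reports(reports)
    (out_dir / "validation_summary.json").write_text(json.dumps(summary, indent=2))
    return {"reports": df, "summary": summary}


def run_enrich(
    calls: pd.DataFrame,
    results: pd.DataFrame,
    gene_sets: enrichment.GeneSetCollection,
    out_dir: Path,
) -> dict:
    """Both enrichment modes over the fitted genes; writes enrichment TSVs.

    Hit list = group-1 (AEU) genes; background = all genes with a converged
    fit.  The sign-partition mode uses every fitted gene's standardized
    overall slope b/SE(b).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    background = results["gene_id"].tolist()
    hits = calls.loc[calls["group"] == "1", "gene_id"].tolist()
    if not hits:
        log.warning("empty AEU hit list; hypergeometric table will be empty")
        hyper = pd.DataFrame()
    else:
        hyper = enrichment.hypergeom_enrich(hits, background, gene_sets)
    assoc = pd.Series(
        (results["b"] / results["se_b"]).to_numpy(),
        index=results["gene_id"].to_numpy(),
    )
    signed = enrichment.sign_partition_enrich(assoc, gene_sets)
    hyper.to_csv(out_dir / "enrichment_hypergeom.tsv", sep="\t", index=False,
                 float_format="%.4g")
    signed.to_csv(out_dir / "enrichment_signed.tsv", sep="\t", index=False,
                  float_format="%.4g")
    return {"hypergeom": hyper, "signed": signed}
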