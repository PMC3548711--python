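"""Decision logic: FDR adjustment, consistency screens, gene classification.

A multi-exon gene is called group 1 (alternative exon usage, AEU) when
three kinds of evidence coincide: (a) the survival-by-exon variance
component is significant, (b) more than two consecutive exons are
consistently over- or under-expressed per survival month, and (c) those
exons' fold changes per month are outside the [fc_low, fc_high] band.
Multi-exon genes with a significant overall survival slope but no AEU are
group 2; single-exon genes with a significant slope (their own FDR family)
are group 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_FDR_MULTI",
    "DEFAULT_FDR_SINGLE",
    "DEFAULT_FC_LOW",
    "DEFAULT_FC_HIGH",
    "DEFAULT_MIN_RUN",
    "DEFAULT_WINDOW",
    "Run",
    "bh_fdr",
    "moving_average",
    "consistent_run",
    "classify_genes",
    "write_bed",
]

DEFAULT_ALPHA = 5.0e-4
DEFAULT_FDR_MULTI = 0.05
DEFAULT_FDR_SINGLE = 0.1
DEFAULT_FC_LOW = 0.995
DEFAULT_FC_HIGH = 1.005
DEFAULT_MIN_RUN = 3  # "more than two consecutive exons"
DEFAULT_WINDOW = 10


@dataclass(frozen=True)
class Run:
    """A maximal run of consecutive extreme exons (1-based start order)."""

    start: int
    length: int
    sign: str  # "over" | "under"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moving_average(values, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving mean over exon order, truncating at the gene's ends.

    For even windows the extra position extends to the right.  Output has
    the same length as the input; ``window`` is capped at the exon count.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("moving_average of empty input")
    if window < 1:
        raise ValidationError("window must be >= 1")
    w = min(window, x.size)
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - (w - 1) // 2)
        hi = min(x.size, i + w // 2 + 1)
        out[i] = x[lo:hi].mean()
    return out


def consistent_run(
    fold_changes,
    fc_low: float = DEFAULT_FC_LOW,
    fc_high: float = DEFAULT_FC_HIGH,
    min_run: int = DEFAULT_MIN_RUN,
) -> Run | None:
    """Longest run of consecutive exons all over- or all under-expressed.

    ``fold_changes`` must be ordered by exon ``order``.  A run is over when
    every fold change exceeds ``fc_high``, under when every one is below
    ``fc_low``.  Returns the longest maximal run (first on ties) iff its
    length reaches ``min_run``, else None.
    """
    fc = np.asarray(fold_changes, dtype=float)
    best: Run | None = None
    i = 0
    while i < fc.size:
        if fc[i] > fc_high:
            sign, ok = "over", lambda v: v > fc_high
        elif fc[i] < fc_low:
            sign, ok = "under", lambda v: v < fc_low
        else:
            i += 1
            continue
        j = i
        while j < fc.size and ok(fc[j]):
            j += 1
        if best is None or (j - i) > best.length:
            best = Run(start=i + 1, length=j - i, sign=sign)
        i = j
    if best is not None and best.length >= min_run:
        return best
    return None


def classify_genes(
    results: pd.DataFrame,
    slopes: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fdr_multi: float = DEFAULT_FDR_MULTI,
    fdr_single: float = DEFAULT_FDR_SINGLE,
    fc_low: float = DEFAULT_FC_LOW,
    fc_high: float = DEFAULT_FC_HIGH,
    min_run: int = DEFAULT_MIN_RUN,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Assign every analyzed gene to group 1/2/3 or none.

    ``results`` needs columns gene_id, n_exons, p_aeu (NaN for single-exon
    genes), p_survival; ``slopes`` needs gene_id, order, fold_change.
    Multi-exon AEU p-values and single-exon survival p-values form separate
    FDR families.  Returns one row per gene with the p/FDR values, the
    three evidence flags, the run descriptor and the group label.
    """
    res = results.copy().reset_index(drop=True)
    multi = res["n_exons"] > 1
    single = ~multi

    res["fdr_aeu"] = np.nan
    res.loc[multi, "fdr_aeu"] = bh_fdr(res.loc[multi, "p_aeu"].to_numpy())
    res["fdr_survival"] = np.nan
    res.loc[multi, "fdr_survival"] = bh_fdr(res.loc[multi, "p_survival"].to_numpy())
    res.loc[single, "fdr_survival"] = bh_fdr(res.loc[single, "p_survival"].to_numpy())

    rows = []
    fc_by_gene = {
        g: df.sort_values("order")["fold_change"].to_numpy()
        for g, df in slopes.groupby("gene_id")
    }
    for rec in res.itertuples(index=False):
        gene = rec.gene_id
        is_multi = rec.n_exons > 1
        group = "none"
        sig_aeu = False
        run = None
        trend = None
        if is_multi:
            sig_aeu = bool(rec.p_aeu < alpha or rec.fdr_aeu < fdr_multi)
            fc = fc_by_gene.get(gene)
            if fc is not None:
                run = consistent_run(fc, fc_low=fc_low, fc_high=fc_high, min_run=min_run)
                trend = moving_average(fc, window=window)
            sig_surv = bool(rec.p_survival < alpha or rec.fdr_survival < fdr_multi)
            if sig_aeu and run is not None:
                group = "1"
            elif sig_surv:
                group = "2"
        else:
            if rec.p_survival < alpha or rec.fdr_survival < fdr_single:
                group = "3"
        rows.append(
            {
                "gene_id": gene,
                "n_exons": rec.n_exons,
                "group": group,
                "p_aeu": rec.p_aeu,
                "fdr_aeu": rec.fdr_aeu,
                "p_survival": rec.p_survival,
                "fdr_survival": rec.fdr_survival,
                "significant": sig_aeu,
                "consistent_run": run is not None,
                "fc_extreme": run is not None,
                "run_start": run.start if run else pd.NA,
                "run_length": run.length if run else pd.NA,
                "run_sign": run.sign if run else pd.NA,
                "ma_trend": ";".join(f"{v:.4f}" for v in trend) if trend is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def write_bed(
    calls: pd.DataFrame,
    slopes: pd.DataFrame,
    annotation: pd.DataFrame,
    path,
    alpha: float = DEFAULT_ALPHA,
) -> None:
    """BED track of significant exons of called genes for browser inspection.

    score = -10*log10(p_exon) capped at 1000, name = gene:exon.
    """
    called = set(calls.loc[calls["group"] != "none", "gene_id"])
    ann = annotation.set_index("exon_id")
    lines = []
    for rec in slopes.itertuples(index=False):
        if rec.gene_id not in called or not rec.p_exon < alpha:
            continue
        a = ann.loc[rec.exon_id]
        score = int(min(1000, round(-10.0 * np.log10(max(rec.p_exon, 1e-100)))))
        lines.append(
            f"{a['chrom']}\t{a['start']}\t{a['end']}\t"
            f"{rec.gene_id}:{rec.exon_id}\t{score}\t{a['strand']}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
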