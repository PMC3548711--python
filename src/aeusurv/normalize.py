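"""Intensity normalization and probe→exon summarization.

The preprocessing chain for exon-array intensities is: log2 transform (if
raw), quantile normalization across samples at the probe level, then a
one-step Tukey biweight collapse of the probes within each exon to a single
exon-level expression value.  Genes whose annotation mixes strands are
reduced to the majority strand before modeling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExonExpressionSet, ProbeMatrix, ValidationError, validate_annotation

__all__ = [
    "quantile_normalize",
    "tukey_biweight",
    "collapse_probes_to_exons",
    "majority_strand_filter",
]

log = logging.getLogger(__name__)

TUKEY_C = 5.0
TUKEY_EPS = 1e-4


def quantile_normalize(matrix: ProbeMatrix) -> ProbeMatrix:
    """Force every sample column onto the common mean distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; ranks within each column are preserved (ties
    broken by position, which is immaterial because tied values map to
    adjacent reference quantiles of equal rank spacing).
    """
    arr = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite values in quantile normalization input")
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        out[order[:, j], j] = ref[rows]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ProbeMatrix(values=values, exon_id=matrix.exon_id, scale=matrix.scale)


def tukey_biweight(values, c: float = TUKEY_C, eps: float = TUKEY_EPS) -> float:
    """One-step Tukey biweight location of ``values``.

    Center = median, scale = median absolute deviation; observations further
    than ``c * MAD + eps`` from the median get zero weight, closer ones the
    redescending weight (1 - u^2)^2.  With constant data (MAD = 0) the
    median is returned.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("tukey_biweight of empty input")
    if not np.all(np.isfinite(x)):
        raise ValidationError("tukey_biweight requires finite input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def collapse_probes_to_exons(
    matrix: ProbeMatrix,
    annotation: pd.DataFrame,
    c: float = TUKEY_C,
    eps: float = TUKEY_EPS,
) -> ExonExpressionSet:
    """Summarize probe intensities into one log2 value per exon per sample.

    Raw-scale input is log2 transformed first.  Probes whose ``exon_id`` is
    absent from the annotation are dropped with a logged count.
    """
    validate_annotation(annotation)
    values = matrix.values
    if matrix.scale == "raw":
        values = np.log2(values)
    known = set(annotation["exon_id"])
    keep = matrix.exon_id.isin(known)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d probe(s) with no exon annotation", n_dropped)
    values = values.loc[keep.to_numpy()]
    exon_of = matrix.exon_id[keep.to_numpy()]

    collapsed = values.groupby(exon_of.to_numpy()).agg(
        lambda col: tukey_biweight(col.to_numpy(), c=c, eps=eps)
    )
    # keep annotation order for exons that actually carry probes
    ordered = [e for e in annotation["exon_id"] if e in collapsed.index]
    collapsed = collapsed.loc[ordered]
    ann = annotation[annotation["exon_id"].isin(collapsed.index)].reset_index(drop=True)
    collapsed.index.name = "exon_id"
    return ExonExpressionSet(values=collapsed, annotation=ann)


def majority_strand_filter(gene_exons: pd.DataFrame) -> pd.DataFrame:
    """Keep only the exons of a gene on its most frequent strand.

    ``order`` is re-ranked contiguously (1..n, ascending genomic start) on
    the surviving exons.  On an exact tie the "+" strand is kept and a
    warning logged.
    """
    if len(gene_exons) == 0:
        raise ValidationError("majority_strand_filter of empty annotation")
    counts = gene_exons["strand"].value_counts()
    n_plus = int(counts.get("+", 0))
    n_minus = int(counts.get("-", 0))
    if n_plus == n_minus and n_minus > 0:
        log.warning(
            "gene %s: strand tie (%d vs %d), keeping '+'",
            gene_exons["gene_id"].iloc[0], n_plus, n_minus,
        )
        strand = "+"
    else:
        strand = "+" if n_plus >= n_minus else "-"
    out = gene_exons[gene_exons["strand"] == strand].copy()
    out = out.sort_values("start").reset_index(drop=True)
    out["order"] = np.arange(1, len(out) + 1)
    return out
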