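"""Tabular input/output for exon-level expression analysis.

All on-disk formats are plain TSV:

* expression: header row of sample ids, first columns ``probe_id`` and
  ``exon_id`` (probe level) or ``exon_id`` alone (exon level), remaining
  columns numeric intensities;
* annotation: ``gene_id, exon_id, chrom, start, end, strand, order`` with
  0-based half-open coordinates;
* clinical: ``patient_id, gender, race, therapy, survival_months``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ProbeMatrix",
    "ExonExpressionSet",
    "GENDER_LEVELS",
    "RACE_LEVELS",
    "THERAPY_LEVELS",
    "read_clinical",
    "read_annotation",
    "read_probe_matrix",
    "read_exon_expression",
    "write_exon_expression",
    "validate_annotation",
    "validate_clinical",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


GENDER_LEVELS = ("female", "male")
RACE_LEVELS = ("other", "caucasian")
THERAPY_LEVELS = ("NONE", "CRT", "CRnT", "OTHER", "R")

ANNOTATION_COLUMNS = ["gene_id", "exon_id", "chrom", "start", "end", "strand", "order"]
CLINICAL_COLUMNS = ["patient_id", "gender", "race", "therapy", "survival_months"]


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus the probe→exon map.

    ``values`` is indexed by probe_id with one numeric column per sample;
    ``exon_id`` aligns with the index.  ``scale`` is ``"raw"`` (positive
    intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    exon_id: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValidationError("empty probe matrix")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite probe intensities")
        if self.scale == "raw" and not np.all(arr > 0):
            raise ValidationError("raw intensities must be positive")
        if not self.exon_id.index.equals(self.values.index):
            raise ValidationError("exon_id index does not match probe matrix index")


@dataclass
class ExonExpressionSet:
    """Exon-level log2 expression with its annotation.

    ``values``: rows indexed by exon_id, columns are patient ids.
    ``annotation``: one row per exon with gene/coordinate metadata.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValidationError("non-finite expression values")
        missing = set(self.values.index) - set(self.annotation["exon_id"])
        if missing:
            raise ValidationError(f"exons without annotation: {sorted(missing)[:5]}")

    def gene_slice(self, gene_id: str) -> pd.DataFrame:
        """Expression rows of one gene, ordered by the exon ``order`` rank."""
        ann = self.annotation[self.annotation["gene_id"] == gene_id]
        ann = ann.sort_values("order")
        return self.values.loc[ann["exon_id"].tolist()]

    @property
    def gene_ids(self) -> list[str]:
        return self.annotation["gene_id"].drop_duplicates().tolist()


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    for col, levels in (
        ("gender", GENDER_LEVELS),
        ("race", RACE_LEVELS),
        ("therapy", THERAPY_LEVELS),
    ):
        bad = set(clinical[col]) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
    surv = clinical["survival_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(surv)) or not np.all(surv > 0):
        raise ValidationError("survival_months must be finite and positive")
    if clinical["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient ids")
    return clinical


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if (annotation["start"].to_numpy() >= annotation["end"].to_numpy()).any():
        raise ValidationError("annotation requires start < end")
    bad = set(annotation["strand"]) - {"+", "-"}
    if bad:
        raise ValidationError(f"bad strand value(s): {sorted(bad)}")
    if annotation["exon_id"].duplicated().any():
        raise ValidationError("duplicate exon ids")
    return annotation


def read_clinical(path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep="\t", dtype={"patient_id": str}))


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(
        pd.read_csv(path, sep="\t", dtype={"gene_id": str, "exon_id": str, "chrom": str})
    )


def read_probe_matrix(path, scale: str = "log2") -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "exon_id": str})
    if df.columns[0] != "probe_id" or df.columns[1] != "exon_id":
        raise ValidationError("probe matrix must start with probe_id, exon_id columns")
    df = df.set_index("probe_id")
    return ProbeMatrix(values=df.drop(columns="exon_id"), exon_id=df["exon_id"], scale=scale)


def read_exon_expression(path, annotation: pd.DataFrame) -> ExonExpressionSet:
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str}).set_index("exon_id")
    return ExonExpressionSet(values=df, annotation=annotation)


def write_exon_expression(eset: ExonExpressionSet, path) -> None:
    eset.values.rename_axis("exon_id").to_csv(path, sep="\t")
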