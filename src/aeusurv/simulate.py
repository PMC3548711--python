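"""Synthetic cohorts and exon expression with known ground truth.

The generator emulates the study design the model targets: a training
cohort of 250 glioblastoma patients and a validation cohort of 78, with
categorical covariates drawn at the observed frequencies (62.4% male,
88.8% caucasian; therapy R 25.2%, CRT 10.8%, CRnT 39.6%, OTHER 14.0%,
NONE 10.4%), survival in months drawn log-normally around the cohort
medians (17.46 training, 15.02 validation) and truncated to the observed
ranges.  Expression is generated exactly from the hierarchical model:

    y_mn = mu + gender + race + therapy + b*S_n + X_m + t_m*S_n + P_n + e_mn

with X_m ~ N(0, s2_exon), P_n ~ N(0, s2_patient), e ~ N(0, s2_resid) and
slope deviations t_m either i.i.d. N(0, s2_slope) or a fixed "cassette"
pattern (a constant deviation over a consecutive exon run, zero
elsewhere).  Every gene draws from its own RNG stream keyed by
(seed, gene_id), so simulation is order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExonExpressionSet, THERAPY_LEVELS

__all__ = [
    "CohortConfig",
    "GeneConfig",
    "SimConfig",
    "SimulatedData",
    "TRAIN_COHORT",
    "VALID_COHORT",
    "simulate_cohort",
    "simulate_gene",
    "simulate_dataset",
    "sample_n_exons",
    "standard_roster",
]

# observed cohort covariate frequencies
MALE_FREQ = 0.624
CAUCASIAN_FREQ = 0.888
THERAPY_FREQS = {"R": 0.252, "CRT": 0.108, "CRnT": 0.396, "OTHER": 0.140, "NONE": 0.104}

# exon-count mixture: genes with 1 / 2-24 / 25-49 / >=50 exons
EXON_BIN_COUNTS = (2857, 20288, 1965, 293)
EXON_BINS = ((1, 1), (2, 24), (25, 49), (50, 191))

DEFAULT_FIXED_EFFECTS = {
    "male": 0.10,
    "caucasian": -0.05,
    "therapy": {"NONE": 0.0, "CRT": 0.20, "CRnT": 0.15, "OTHER": 0.05, "R": 0.10},
}


@dataclass(frozen=True)
class CohortConfig:
    """Covariate and survival distribution of one cohort."""

    n_patients: int
    median_survival: float
    survival_sigma: float = 1.0  # log-scale SD of the log-normal
    survival_bounds: tuple[float, float] = (0.16, 128.0)
    male_freq: float = MALE_FREQ
    caucasian_freq: float = CAUCASIAN_FREQ
    therapy_freqs: dict[str, float] = field(default_factory=lambda: dict(THERAPY_FREQS))


TRAIN_COHORT = CohortConfig(n_patients=250, median_survival=17.46,
                            survival_bounds=(0.16, 128.0))
VALID_COHORT = CohortConfig(n_patients=78, median_survival=15.02,
                            survival_bounds=(0.10, 77.57))


@dataclass(frozen=True)
class GeneConfig:
    """Generative truth for one gene."""

    gene_id: str
    n_exons: int
    group: str = "null"  # "aeu" | "exon_common" | "single" | "null"
    mu: float = 7.0
    b: float = 0.0  # overall slope, log2 units per month
    sigma2_exon: float = 0.25
    sigma2_slope: float = 0.0  # variance of i.i.d. slope deviations
    sigma2_patient: float = 0.25
    sigma2_resid: float = 0.25
    cassette: tuple[int, int, float] | None = None  # (start order, length, deviation)
    fixed_effects: dict = field(
        default_factory=lambda: {
            "male": DEFAULT_FIXED_EFFECTS["male"],
            "caucasian": DEFAULT_FIXED_EFFECTS["caucasian"],
            "therapy": dict(DEFAULT_FIXED_EFFECTS["therapy"]),
        }
    )


@dataclass(frozen=True)
class SimConfig:
    """Full synthetic-study configuration."""

    roster: tuple[GeneConfig, ...]
    seed: int = 0
    train: CohortConfig = TRAIN_COHORT
    valid: CohortConfig = VALID_COHORT
    minority_strand_fraction: float = 0.0


@dataclass
class SimulatedData:
    train_expression: ExonExpressionSet
    train_clinical: pd.DataFrame
    valid_expression: ExonExpressionSet
    valid_clinical: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame


def _stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


def simulate_cohort(config: CohortConfig, seed: int, prefix: str = "P") -> pd.DataFrame:
    """Draw one clinical table; byte-identical under a fixed seed."""
    rng = _stream(seed, f"cohort:{prefix}")
    n = config.n_patients
    gender = np.where(rng.random(n) < config.male_freq, "male", "female")
    race = np.where(rng.random(n) < config.caucasian_freq, "caucasian", "other")
    levels = list(config.therapy_freqs)
    probs = np.array([config.therapy_freqs[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    therapy = rng.choice(levels, size=n, p=probs)
    lo, hi = config.survival_bounds
    mu_ln = np.log(config.median_survival)
    surv = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(mean=mu_ln, sigma=config.survival_sigma, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        surv[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return pd.DataFrame(
        {
            "patient_id": [f"{prefix}{i:04d}" for i in range(n)],
            "gender": gender,
            "race": race,
            "therapy": therapy,
            "survival_months": surv,
        }
    )


def _true_slope_devs(cfg: GeneConfig, rng: np.random.Generator) -> np.ndarray:
    dev = np.zeros(cfg.n_exons)
    if cfg.cassette is not None:
        start, length, size = cfg.cassette
        if not (1 <= start and start + length - 1 <= cfg.n_exons):
            raise ValueError(f"cassette out of range for gene {cfg.gene_id}")
        dev[start - 1:start - 1 + length] = size
    elif cfg.sigma2_slope > 0:
        dev = rng.normal(0.0, np.sqrt(cfg.sigma2_slope), size=cfg.n_exons)
    return dev


def simulate_gene(
    clinical: pd.DataFrame, cfg: GeneConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Expression slice (exons x patients) plus the truth record for one gene.

    Patient effects and residuals are cohort-specific draws; exon-level
    effects (intercept deviations and slope deviations) are drawn once per
    gene so that training and validation cohorts simulated from the same
    seed share the same gene-level truth.
    """
    gene_rng = _stream(seed, f"gene:{cfg.gene_id}")
    X_m = (
        gene_rng.normal(0.0, np.sqrt(cfg.sigma2_exon), size=cfg.n_exons)
        if cfg.sigma2_exon > 0 else np.zeros(cfg.n_exons)
    )
    dev = _true_slope_devs(cfg, gene_rng)

    cohort_rng = _stream(seed, f"gene:{cfg.gene_id}:cohort:{clinical['patient_id'].iloc[0]}")
    n_pat = len(clinical)
    S = clinical["survival_months"].to_numpy(float)
    fe = cfg.fixed_effects
    fixed = (
        cfg.mu
        + np.where(clinical["gender"] == "male", fe.get("male", 0.0), 0.0)
        + np.where(clinical["race"] == "caucasian", fe.get("caucasian", 0.0), 0.0)
        + np.array([fe.get("therapy", {}).get(t, 0.0) for t in clinical["therapy"]])
        + cfg.b * S
    )
    P_n = (
        cohort_rng.normal(0.0, np.sqrt(cfg.sigma2_patient), size=n_pat)
        if cfg.sigma2_patient > 0 else np.zeros(n_pat)
    )
    e = cohort_rng.normal(0.0, np.sqrt(cfg.sigma2_resid), size=(cfg.n_exons, n_pat))
    y = fixed[None, :] + X_m[:, None] + dev[:, None] * S[None, :] + P_n[None, :] + e
    expr = pd.DataFrame(
        y,
        index=[f"{cfg.gene_id}_e{m + 1}" for m in range(cfg.n_exons)],
        columns=clinical["patient_id"].to_numpy(),
    )
    truth = {
        "gene_id": cfg.gene_id,
        "group": cfg.group,
        "n_exons": cfg.n_exons,
        "b": cfg.b,
        "sigma2_exon": cfg.sigma2_exon,
        "sigma2_slope": cfg.sigma2_slope,
        "sigma2_patient": cfg.sigma2_patient,
        "sigma2_resid": cfg.sigma2_resid,
        "cassette_start": cfg.cassette[0] if cfg.cassette else pd.NA,
        "cassette_length": cfg.cassette[1] if cfg.cassette else pd.NA,
        "cassette_dev": cfg.cassette[2] if cfg.cassette else pd.NA,
        "true_slopes": ";".join(f"{cfg.b + d:.6g}" for d in dev),
    }
    return expr, truth


def _gene_annotation(
    cfg: GeneConfig, gene_index: int, minority_fraction: float, seed: int
) -> pd.DataFrame:
    """Monotone genomic coordinates; optional decoy minority-strand exons."""
    chrom = f"chr{(gene_index % 22) + 1}"
    gbase = 1_000_000 + 500_000 * gene_index
    rows = []
    for m in range(cfg.n_exons):
        start = gbase + m * 1150
        rows.append(
            {
                "gene_id": cfg.gene_id,
                "exon_id": f"{cfg.gene_id}_e{m + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + 150,
                "strand": "+",
                "order": m + 1,
            }
        )
    n_decoy = int(round(minority_fraction * cfg.n_exons))
    n_decoy = min(n_decoy, cfg.n_exons - 1)  # minority must stay the minority
    for d in range(n_decoy):
        start = gbase + (cfg.n_exons + d) * 1150
        rows.append(
            {
                "gene_id": cfg.gene_id,
                "exon_id": f"{cfg.gene_id}_anti{d + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + 150,
                "strand": "-",
                "order": cfg.n_exons + d + 1,
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Generate the full paired-cohort study with annotation and truth."""
    train_clin = simulate_cohort(config.train, config.seed, prefix="T")
    valid_clin = simulate_cohort(config.valid, config.seed, prefix="V")

    train_parts, valid_parts, truth_rows, ann_parts = [], [], [], []
    for gi, cfg in enumerate(config.roster):
        expr_t, truth = simulate_gene(train_clin, cfg, config.seed)
        expr_v, _ = simulate_gene(valid_clin, cfg, config.seed)
        ann = _gene_annotation(cfg, gi, config.minority_strand_fraction, config.seed)
        decoys = ann[ann["strand"] == "-"]
        if len(decoys):
            rng = _stream(config.seed, f"decoy:{cfg.gene_id}")
            tot = cfg.sigma2_exon + cfg.sigma2_patient + cfg.sigma2_resid
            for which, clin, parts in (
                ("T", train_clin, train_parts), ("V", valid_clin, valid_parts)
            ):
                noise = rng.normal(cfg.mu, np.sqrt(max(tot, 1e-12)),
                                   size=(len(decoys), len(clin)))
                parts.append(pd.DataFrame(
                    noise, index=decoys["exon_id"].tolist(),
                    columns=clin["patient_id"].to_numpy(),
                ))
        train_parts.append(expr_t)
        valid_parts.append(expr_v)
        truth_rows.append(truth)
        ann_parts.append(ann)

    annotation = pd.concat(ann_parts, ignore_index=True)
    train = ExonExpressionSet(values=pd.concat(train_parts), annotation=annotation)
    valid = ExonExpressionSet(values=pd.concat(valid_parts), annotation=annotation)
    return SimulatedData(
        train_expression=train,
        train_clinical=train_clin,
        valid_expression=valid,
        valid_clinical=valid_clin,
        annotation=annotation,
        truth=pd.DataFrame(truth_rows),
    )


def sample_n_exons(rng: np.random.Generator) -> int:
    """Exon count drawn from the observed gene-size mixture bins."""
    probs = np.array(EXON_BIN_COUNTS, dtype=float)
    probs /= probs.sum()
    lo, hi = EXON_BINS[rng.choice(len(EXON_BINS), p=probs)]
    return int(rng.integers(lo, hi + 1))


def standard_roster(
    n_aeu: int,
    n_exon_common: int,
    n_single: int,
    n_null: int,
    seed: int = 0,
    n_exons_aeu: int = 10,
    n_exons_common: int = 10,
    n_exons_null: int = 8,
    cassette_dev: float = 0.02,
    cassette_length: int = 3,
    b_common: float = 0.01,
    b_single: float = 0.01,
) -> tuple[GeneConfig, ...]:
    """A labelled gene roster covering the three groups plus nulls.

    AEU genes carry a cassette of ``cassette_length`` consecutive exons with
    slope deviation ``cassette_dev`` (log2/month, alternating sign across
    genes); exon-common genes carry an overall slope ``b_common``; nulls
    have every survival term zero.  Single-exon genes mirror the single-exon
    specification (no exon variance).
    """
    rng = _stream(seed, "roster")
    roster: list[GeneConfig] = []
    for i in range(n_aeu):
        start = int(rng.integers(1, n_exons_aeu - cassette_length + 2))
        sign = 1.0 if i % 2 == 0 else -1.0
        roster.append(GeneConfig(
            gene_id=f"aeu{i:04d}", n_exons=n_exons_aeu, group="aeu",
            cassette=(start, cassette_length, sign * cassette_dev),
        ))
    for i in range(n_exon_common):
        sign = 1.0 if i % 2 == 0 else -1.0
        roster.append(GeneConfig(
            gene_id=f"common{i:04d}", n_exons=n_exons_common, group="exon_common",
            b=sign * b_common,
        ))
    for i in range(n_single):
        sign = 1.0 if i % 2 == 0 else -1.0
        roster.append(GeneConfig(
            gene_id=f"single{i:04d}", n_exons=1, group="single",
            b=sign * b_single, sigma2_exon=0.0,
        ))
    for i in range(n_null):
        roster.append(GeneConfig(
            gene_id=f"null{i:04d}", n_exons=n_exons_null, group="null",
        ))
    return tuple(roster)
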