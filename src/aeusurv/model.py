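"""Per-gene hierarchical mixed model: design, REML fit, tests, BLUPs.

For a gene with exons m = 1..M measured on patients n = 1..N the model of
exon expression y_mn (log2 scale) is

    y_mn = mu + gender + race + therapy + b * S_n + X_m + t_m * S_n + P_n + e_mn

with fixed effects for gender, race, therapy and the survival covariate
S_n (months), and independent Gaussian random effects: exon intercept
deviations X_m ~ N(0, s2_exon), exon-specific survival-slope deviations
t_m ~ N(0, s2_slope), patient effects P_n ~ N(0, s2_patient) and residual
e ~ N(0, s2_resid).  Three nested specifications cover the three gene
classes: the full model above (multi-exon, alternative exon usage), the
model without the slope deviations (multi-exon, exon-independent
association), and a single-exon model with neither exon term (the patient
effect is then absorbed into the residual and the fit reduces to OLS).

Variance components are estimated by REML.  The residual variance is
profiled out analytically and the remaining variance ratios are optimized
under non-negativity bounds, so boundary estimates (a ratio exactly 0) are
attainable — required by the chi-bar-square likelihood-ratio test of
s2_slope = 0.  All per-iteration linear algebra is done on q x q
cross-product matrices (q = total random-effect levels) via the Woodbury
identity, never on the full N_obs x N_obs covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io import (
    GENDER_LEVELS,
    RACE_LEVELS,
    THERAPY_LEVELS,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "AEU_FULL",
    "EXON_COMMON",
    "SINGLE_EXON",
    "DesignBundle",
    "GeneFit",
    "build_design",
    "encode_fixed",
    "fit_reml",
    "test_aeu",
    "test_survival",
    "exon_slopes",
    "fold_change",
]

log = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-10  # variance ratio below this is snapped to the boundary


@dataclass(frozen=True)
class ModelSpec:
    """One of the three nested model specifications."""

    kind: str  # "aeu_full" | "exon_common" | "single_exon"

    @property
    def random_effects(self) -> tuple[str, ...]:
        return {
            "aeu_full": ("exon", "survival_exon", "patient"),
            "exon_common": ("exon", "patient"),
            "single_exon": (),
        }[self.kind]


AEU_FULL = ModelSpec("aeu_full")
EXON_COMMON = ModelSpec("exon_common")
SINGLE_EXON = ModelSpec("single_exon")


@dataclass
class DesignBundle:
    """Response, fixed design and random-effect incidence blocks for a gene.

    Rows are stacked exon-major: observation index = m * n_patients + n.
    """

    y: np.ndarray
    X: np.ndarray
    Z_blocks: dict[str, np.ndarray]
    fixed_names: list[str]
    exon_ids: list[str]
    patient_ids: list[str]
    survival: np.ndarray
    spec: ModelSpec
    gene_id: str = ""

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)


@dataclass
class GeneFit:
    """REML fit of one gene under one model specification."""

    gene_id: str
    spec: ModelSpec
    beta: pd.Series
    vcov_beta: pd.DataFrame
    components: dict[str, float]  # per-block variances plus "resid"
    loglik: float  # restricted log-likelihood
    converged: bool
    n_obs: int
    n_exons: int
    exon_ids: list[str]
    survival_col: str = "survival"
    blups: dict[str, pd.Series] = field(default_factory=dict)
    blup_predvar: dict[str, np.ndarray] = field(default_factory=dict)
    slope_blup_cov_b: np.ndarray | None = None  # cov(b_hat, slope BLUP error)
    components_se: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def se_beta(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov_beta.to_numpy())), index=self.beta.index)

    @property
    def sigma2_slope(self) -> float:
        return self.components.get("survival_exon", 0.0)


# ---------------------------------------------------------------------------
# design construction


def encode_fixed(
    clinical: pd.DataFrame,
    center_survival: bool = False,
    keep_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-patient fixed-effect design (intercept, contrasts, survival).

    Reference levels: female, other race, NONE therapy.  A contrast column
    whose level is absent from ``clinical`` is dropped with a warning so the
    design stays full rank; pass ``keep_columns`` (from a training fit) to
    demand a specific column set instead — an observation needing a dropped
    column then raises, naming the level.
    """
    for col, levels in (
        ("gender", GENDER_LEVELS),
        ("race", RACE_LEVELS),
        ("therapy", THERAPY_LEVELS),
    ):
        bad = set(clinical[col]) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(clinical))}
    cols["gender[male]"] = (clinical["gender"] == "male").to_numpy(float)
    cols["race[caucasian]"] = (clinical["race"] == "caucasian").to_numpy(float)
    for lev in THERAPY_LEVELS[1:]:
        cols[f"therapy[{lev}]"] = (clinical["therapy"] == lev).to_numpy(float)
    surv = clinical["survival_months"].to_numpy(float)
    cols["survival"] = surv - surv.mean() if center_survival else surv

    X = pd.DataFrame(cols, index=clinical["patient_id"].to_numpy())
    if keep_columns is not None:
        needed = [c for c in keep_columns if c not in X.columns]
        if needed:
            raise ValidationError(f"missing design columns {needed}")
        extra = [
            c for c in X.columns
            if c not in keep_columns and c != "intercept" and X[c].to_numpy().any()
        ]
        if extra:
            raise ValidationError(
                f"covariate level(s) unseen in training: {extra}"
            )
        return X[keep_columns]

    drop = [
        c for c in X.columns
        if c != "intercept" and (X[c].to_numpy() == X[c].to_numpy()[0]).all()
    ]
    if drop:
        log.warning("dropping constant fixed-effect column(s): %s", drop)
        X = X.drop(columns=drop)
    return X


def build_design(
    gene_expr: pd.DataFrame,
    clinical: pd.DataFrame,
    spec: ModelSpec,
    center_survival: bool = False,
    gene_id: str = "",
) -> DesignBundle:
    """Assemble the stacked per-gene design.

    ``gene_expr``: exons (rows, ordered by genomic rank) x patients; columns
    must match the clinical table's patients.
    """
    patients = clinical["patient_id"].tolist()
    if list(gene_expr.columns) != patients:
        if set(gene_expr.columns) != set(patients):
            raise ValidationError("expression columns do not match clinical patients")
        gene_expr = gene_expr[patients]
    n_pat = len(patients)
    n_exon = gene_expr.shape[0]
    if n_pat < 2:
        raise ValidationError("need at least 2 patients")
    if spec.kind == "single_exon" and n_exon != 1:
        raise ValidationError("single_exon spec requires exactly 1 exon")
    if spec.kind != "single_exon" and n_exon < 2:
        raise ValidationError(f"{spec.kind} spec requires >= 2 exons")

    y = gene_expr.to_numpy(dtype=float).ravel(order="C")
    Xp = encode_fixed(clinical, center_survival=center_survival)
    X = np.tile(Xp.to_numpy(dtype=float), (n_exon, 1))
    survival = Xp["survival"].to_numpy(dtype=float)

    Z_blocks: dict[str, np.ndarray] = {}
    if "exon" in spec.random_effects:
        Z_blocks["exon"] = np.kron(np.eye(n_exon), np.ones((n_pat, 1)))
    if "survival_exon" in spec.random_effects:
        Z_blocks["survival_exon"] = np.kron(np.eye(n_exon), survival[:, None])
    if "patient" in spec.random_effects:
        Z_blocks["patient"] = np.tile(np.eye(n_pat), (n_exon, 1))

    return DesignBundle(
        y=y,
        X=X,
        Z_blocks=Z_blocks,
        fixed_names=list(Xp.columns),
        exon_ids=list(gene_expr.index),
        patient_ids=patients,
        survival=survival,
        spec=spec,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# REML machinery


class _REMLProblem:
    """Profiled REML objective on variance ratios gamma_r = s2_r / s2_resid.

    Everything is precomputed as cross-products so one objective evaluation
    costs O(q^3) with q = sum of random-effect levels.
    """

    def __init__(self, design: DesignBundle):
        y, X = design.y, design.X
        self.N = y.shape[0]
        self.p = X.shape[1]
        if np.linalg.matrix_rank(X) < self.p:
            raise ValidationError("singular fixed-effect design")
        if self.N - self.p <= 0:
            raise ValidationError("no residual degrees of freedom")
        self.block_names = list(design.Z_blocks.keys())
        self.block_sizes = [design.Z_blocks[b].shape[1] for b in self.block_names]
        if self.block_names:
            Z = np.hstack([design.Z_blocks[b] for b in self.block_names])
        else:
            Z = np.zeros((self.N, 0))
        self.q = Z.shape[1]
        self.col_block = np.repeat(np.arange(len(self.block_names)), self.block_sizes)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.design = design

    # -- core linear algebra ------------------------------------------------

    def _pieces(self, gamma: np.ndarray):
        """Cholesky pieces of the scaled covariance Vtilde = I + Z G Z'."""
        s = np.sqrt(gamma[self.col_block]) if self.q else np.zeros(0)
        A = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        cA = linalg.cho_factor(A, lower=True, check_finite=False)
        WtX = s[:, None] * self.ZtX
        Wty = s * self.Zty
        AiWtX = linalg.cho_solve(cA, WtX, check_finite=False)
        AiWty = linalg.cho_solve(cA, Wty, check_finite=False)
        XtVinvX = self.XtX - WtX.T @ AiWtX
        XtVinvy = self.Xty - WtX.T @ AiWty
        ytVinvy = self.yty - Wty @ AiWty
        cB = linalg.cho_factor(XtVinvX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cB, XtVinvy, check_finite=False)
        r2 = float(ytVinvy - XtVinvy @ beta)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cA[0])))) if self.q else 0.0
        logdetXtVinvX = 2.0 * float(np.sum(np.log(np.diag(cB[0]))))
        return beta, r2, logdetV, logdetXtVinvX, (cA, s, cB, XtVinvX)

    def m2ll_profiled(self, gamma: np.ndarray) -> float:
        """-2 * restricted log-likelihood with s2_resid at its maximizer."""
        try:
            _, r2, ldV, ldX, _ = self._pieces(gamma)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return np.inf
        df = self.N - self.p
        if r2 <= 0:
            return np.inf
        s2e = r2 / df
        return df * np.log(s2e) + ldV + ldX + df + df * np.log(2.0 * np.pi)

    def m2ll_and_grad(self, gamma: np.ndarray) -> tuple[float, np.ndarray]:
        """Profiled objective and its analytic gradient in gamma.

        dF/dgamma_r = tr(P Z_r Z_r') - df * ||Z_r' P y||^2 / r2 with P the
        REML projection in the scaled (Vtilde) metric.
        """
        k = len(self.block_names)
        try:
            s = np.sqrt(gamma[self.col_block])
            A = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
            cA = linalg.cho_factor(A, lower=True, check_finite=False)
            SZtZ = s[:, None] * self.ZtZ  # = W' Z
            AiSZtZ = linalg.cho_solve(cA, SZtZ, check_finite=False)
            T1 = self.ZtZ - SZtZ.T @ AiSZtZ  # Z' Vtilde^-1 Z
            WtX = s[:, None] * self.ZtX
            Wty = s * self.Zty
            AiWtX = linalg.cho_solve(cA, WtX, check_finite=False)
            AiWty = linalg.cho_solve(cA, Wty, check_finite=False)
            U = self.ZtX - SZtZ.T @ AiWtX  # Z' Vtilde^-1 X
            w = self.Zty - SZtZ.T @ AiWty  # Z' Vtilde^-1 y
            B = self.XtX - WtX.T @ AiWtX
            cB = linalg.cho_factor(B, lower=True, check_finite=False)
            XtVinvy = self.Xty - WtX.T @ AiWty
            beta = linalg.cho_solve(cB, XtVinvy, check_finite=False)
            r2 = float(self.yty - Wty @ AiWty - XtVinvy @ beta)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return np.inf, np.zeros(k)
        df = self.N - self.p
        if r2 <= 0:
            return np.inf, np.zeros(k)
        ldV = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
        ldX = 2.0 * float(np.sum(np.log(np.diag(cB[0]))))
        F = df * np.log(r2 / df) + ldV + ldX + df + df * np.log(2.0 * np.pi)

        v = w - U @ beta  # Z' P y
        BiUt = linalg.cho_solve(cB, U.T, check_finite=False)
        diag_proj = np.einsum("ij,ji->i", U, BiUt)
        per_col = (np.diag(T1) - diag_proj) - df * v**2 / r2
        grad = np.array([
            per_col[self.col_block == i].sum() for i in range(k)
        ])
        return float(F), grad

    def m2ll_at(self, sigma2: np.ndarray, sigma2_resid: float) -> float:
        """-2 * restricted log-likelihood at explicit variance components."""
        gamma = np.asarray(sigma2, dtype=float) / sigma2_resid
        _, r2, ldV, ldX, _ = self._pieces(gamma)
        df = self.N - self.p
        return (
            df * np.log(sigma2_resid) + ldV + ldX + r2 / sigma2_resid
            + df * np.log(2.0 * np.pi)
        )

    # -- optimization -------------------------------------------------------

    def _starts(self, extra: list[np.ndarray] | None) -> list[np.ndarray]:
        k = len(self.block_names)
        starts = [np.full(k, 1.0), np.full(k, 0.1)]
        if extra:
            starts.extend(extra)
        return starts

    def _newton_polish(self, gamma: np.ndarray, max_steps: int = 12) -> np.ndarray:
        """Sharpen the optimum with projected Newton steps on the analytic
        gradient (Hessian by forward differences of the gradient)."""
        k = gamma.size
        f0, g0 = self.m2ll_and_grad(gamma)
        if not np.isfinite(f0):
            return gamma
        for _ in range(max_steps):
            free = (gamma > _BOUNDARY_TOL) | (g0 < 0)
            idx = np.where(free)[0]
            if idx.size == 0 or np.max(np.abs(g0[idx])) < 1e-11:
                break
            H = np.zeros((idx.size, idx.size))
            h = 1e-7 * np.maximum(gamma[idx], 1e-3)
            for a, i in enumerate(idx):
                gp = gamma.copy()
                gp[i] += h[a]
                _, gi = self.m2ll_and_grad(gp)
                H[:, a] = (gi[idx] - g0[idx]) / h[a]
            H = 0.5 * (H + H.T)
            try:
                step = np.linalg.solve(H, g0[idx])
            except np.linalg.LinAlgError:
                break
            trial = gamma.copy()
            trial[idx] = np.maximum(trial[idx] - step, 0.0)
            f1, g1 = self.m2ll_and_grad(trial)
            if not np.isfinite(f1) or f1 > f0 + 1e-10:
                break
            gamma, f0, g0 = trial, f1, g1
        return gamma

    def fit(
        self,
        starts: list[np.ndarray] | None = None,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        k = len(self.block_names)
        if k == 0:
            gamma = np.zeros(0)
            converged, message = True, "OLS (no random effects)"
        else:
            best = None
            for x0 in self._starts(starts):
                res = optimize.minimize(
                    self.m2ll_and_grad,
                    np.clip(x0, 0.0, 1e6),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(0.0, 1e8)] * k,
                    options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-11},
                )
                if best is None or res.fun < best.fun:
                    best = res
            gamma = self._newton_polish(np.asarray(best.x, dtype=float))
            gamma[gamma < _BOUNDARY_TOL] = 0.0
            converged = bool(best.success) or np.isfinite(best.fun)
            message = str(best.message)

        beta, r2, ldV, ldX, aux = self._pieces(gamma)
        df = self.N - self.p
        s2e = r2 / df
        loglik = -0.5 * (
            df * np.log(s2e) + ldV + ldX + df + df * np.log(2.0 * np.pi)
        )
        return gamma, s2e, beta, loglik, converged, message, aux


def _henderson_solution(problem: _REMLProblem, gamma: np.ndarray, s2e: float):
    """Fixed effects, BLUPs and their joint covariance from the MME.

    Components on the boundary (gamma = 0) are excluded; their BLUPs are
    exactly 0 with zero prediction variance.  Returns (beta_cov, blup dict,
    predvar dict, cov(beta, slope-BLUP error)).
    """
    keep = [i for i, g in enumerate(gamma) if g > 0.0]
    p = problem.p
    cols = np.concatenate(
        [np.where(problem.col_block == i)[0] for i in keep]
    ) if keep else np.zeros(0, dtype=int)
    q = len(cols)
    M = np.zeros((p + q, p + q))
    M[:p, :p] = problem.XtX
    rhs = np.zeros(p + q)
    rhs[:p] = problem.Xty
    if q:
        M[:p, p:] = problem.ZtX[cols].T
        M[p:, :p] = problem.ZtX[cols]
        M[p:, p:] = problem.ZtZ[np.ix_(cols, cols)]
        ginv = np.concatenate(
            [np.full(problem.block_sizes[i], 1.0 / gamma[i]) for i in keep]
        )
        M[p:, p:] += np.diag(ginv)
        rhs[p:] = problem.Zty[cols]
    Minv = linalg.inv(M, check_finite=False)
    sol = Minv @ rhs
    cov = s2e * Minv  # joint cov of (beta_hat, u_hat - u)

    beta_cov = cov[:p, :p]
    blups: dict[str, np.ndarray] = {}
    predvar: dict[str, np.ndarray] = {}
    cov_beta_u: dict[str, np.ndarray] = {}
    offset = p
    for i, name in enumerate(problem.block_names):
        size = problem.block_sizes[i]
        if i in keep:
            blups[name] = sol[offset:offset + size]
            predvar[name] = np.diag(cov)[offset:offset + size]
            cov_beta_u[name] = cov[:p, offset:offset + size]
            offset += size
        else:
            blups[name] = np.zeros(size)
            predvar[name] = np.zeros(size)
            cov_beta_u[name] = np.zeros((p, size))
    return beta_cov, blups, predvar, cov_beta_u, sol[:p]


def fit_reml(
    design: DesignBundle,
    starts: list[np.ndarray] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    compute_component_se: bool = False,
) -> GeneFit:
    """Fit the mixed model for one gene by profiled REML.

    ``starts`` supplies extra optimizer starting points as variance-ratio
    vectors in the order of ``design.spec.random_effects`` (used to embed a
    reduced-model optimum into the full model so the LRT is never negative
    beyond round-off).
    """
    problem = _REMLProblem(design)
    gamma, s2e, _, loglik, converged, message, _ = problem.fit(
        starts=starts, max_iter=max_iter, tol=tol
    )
    beta_cov, blups, predvar, cov_beta_u, beta = _henderson_solution(
        problem, gamma, s2e
    )

    components = {
        name: float(g * s2e) for name, g in zip(problem.block_names, gamma)
    }
    components["resid"] = float(s2e)

    fixed = pd.Series(beta, index=design.fixed_names)
    vcov = pd.DataFrame(beta_cov, index=design.fixed_names, columns=design.fixed_names)

    blup_series: dict[str, pd.Series] = {}
    for name, vals in blups.items():
        idx = design.exon_ids if name in ("exon", "survival_exon") else design.patient_ids
        blup_series[name] = pd.Series(vals, index=idx)

    slope_cov = None
    if "survival_exon" in problem.block_names and "survival" in design.fixed_names:
        j = design.fixed_names.index("survival")
        slope_cov = cov_beta_u["survival_exon"][j]

    fit = GeneFit(
        gene_id=design.gene_id,
        spec=design.spec,
        beta=fixed,
        vcov_beta=vcov,
        components=components,
        loglik=float(loglik),
        converged=converged,
        n_obs=problem.N,
        n_exons=design.n_exons,
        exon_ids=list(design.exon_ids),
        blups=blup_series,
        blup_predvar=predvar,
        slope_blup_cov_b=slope_cov,
        message=message,
    )

    if compute_component_se and problem.block_names:
        fit.components_se = _component_se(problem, gamma, s2e)
    return fit


def _component_se(problem: _REMLProblem, gamma: np.ndarray, s2e: float) -> dict[str, float]:
    """Asymptotic SEs of the variance components from the observed information.

    Central-difference Hessian of -2*loglik in the (s2_1..s2_k, s2_resid)
    parameterization; boundary components get SE = nan.
    """
    sig = np.append(gamma * s2e, s2e)
    k = len(sig)

    def f(v: np.ndarray) -> float:
        if v[-1] <= 0 or np.any(v[:-1] < 0):
            return np.inf
        return problem.m2ll_at(v[:-1], v[-1])

    h = np.maximum(1e-4 * np.abs(sig), 1e-9)
    H = np.zeros((k, k))
    f0 = f(sig)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(sig + ei) - 2 * f0 + f(sig - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(sig + ei + ej) - f(sig + ei - ej)
                    - f(sig - ei + ej) + f(sig - ei - ej)
                ) / (4 * h[i] * h[j])
    out: dict[str, float] = {}
    names = problem.block_names + ["resid"]
    try:
        cov = 2.0 * linalg.inv(H, check_finite=False)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except (np.linalg.LinAlgError, linalg.LinAlgError):
        se = np.full(k, np.nan)
    for name, sig_i, se_i in zip(names, sig, se):
        out[name] = float("nan") if (name != "resid" and sig_i == 0.0) else float(se_i)
    return out


# ---------------------------------------------------------------------------
# tests and derived quantities


def test_aeu(fit_full: GeneFit, fit_reduced: GeneFit, method: str = "lrt") -> float:
    """P-value for H0: s2_slope = 0 (no alternative exon usage).

    Default is the REML likelihood-ratio statistic referred to the 50:50
    chi-bar-square mixture of a point mass at 0 and chi2(1) — the boundary
    reference for a single variance component.  ``method="wald"`` instead
    uses Z = s2_slope / SE(s2_slope) with a one-sided normal reference.
    """
    if not (fit_full.converged and fit_reduced.converged):
        raise ValidationError("both fits must have converged")
    if method == "lrt":
        q = 2.0 * (fit_full.loglik - fit_reduced.loglik)
        if q < -1e-6:
            warnings.warn(
                f"full-model loglik below reduced by {-q:.3g}; clipping LRT to 0",
                stacklevel=2,
            )
        q = max(q, 0.0)
        return 1.0 if q == 0.0 else float(0.5 * stats.chi2.sf(q, df=1))
    if method == "wald":
        se = fit_full.components_se.get("survival_exon", float("nan"))
        s2 = fit_full.components.get("survival_exon", 0.0)
        if not np.isfinite(se) or se == 0.0:
            return 1.0 if s2 == 0.0 else float("nan")
        return float(stats.norm.sf(s2 / se))
    raise ValueError(f"unknown AEU test method {method!r}")


def test_survival(fit: GeneFit) -> float:
    """Two-sided p-value for H0: overall survival slope b = 0 (Wald t)."""
    b = float(fit.beta["survival"])
    se = float(fit.se_beta["survival"])
    if se == 0.0:
        raise ValidationError("zero standard error for survival slope")
    df = fit.n_obs - len(fit.beta)
    return float(2.0 * stats.t.sf(abs(b) / se, df=df))


def exon_slopes(fit: GeneFit) -> pd.DataFrame:
    """Per-exon survival slopes b + t_m with prediction SEs and fold changes.

    The SE combines var(b_hat), the BLUP prediction variance of t_m and
    their covariance; with s2_slope on the boundary every exon's slope is
    exactly the common b.
    """
    b = float(fit.beta["survival"])
    var_b = float(fit.vcov_beta.loc["survival", "survival"])
    n = fit.n_exons
    if "survival_exon" in fit.blups:
        dev = fit.blups["survival_exon"].to_numpy()
        pv = fit.blup_predvar["survival_exon"]
        cov = fit.slope_blup_cov_b if fit.slope_blup_cov_b is not None else np.zeros(n)
    else:
        dev = np.zeros(n)
        pv = np.zeros(n)
        cov = np.zeros(n)
    slope = b + dev
    var = np.maximum(var_b + pv + 2.0 * cov, 0.0)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "exon_id": fit.exon_ids,
            "order": np.arange(1, n + 1),
            "slope": slope,
            "se": se,
            "p_exon": p,
            "fold_change": fold_change(slope),
        }
    )


def fold_change(slope):
    """Expression fold change per additional survival month: 2**slope."""
    return 2.0 ** np.asarray(slope, dtype=float) if np.ndim(slope) else 2.0 ** float(slope)
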