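"""Variance components for the single-trait animal model by AI-REML.

The animal model analysed here is

    y = X b + Z a + (W p) + e,   a ~ N(0, sigma_a^2 H),
                                 p ~ N(0, sigma_p^2 I),  e ~ N(0, sigma_e^2 I)

with fixed effects b (contemporary group herd-year-season, country, parity
for repeated-records data) and covariates (age at calving, linear and
quadratic), additive genetic effects a structured by the combined
pedigree-genomic relationship matrix H, and — for animals with repeated
lactations — a permanent environmental effect p.  Heritability is
h2 = sigma_a^2 / (sigma_a^2 + sigma_p^2 + sigma_e^2) and repeatability is
r = (sigma_a^2 + sigma_p^2) / (sigma_a^2 + sigma_p^2 + sigma_e^2).

Estimation maximizes the restricted likelihood with average-information (AI)
updates, step-halving when a step overshoots, and a ratio-type EM-style
fallback when the AI matrix is not usable.  All algebra is dense: the
likelihood, its gradient and the AI matrix are formed from the record-level
covariance V = sum_i theta_i K_i and its projection P, which at desk scale
also yields exact prediction error variances downstream.

:func:`build_mme` assembles Henderson's mixed-model equations for the same
model; BLUP solutions and PEV for single-step GWAS are extracted from the
inverse coefficient matrix there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MMESystem",
    "design_matrices",
    "build_mme",
    "aireml",
    "heritability_from_components",
    "bivariate_aireml",
    "BivariateResult",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which columns of the phenotype table enter the model, and how.

    ``fixed_effects`` are categorical columns (one-hot encoded, first level
    dropped, redundant columns pruned to full rank); ``covariates`` enter as
    numeric regressors as given (pass e.g. both ``age`` and ``age_sq``).
    ``permanent_env`` switches on the repeatability model for repeated
    records per animal.
    """

    response: str
    fixed_effects: Sequence[str] = ("hys", "country")
    covariates: Sequence[str] = ("age", "age_sq")
    permanent_env: bool = False


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_p2: float
    sigma_e2: float
    se: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    converged: bool = False
    n_iterations: int = 0

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_p2 + self.sigma_e2

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma_a2 + self.sigma_p2) / self.total


def heritability_from_components(sigma_a2: float, sigma_p2: float, sigma_e2: float):
    """(h2, repeatability) from variance components.

    h2 = sigma_a2 / total, r = (sigma_a2 + sigma_p2) / total; with no
    permanent environmental variance the two coincide.
    """
    if min(sigma_a2, sigma_p2, sigma_e2) < 0:
        raise ValueError("variance components must be nonnegative")
    total = sigma_a2 + sigma_p2 + sigma_e2
    if total <= 0:
        raise ValueError("total variance is zero")
    return sigma_a2 / total, (sigma_a2 + sigma_p2) / total


def _full_rank_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size else 0
    return np.sort(piv[:rank])


def design_matrices(model: ModelSpec, phenotypes: pd.DataFrame, all_ids: np.ndarray):
    """(y, X, Z, W) for the animal model.

    X includes an intercept, dummy-coded fixed effects and the covariates,
    pruned to full column rank.  Z is the record -> animal incidence over
    the full pedigree order ``all_ids``; W (or None) is the record ->
    recorded-animal incidence for the permanent environmental term.
    """
    y = phenotypes[model.response].to_numpy(dtype=float)
    n = len(phenotypes)
    blocks = [np.ones((n, 1))]
    for col in model.fixed_effects:
        d = pd.get_dummies(phenotypes[col].astype("category"), drop_first=True)
        if d.shape[1]:
            blocks.append(d.to_numpy(dtype=float))
    for col in model.covariates:
        blocks.append(phenotypes[col].to_numpy(dtype=float).reshape(-1, 1))
    X = np.hstack(blocks)
    keep = _full_rank_columns(X)
    X = X[:, keep]

    pos = {int(a): i for i, a in enumerate(all_ids)}
    try:
        rec_idx = np.array([pos[int(a)] for a in phenotypes["animal"]])
    except KeyError as e:
        missing = sorted(set(int(a) for a in phenotypes["animal"]) - set(pos))
        raise KeyError(f"phenotyped animals absent from pedigree: {missing[:10]}") from e
    Z = np.zeros((n, len(all_ids)))
    Z[np.arange(n), rec_idx] = 1.0

    W = None
    if model.permanent_env:
        rec_animals = pd.Categorical(phenotypes["animal"])
        W = np.zeros((n, len(rec_animals.categories)))
        W[np.arange(n), rec_animals.codes] = 1.0
    return y, X, Z, W


@dataclass
class MMESystem:
    """Henderson's mixed-model equations for one trait.

    Solving ``C s = rhs`` gives (b, a, [p]); the inverse of C yields
    prediction error variances for the additive block.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray | None
    H_inv: np.ndarray
    C: np.ndarray
    rhs: np.ndarray
    slices: dict

    def solve(self):
        sol = np.linalg.solve(self.C, self.rhs)
        return {k: sol[v] for k, v in self.slices.items()}

    def solve_with_inverse(self):
        C_inv = np.linalg.inv(self.C)
        sol = C_inv @ self.rhs
        return {k: sol[v] for k, v in self.slices.items()}, C_inv


def build_mme(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    H_inv: np.ndarray,
    all_ids: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    sigma_p2: float = 0.0,
) -> MMESystem:
    """Assemble the MME: the additive block gets H^-1 * (sigma_e2/sigma_a2),
    the permanent environmental block I * (sigma_e2/sigma_p2)."""
    y, X, Z, W = design_matrices(model, phenotypes, all_ids)
    lam_a = sigma_e2 / sigma_a2
    parts = [X, Z] if W is None else [X, Z, W]
    M = np.hstack(parts)
    C = M.T @ M
    nx, nz = X.shape[1], Z.shape[1]
    C[nx:nx + nz, nx:nx + nz] += H_inv * lam_a
    slices = {"fixed": slice(0, nx), "additive": slice(nx, nx + nz)}
    if W is not None:
        if sigma_p2 <= 0:
            raise ValueError("repeatability model requires sigma_p2 > 0")
        nw = W.shape[1]
        C[nx + nz:, nx + nz:] += np.eye(nw) * (sigma_e2 / sigma_p2)
        slices["pe"] = slice(nx + nz, nx + nz + nw)
    rhs = M.T @ y
    return MMESystem(y=y, X=X, Z=Z, W=W, H_inv=H_inv, C=C, rhs=rhs, slices=slices)


# ---------------------------------------------------------------------------
# AI-REML core on the record-level covariance V = sum_i theta_i K_i
# ---------------------------------------------------------------------------

def _projection(V: np.ndarray, X: np.ndarray):
    """P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 and the restricted log-likelihood pieces."""
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return None, None, None
    V_inv = np.linalg.inv(V)
    XtVX = X.T @ V_inv @ X
    sign2, logdet_x = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return None, None, None
    P = V_inv - V_inv @ X @ np.linalg.solve(XtVX, X.T @ V_inv)
    return P, logdet_v, logdet_x


def _restricted_loglik(y, P, logdet_v, logdet_x):
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))


def _aireml_core(
    y: np.ndarray,
    X: np.ndarray,
    K_list: list,
    theta0: np.ndarray,
    positive: np.ndarray,
    max_iter: int = 200,
    tol_param: float = 1e-8,
    tol_grad: float = 1e-6,
    floor_frac: float = 1e-8,
):
    """Maximize the restricted likelihood over theta in V = sum theta_i K_i.

    ``positive`` marks components constrained > 0 (variances); unconstrained
    entries (covariances) may take any sign.  Accepted steps never decrease
    the restricted log-likelihood (step-halving); if an AI step cannot be
    made useful, a ratio-type EM-style update on the positive components is
    taken instead.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    floor = floor_frac * var_y
    n_theta = len(theta)

    def build_V(th):
        V = np.zeros_like(K_list[0])
        for t, K in zip(th, K_list):
            V += t * K
        return V

    P, ldv, ldx = _projection(build_V(theta), X)
    if P is None:
        raise np.linalg.LinAlgError("initial V not positive definite; adjust starting values")
    ll = _restricted_loglik(y, P, ldv, ldx)
    AI = np.eye(n_theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_old, ll_old = theta.copy(), ll
        Py = P @ y
        KPy = [K @ Py for K in K_list]
        grad = np.array([
            -0.5 * (float(np.sum(P * K)) - float(Py @ KPy[i]))
            for i, K in enumerate(K_list)
        ])
        AI = 0.5 * np.array([
            [float(KPy[i] @ P @ KPy[j]) for j in range(n_theta)]
            for i in range(n_theta)
        ])
        # candidate AI step (regularized), halved until the likelihood improves
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(n_theta) * np.trace(AI), grad)
        except np.linalg.LinAlgError:
            step = None
        accepted = False
        if step is not None and np.all(np.isfinite(step)):
            s = step.copy()
            for _ in range(25):
                cand = theta + s
                cand[positive] = np.maximum(cand[positive], floor)
                P_c, ldv_c, ldx_c = _projection(build_V(cand), X)
                if P_c is not None:
                    ll_c = _restricted_loglik(y, P_c, ldv_c, ldx_c)
                    if ll_c >= ll - 1e-10:
                        theta, P, ll = cand, P_c, ll_c
                        accepted = True
                        break
                s *= 0.5
        if not accepted:
            # EM-style multiplicative fallback on positive components:
            # at a stationary point y'P K P y = tr(P K), so scale toward the ratio.
            cand = theta.copy()
            for i in range(n_theta):
                if positive[i]:
                    trPK = float(np.sum(P * K_list[i]))
                    quad = float(Py @ KPy[i])
                    if trPK > 0 and quad >= 0:
                        cand[i] = max(theta[i] * quad / trPK, floor)
            P_c, ldv_c, ldx_c = _projection(build_V(cand), X)
            if P_c is not None:
                ll_c = _restricted_loglik(y, P_c, ldv_c, ldx_c)
                if ll_c >= ll - 1e-10:
                    theta, P, ll = cand, P_c, ll_c
                    accepted = True
                    logger.debug("iter %d: EM fallback step taken", it)
        if not accepted:
            # neither AI nor EM improves: at a (possibly boundary) optimum
            converged = True
            break
        scale = np.maximum(np.abs(theta), floor)
        rel_change = float(np.max(np.abs(theta - theta_old) / scale))
        grad_scaled = float(np.max(np.abs(grad) * scale))
        if rel_change < tol_param or (ll - ll_old < 1e-9 * (1 + abs(ll)) and grad_scaled < tol_grad):
            converged = True
            break
    se = np.full(n_theta, np.nan)
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        pass
    return theta, se, ll, converged, it


def aireml(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    H_inv: np.ndarray,
    all_ids: np.ndarray,
    start: tuple | None = None,
    max_iter: int = 200,
) -> VarianceComponents:
    """Estimate (sigma_a2, [sigma_p2], sigma_e2) for the animal model.

    ``H_inv`` is the (pedigree or combined) relationship inverse over
    ``all_ids``; the permanent environmental term is included when the model
    requests it.  Default start splits the phenotypic variance 50/50 between
    additive and residual (with 20% diverted to PE when present).
    """
    y, X, Z, W = design_matrices(model, phenotypes, all_ids)
    H = np.linalg.inv(H_inv)
    K_a = Z @ H @ Z.T
    K_list = [K_a]
    names = ["sigma_a2"]
    if model.permanent_env:
        if W is None:
            raise ValueError("permanent_env model but no W")
        K_list.append(W @ W.T)
        names.append("sigma_p2")
    K_list.append(np.eye(len(y)))
    names.append("sigma_e2")

    var_y = float(np.var(y, ddof=1))
    if start is None:
        if model.permanent_env:
            theta0 = np.array([0.4, 0.2, 0.4]) * var_y
        else:
            theta0 = np.array([0.5, 0.5]) * var_y
    else:
        theta0 = np.asarray(start, dtype=float)
    positive = np.ones(len(K_list), dtype=bool)
    theta, se, ll, converged, it = _aireml_core(
        y, X, K_list, theta0, positive, max_iter=max_iter)
    comp = dict(zip(names, theta))
    se_d = dict(zip(names, se))
    return VarianceComponents(
        sigma_a2=float(comp["sigma_a2"]),
        sigma_p2=float(comp.get("sigma_p2", 0.0)),
        sigma_e2=float(comp["sigma_e2"]),
        se=se_d, log_likelihood=float(ll), converged=bool(converged),
        n_iterations=it,
    )


@dataclass
class BivariateResult:
    genetic_cov: np.ndarray     # 2x2 additive (co)variance matrix
    residual_cov: np.ndarray    # 2x2 residual (co)variance matrix
    genetic_correlation: float
    log_likelihood: float
    converged: bool


def _psd_project(M: np.ndarray, min_corr_margin: float = 1e-4) -> np.ndarray:
    """Clip a symmetric 2x2 to positive semidefinite by bounding the correlation."""
    M = 0.5 * (M + M.T)
    d = np.sqrt(np.maximum(np.diag(M), 1e-12))
    rho = M[0, 1] / (d[0] * d[1])
    rho = np.clip(rho, -1.0 + min_corr_margin, 1.0 - min_corr_margin)
    out = M.copy()
    out[0, 1] = out[1, 0] = rho * d[0] * d[1]
    return out


def bivariate_aireml(
    models: tuple[ModelSpec, ModelSpec],
    phenotypes: pd.DataFrame,
    H_inv: np.ndarray,
    all_ids: np.ndarray,
    start: dict | None = None,
    max_iter: int = 200,
) -> BivariateResult:
    """Two-trait AI-REML for the genetic correlation between two responses.

    Both traits are taken from the same phenotype table (one record per
    animal per trait; rows with NaN in a response are dropped for that
    trait).  Residual covariance applies between the two traits measured on
    the same animal.  The fitted 2x2 genetic and residual matrices are
    PSD-projected whenever an update leaves the cone.
    """
    m1, m2 = models
    ph1 = phenotypes.dropna(subset=[m1.response])
    ph2 = phenotypes.dropna(subset=[m2.response])
    y1, X1, Z1, _ = design_matrices(m1, ph1, all_ids)
    y2, X2, Z2, _ = design_matrices(m2, ph2, all_ids)
    n1, n2 = len(y1), len(y2)
    y = np.concatenate([y1, y2])
    X = np.block([
        [X1, np.zeros((n1, X2.shape[1]))],
        [np.zeros((n2, X1.shape[1])), X2],
    ])
    H = np.linalg.inv(H_inv)
    G11 = Z1 @ H @ Z1.T
    G12 = Z1 @ H @ Z2.T
    G22 = Z2 @ H @ Z2.T
    zero12 = np.zeros((n1, n2))
    Ka11 = np.block([[G11, zero12], [zero12.T, np.zeros((n2, n2))]])
    Ka12 = np.block([[np.zeros((n1, n1)), G12], [G12.T, np.zeros((n2, n2))]])
    Ka22 = np.block([[np.zeros((n1, n1)), zero12], [zero12.T, G22]])
    # residual cross-covariance links records of the same animal across traits
    a1 = ph1["animal"].to_numpy()
    a2 = ph2["animal"].to_numpy()
    E12 = (a1[:, None] == a2[None, :]).astype(float)
    Ke11 = np.block([[np.eye(n1), zero12], [zero12.T, np.zeros((n2, n2))]])
    Ke12 = np.block([[np.zeros((n1, n1)), E12], [E12.T, np.zeros((n2, n2))]])
    Ke22 = np.block([[np.zeros((n1, n1)), zero12], [zero12.T, np.eye(n2)]])
    K_list = [Ka11, Ka12, Ka22, Ke11, Ke12, Ke22]
    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    if start is None:
        theta0 = np.array([0.5 * v1, 0.25 * np.sqrt(v1 * v2), 0.5 * v2,
                           0.5 * v1, 0.1 * np.sqrt(v1 * v2), 0.5 * v2])
    else:
        theta0 = np.array([start["va11"], start["va12"], start["va22"],
                           start["ve11"], start["ve12"], start["ve22"]])
    positive = np.array([True, False, True, True, False, True])
    theta, _, ll, converged, _ = _aireml_core(
        y, X, K_list, theta0, positive, max_iter=max_iter)
    Ga = _psd_project(np.array([[theta[0], theta[1]], [theta[1], theta[2]]]))
    Re = _psd_project(np.array([[theta[3], theta[4]], [theta[4], theta[5]]]))
    rg = Ga[0, 1] / np.sqrt(Ga[0, 0] * Ga[1, 1])
    return BivariateResult(
        genetic_cov=Ga, residual_cov=Re,
        genetic_correlation=float(np.clip(rg, -1.0, 1.0)),
        log_likelihood=float(ll), converged=bool(converged),
    )
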