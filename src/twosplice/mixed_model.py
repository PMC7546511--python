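"""Per-gene linear mixed model for log-scale isoform abundance.

The model for gene *m* with L isoforms over J conditions is the two-factor
split-plot model

    Y_jkl = beta^G + beta_l^I + beta_j^C + beta_jl^IC + rho_k(j) + eps_jkl,

where rho_k(j) ~ N(0, sigma_rho^2) is the whole-plot (sample) random effect
shared by the L isoform measurements of sample k in condition j, and
eps_jkl ~ N(0, sigma_l^2) allows isoform-specific error variances.  The
length-L vector Y_jk of one sample is then multivariate normal with

    Var(Y_jk) = Sigma = diag(sigma_1^2, ..., sigma_L^2) + sigma_rho^2 * 1 1^T,

the "unequal variance" structure; it reduces to compound symmetry when all
sigma_l^2 are equal and generalizes to an unstructured Sigma.

Fixed effects are reference-coded (beta_1^C = beta_1^I = beta_j1^IC =
beta_1l^IC = 0).  Fitting is by maximum likelihood: for fixed variance
parameters the fixed effects have a closed-form generalized-least-squares
solution, so the likelihood is profiled and only the variance parameters are
optimized numerically.  Because every sample in a condition shares the same
design block, the profiled likelihood is computed from per-condition
sufficient statistics (sample count, sum, and sum of outer products), making
each evaluation O(L^3) regardless of the number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .data_io import GeneData

logger = logging.getLogger("twosplice")

__all__ = [
    "MODEL_FORMS",
    "COVARIANCE_STRUCTURES",
    "OptimizerSettings",
    "FittedGeneModel",
    "ModelFitError",
    "StructureError",
    "n_fixed_params",
    "n_variance_params",
    "fixed_effect_names",
    "build_design_matrix",
    "build_covariance",
    "profile_loglik",
    "fit_gene_model",
]

MODEL_FORMS = ("full", "null_type1", "null_type2")
COVARIANCE_STRUCTURES = ("compound_symmetry", "unequal_variance", "unstructured")

UNSTRUCTURED_MAX_L = 15


class ModelFitError(RuntimeError):
    """Numerical failure (singular covariance / rank-deficient design) for a gene."""


class StructureError(ValueError):
    """Requested covariance structure is not estimable for this gene."""


@dataclass(frozen=True)
class OptimizerSettings:
    """Variance-parameter optimizer controls.

    ``rel_tol`` is the relative log-likelihood change below which L-BFGS-B
    stops; ``var_floor_scale`` times the total sample variance of the gene's
    log abundances floors the random-effect variance away from an exact zero
    boundary in the log parameterization.
    """

    max_iter: int = 500
    rel_tol: float = 1e-10
    grad_tol: float = 1e-7
    var_floor_scale: float = 1e-8
    fallback: bool = True  # derivative-free restart on optimizer failure


@dataclass
class FittedGeneModel:
    """One maximum-likelihood fit: a model form x covariance structure for one gene."""

    gene_id: str
    form: str
    structure: str
    beta: np.ndarray
    beta_names: list[str]
    var_params: np.ndarray
    loglik: float
    cov_beta: np.ndarray
    converged: bool
    n_iter: int
    J: int
    L: int
    isoform_ids: list[str] = field(default_factory=list)
    condition_labels: list[str] = field(default_factory=list)

    @property
    def n_fixed(self) -> int:
        return len(self.beta)


def n_fixed_params(form: str, J: int, L: int) -> int:
    """Free fixed-effect count under reference coding: J*L, L, or J+L-1."""
    if form == "full":
        return J * L
    if form == "null_type1":
        return L
    if form == "null_type2":
        return J + L - 1
    raise ValueError(f"unknown model form {form!r}")


def n_variance_params(structure: str, L: int) -> int:
    if structure == "compound_symmetry":
        return 2
    if structure == "unequal_variance":
        return L + 1
    if structure == "unstructured":
        return L * (L + 1) // 2
    raise ValueError(f"unknown covariance structure {structure!r}")


def fixed_effect_names(form: str, J: int, L: int) -> list[str]:
    names = ["intercept"]
    if form in ("full", "null_type2"):
        names += [f"cond[{j}]" for j in range(2, J + 1)]
    names += [f"iso[{l}]" for l in range(2, L + 1)]
    if form == "full":
        names += [f"cond[{j}]:iso[{l}]" for j in range(2, J + 1) for l in range(2, L + 1)]
    return names


def build_design_matrix(gene_or_dims, form: str) -> np.ndarray:
    """Per-condition design blocks, shape (J, L, p).

    Within a condition every sample shares the same L x p block.  Columns are
    ordered intercept, condition dummies (j = 2..J), isoform dummies
    (l = 2..L), then condition-by-isoform interactions (j-major).
    """
    if isinstance(gene_or_dims, GeneData):
        J, L = gene_or_dims.J, gene_or_dims.L
    else:
        J, L = gene_or_dims
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}")
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    if J < 2 and form != "null_type1":
        raise ValueError(f"form {form!r} requires J >= 2, got {J}")
    p = n_fixed_params(form, J, L)
    X = np.zeros((J, L, p))
    X[:, :, 0] = 1.0
    col = 1
    if form in ("full", "null_type2"):
        for j in range(2, J + 1):
            X[j - 1, :, col] = 1.0
            col += 1
    for l in range(2, L + 1):
        X[:, l - 1, col] = 1.0
        col += 1
    if form == "full":
        for j in range(2, J + 1):
            for l in range(2, L + 1):
                X[j - 1, l - 1, col] = 1.0
                col += 1
    return X


def build_covariance(params, structure: str, L: int) -> np.ndarray:
    """Map a variance-parameter vector to the L x L covariance Sigma.

    compound_symmetry: (sigma^2, sigma_rho^2); unequal_variance:
    (sigma_1^2..sigma_L^2, sigma_rho^2); unstructured: row-major
    lower-triangular Cholesky entries of Sigma.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 1 or len(params) != n_variance_params(structure, L):
        raise ValueError(
            f"{structure} with L={L} needs {n_variance_params(structure, L)} parameters, got {params.shape}"
        )
    if structure == "compound_symmetry":
        s2, srho2 = params
        if s2 <= 0 or srho2 < 0:
            raise ValueError("compound_symmetry requires sigma^2 > 0 and sigma_rho^2 >= 0")
        return np.full((L, L), srho2) + np.eye(L) * s2
    if structure == "unequal_variance":
        s2 = params[:L]
        srho2 = params[L]
        if (s2 <= 0).any() or srho2 < 0:
            raise ValueError("unequal_variance requires sigma_l^2 > 0 and sigma_rho^2 >= 0")
        return np.full((L, L), srho2) + np.diag(s2)
    # unstructured: Cholesky product
    C = np.zeros((L, L))
    C[np.tril_indices(L)] = params
    if (np.diag(C) <= 0).any():
        raise ValueError("unstructured requires positive Cholesky diagonal")
    return C @ C.T


def _suffstats(gene: GeneData):
    """Per-condition (K_j, sum Y_jk, sum Y_jk Y_jk^T)."""
    K = np.array(gene.K)
    T = [a.sum(axis=0) for a in gene.y]
    S = [a.T @ a for a in gene.y]
    return K, T, S


def _gls(Sigma: np.ndarray, X: np.ndarray, K, T, S, N: int, L: int):
    """Profiled GLS at a fixed Sigma, from sufficient statistics.

    Returns (loglik, beta, cov_beta, cho) with
    beta = (sum_jk X_j' Sigma^-1 X_j)^-1 sum_jk X_j' Sigma^-1 Y_jk.
    """
    try:
        cho = linalg.cho_factor(Sigma, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ModelFitError(f"singular covariance: {exc}") from exc
    J = X.shape[0]
    p = X.shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    SiX = []
    for j in range(J):
        W = linalg.cho_solve(cho, X[j], check_finite=False)  # Sigma^-1 X_j
        SiX.append(W)
        A += K[j] * (X[j].T @ W)
        b += W.T @ T[j]
    try:
        beta = linalg.solve(A, b, assume_a="pos", check_finite=False)
        cov_beta = linalg.inv(A, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ModelFitError(f"rank-deficient design: {exc}") from exc
    q = 0.0
    for j in range(J):
        m = X[j] @ beta
        w = linalg.cho_solve(cho, m, check_finite=False)
        q += np.trace(linalg.cho_solve(cho, S[j], check_finite=False))
        q += -2.0 * (T[j] @ w) + K[j] * (m @ w)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ll = -0.5 * (N * L * np.log(2.0 * np.pi) + N * logdet + q)
    return ll, beta, cov_beta, cho


def profile_loglik(params, gene: GeneData, form: str, structure: str):
    """Exact log-likelihood at given variance parameters, with the GLS fixed effects.

    Returns ``(loglik, beta, cov_beta)`` where ``cov_beta`` is the
    plug-in covariance (sum_jk X' Sigma^-1 X)^-1 of the estimates.
    """
    Sigma = build_covariance(params, structure, gene.L)
    X = build_design_matrix(gene, form)
    K, T, S = _suffstats(gene)
    try:
        ll, beta, cov_beta, _ = _gls(Sigma, X, K, T, S, gene.N, gene.L)
    except ModelFitError as exc:
        raise ModelFitError(f"gene {gene.gene_id}: {exc}") from exc
    return ll, beta, cov_beta


# ---------------------------------------------------------------------------
# Optimization over variance parameters.
#
# Working parameterization theta: log sigma_l^2 (or log sigma^2) and
# log(sigma_rho^2 + floor) for the structured forms; log-Cholesky for the
# unstructured form.  The gradient of the profiled log-likelihood with
# respect to theta uses the envelope theorem (dl/dbeta = 0 at the GLS
# solution):  dl/dtheta_i = 1/2 tr[(Q - N P) dSigma/dtheta_i],
# P = Sigma^-1, Q = P R P, R the residual cross-product matrix at beta-hat.


def _pack(values: np.ndarray, structure: str, L: int, floor: float) -> np.ndarray:
    if structure == "compound_symmetry":
        return np.array([np.log(values[0]), np.log(values[1] + floor)])
    if structure == "unequal_variance":
        return np.concatenate([np.log(values[:L]), [np.log(values[L] + floor)]])
    theta = values.copy()
    C = np.zeros((L, L))
    C[np.tril_indices(L)] = values
    di = np.cumsum(np.arange(1, L + 1)) - 1  # positions of diagonal entries
    theta[di] = np.log(values[di])
    return theta


def _unpack(theta: np.ndarray, structure: str, L: int, floor: float) -> np.ndarray:
    if structure == "compound_symmetry":
        return np.array([np.exp(theta[0]), max(np.exp(theta[1]) - floor, 0.0)])
    if structure == "unequal_variance":
        return np.concatenate([np.exp(theta[:L]), [max(np.exp(theta[L]) - floor, 0.0)]])
    values = theta.copy()
    di = np.cumsum(np.arange(1, L + 1)) - 1
    values[di] = np.exp(theta[di])
    return values


def _nll_and_grad(theta, structure, L, floor, X, K, T, S, N):
    values = _unpack(theta, structure, L, floor)
    if structure == "unstructured":
        Sigma = build_covariance(values, structure, L)
    elif structure == "compound_symmetry":
        Sigma = np.full((L, L), values[1] + 0.0) + np.eye(L) * values[0]
    else:
        Sigma = np.full((L, L), values[L]) + np.diag(values[:L])
    ll, beta, _, cho = _gls(Sigma, X, K, T, S, N, L)

    # residual cross-products R = sum_jk r_jk r_jk', from sufficient stats
    R = np.zeros((L, L))
    for j in range(X.shape[0]):
        m = X[j] @ beta
        R += S[j] - np.outer(T[j], m) - np.outer(m, T[j]) + K[j] * np.outer(m, m)
    P = linalg.cho_solve(cho, np.eye(L), check_finite=False)
    G = P @ R @ P - N * P  # dl/dSigma = G/2

    grad = np.empty_like(theta)
    if structure == "compound_symmetry":
        grad[0] = 0.5 * np.trace(G) * values[0]
        grad[1] = 0.5 * G.sum() * (values[1] + floor)
    elif structure == "unequal_variance":
        grad[:L] = 0.5 * np.diag(G) * values[:L]
        grad[L] = 0.5 * G.sum() * (values[L] + floor)
    else:
        C = np.zeros((L, L))
        C[np.tril_indices(L)] = values
        GC = G @ C  # dl/dC_ab = (G C)_ab for a >= b
        full = GC[np.tril_indices(L)]
        di = np.cumsum(np.arange(1, L + 1)) - 1
        full[di] *= values[di]  # chain rule through log diagonal
        grad[:] = full
    return -ll, -grad


def _init_varparams(gene: GeneData, structure: str, floor: float) -> np.ndarray:
    """Moment-based start: pooled within-condition residual covariance."""
    L, N = gene.L, gene.N
    R = np.zeros((L, L))
    for a in gene.y:
        resid = a - a.mean(axis=0, keepdims=True)
        R += resid.T @ resid
    S0 = R / max(N - gene.J, 1)
    off = S0[~np.eye(L, dtype=bool)]
    srho0 = float(np.clip(off.mean() if off.size else 0.0, floor, None))
    diag = np.diag(S0)
    s20 = np.maximum(diag - srho0, 0.05 * np.maximum(diag, floor))
    s20 = np.maximum(s20, floor)
    if structure == "compound_symmetry":
        return np.array([float(s20.mean()), srho0])
    if structure == "unequal_variance":
        return np.concatenate([s20, [srho0]])
    ridge = 1e-6 * np.trace(S0) / L + floor
    C = np.linalg.cholesky(S0 + ridge * np.eye(L))
    return C[np.tril_indices(L)]


def fit_gene_model(
    gene: GeneData,
    form: str = "full",
    structure: str = "unequal_variance",
    settings: OptimizerSettings | None = None,
) -> FittedGeneModel:
    """Maximum-likelihood fit of one model form under one covariance structure.

    Optimizes the profiled log-likelihood over variance parameters with
    L-BFGS-B and analytic gradients (a Nelder-Mead restart is attempted on
    failure).  ML, not REML, so that likelihood-ratio tests between nested
    fixed-effect structures are valid.  Deterministic given inputs.
    """
    settings = settings or OptimizerSettings()
    L, J, N = gene.L, gene.J, gene.N
    if structure == "unstructured":
        p = n_fixed_params(form, J, L)
        if L > UNSTRUCTURED_MAX_L or N < L * (L + 1) // 2 + p:
            raise StructureError(
                f"gene {gene.gene_id}: unstructured covariance needs L <= {UNSTRUCTURED_MAX_L} and "
                f"N >= L(L+1)/2 + p = {L * (L + 1) // 2 + p} (got L={L}, N={N}); "
                "use unequal_variance instead"
            )
    X = build_design_matrix(gene, form)
    K, T, S = _suffstats(gene)
    floor = settings.var_floor_scale * float(np.var(gene.stacked())) + 1e-300
    theta0 = _pack(_init_varparams(gene, structure, floor), structure, L, floor)
    args = (structure, L, floor, X, K, T, S, N)
    if structure in ("compound_symmetry", "unequal_variance"):
        # keep sigma_rho^2 = exp(theta) - floor non-negative
        bounds = [(None, None)] * (len(theta0) - 1) + [(np.log(floor), None)]
    else:
        bounds = None

    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": settings.max_iter, "ftol": settings.rel_tol, "gtol": settings.grad_tol},
    )
    n_iter = int(res.nit)
    converged = bool(res.success)
    if not converged and settings.fallback:
        res2 = optimize.minimize(
            lambda th: _nll_and_grad(th, *args)[0],
            res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 200 * len(theta0), "fatol": 1e-9, "xatol": 1e-7},
        )
        if res2.fun <= res.fun:
            res = res2
        n_iter += int(res2.nit)
        converged = bool(res2.success)

    values = _unpack(res.x, structure, L, floor)
    ll, beta, cov_beta = profile_loglik(values, gene, form, structure)
    if not converged:
        logger.warning("gene %s: %s/%s fit did not converge after %d iterations",
                       gene.gene_id, form, structure, n_iter)
    return FittedGeneModel(
        gene_id=gene.gene_id,
        form=form,
        structure=structure,
        beta=beta,
        beta_names=fixed_effect_names(form, J, L),
        var_params=values,
        loglik=float(ll),
        cov_beta=cov_beta,
        converged=converged,
        n_iter=n_iter,
        J=J,
        L=L,
        isoform_ids=list(gene.isoform_ids),
        condition_labels=list(gene.condition_labels),
    )
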