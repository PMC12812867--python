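"""Univariate GBLUP via Henderson's mixed-model equations.

The model is y = 1μ + Z_env β_env + Z_g g + Z_ge g_ge + ε with
g ~ N(0, σ²_g G), g_ge ~ N(0, σ²_ge (I_e ⊗ G)) and ε ~ N(0, σ²_ε I).
Variance components are supplied as ratios λ = σ²_ε / σ²_g (and λ_ge),
not estimated: the solver's role is algebraic verification and a
deterministic baseline, not variance-component inference.

A useful identity, used as a cross-check of the covariate assembly: ridge
regression with an unpenalised intercept on the Cholesky features Z_g Qᵗ
(penalty λ‖a‖²) yields exactly the GBLUP solution with ĝ = Qᵗ â, because
the substitution g = Qᵗ a turns the penalty λ gᵗ G⁻¹ g into λ aᵗ a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .prepare import IncidenceMatrix
from .relationship import RelationshipMatrix

log = logging.getLogger(__name__)


@dataclass
class GBLUPFit:
    """Solution of the mixed-model equations at fixed variance ratios."""

    mu: float
    beta_env: np.ndarray  # effect per environment level; first level fixed at 0
    g_hat: np.ndarray  # additive genomic effect per individual
    lambda_g: float
    env_levels: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    gge_hat: np.ndarray | None = None  # env-major: env_index * n + individual_index
    lambda_ge: float | None = None
    normal_residual: float = 0.0  # ‖Aθ − b‖∞ of the solved system


def gblup_fit(
    y: np.ndarray,
    ze: IncidenceMatrix | None,
    zg: IncidenceMatrix,
    G: RelationshipMatrix,
    lambda_g: float,
    lambda_ge: float | None = None,
    zge: IncidenceMatrix | None = None,
) -> GBLUPFit:
    """Solve Henderson's equations for (μ, β_env, g[, g_ge]).

    ``ze`` may be None for a single environment. The environment block is
    made identifiable by dropping the first level (its effect is 0). When
    ``lambda_ge`` is given, ``zge`` must be supplied with columns ordered
    environment-major, matching the I_e ⊗ G covariance.
    """
    y = np.asarray(y, dtype=float).ravel()
    if lambda_g <= 0 or (lambda_ge is not None and lambda_ge <= 0):
        raise ValueError("variance ratios must be positive")
    n_rec = y.size
    Zg = zg.values
    if Zg.shape[0] != n_rec:
        raise ValueError("y and Z_g are not conformable")
    n_ind = Zg.shape[1]
    if G.values.shape != (n_ind, n_ind):
        raise ValueError("G dimension does not match genotype levels")

    # fixed effects: intercept plus environment effects with first level dropped
    env_levels: list[str] = []
    if ze is not None and len(ze.cols) > 1:
        env_levels = list(ze.cols)
        Xf = np.hstack([np.ones((n_rec, 1)), ze.values[:, 1:]])
        log.debug("dropped environment level %r to keep fixed effects identifiable",
                  env_levels[0])
    else:
        if ze is not None:
            env_levels = list(ze.cols)
        Xf = np.ones((n_rec, 1))

    Ginv = np.linalg.inv(G.values)
    blocks = [Xf, Zg]
    penalties = [np.zeros((Xf.shape[1], Xf.shape[1])), lambda_g * Ginv]
    if lambda_ge is not None:
        if zge is None:
            raise ValueError("lambda_ge given but no Z_ge incidence")
        n_env = len(ze.cols) if ze is not None else 1
        if zge.values.shape[1] != n_ind * n_env:
            raise ValueError("Z_ge columns must be individuals x environments (env-major)")
        blocks.append(zge.values)
        penalties.append(lambda_ge * np.kron(np.eye(n_env), Ginv))

    Z = np.hstack(blocks)
    A = Z.T @ Z
    ofs = np.cumsum([0, *(b.shape[1] for b in blocks)])
    for k, P in enumerate(penalties):
        A[ofs[k]:ofs[k + 1], ofs[k]:ofs[k + 1]] += P
    b = Z.T @ y
    theta = np.linalg.solve(A, b)
    resid = float(np.max(np.abs(A @ theta - b)))

    mu = float(theta[0])
    beta = np.zeros(len(env_levels)) if env_levels else np.zeros(0)
    if env_levels and Xf.shape[1] > 1:
        beta[1:] = theta[1:Xf.shape[1]]
    g_hat = theta[ofs[1]:ofs[2]]
    gge_hat = theta[ofs[2]:ofs[3]] if lambda_ge is not None else None
    return GBLUPFit(
        mu=mu,
        beta_env=beta,
        g_hat=g_hat,
        lambda_g=float(lambda_g),
        env_levels=env_levels,
        individual_ids=list(zg.cols),
        gge_hat=gge_hat,
        lambda_ge=lambda_ge,
        normal_residual=resid,
    )


def gblup_predict(
    fit: GBLUPFit,
    ze_new: IncidenceMatrix | None,
    zg_new: IncidenceMatrix,
    zge_new: IncidenceMatrix | None = None,
) -> np.ndarray:
    """Predict records for known individuals: μ + Z_E β̂ + Z_g ĝ (+ Z_ge ĝ_ge)."""
    unknown = [c for c in zg_new.cols if c not in fit.individual_ids]
    if unknown:
        raise ValueError(f"individuals absent from the fitted G: {unknown[:5]}")
    order = [fit.individual_ids.index(c) for c in zg_new.cols]
    pred = fit.mu + zg_new.values @ fit.g_hat[order]
    if ze_new is not None and len(fit.env_levels):
        unknown_env = [c for c in ze_new.cols if c not in fit.env_levels]
        if unknown_env:
            raise ValueError(f"environments absent from the fit: {unknown_env}")
        eorder = [fit.env_levels.index(c) for c in ze_new.cols]
        pred = pred + ze_new.values @ fit.beta_env[eorder]
    if zge_new is not None:
        if fit.gge_hat is None:
            raise ValueError("fit has no G×E effects")
        pred = pred + zge_new.values @ fit.gge_hat
    return pred


def ridge_fit(F: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Ridge with an unpenalised intercept: min ‖y − 1μ − F a‖² + λ‖a‖²."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = F.shape
    A = np.empty((p + 1, p + 1))
    A[0, 0] = n
    A[0, 1:] = F.sum(axis=0)
    A[1:, 0] = F.sum(axis=0)
    A[1:, 1:] = F.T @ F + lam * np.eye(p)
    b = np.concatenate([[y.sum()], F.T @ y])
    theta = np.linalg.solve(A, b)
    return float(theta[0]), theta[1:]


def ridge_model_factory(lam: float):
    """Cross-validation factory: ridge on the prepared covariates.

    On a relationship-matrix PreparedDataset the covariates are the
    Cholesky features, so this is exactly GBLUP at variance ratio ``lam``.
    """

    def factory(X_train, Y_train, seed):
        Y_train = np.asarray(Y_train, dtype=float)
        if Y_train.ndim == 1:
            Y_train = Y_train[:, None]
        fits = [ridge_fit(X_train, Y_train[:, j], lam) for j in range(Y_train.shape[1])]

        def predict_fn(X_new):
            X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
            return np.column_stack([mu + X_new @ a for mu, a in fits])

        return predict_fn

    return factory
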