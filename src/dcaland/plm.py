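"""Model fitting: regularized pseudolikelihood maximization and frequency counting.

The Potts fit follows the asymmetric plmDCA scheme: for every site ``i`` the
weighted conditional likelihood of column ``i`` given the other columns is
maximized independently over (h_i, {J_ij}_{j≠i}) with an L2 penalty, the two
directed estimates of each coupling block are averaged, and the final model
is shifted to the zero-sum gauge. Defaults mirror the standard plmDCA
settings: reweighting θ = 0.2 and λ_h = λ_J = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from dcaland.alphabet import Alphabet
from dcaland.models import IndependentModel, PottsModel, gauge_transform
from dcaland.msa import MSA, SequenceWeights

logger = logging.getLogger(__name__)


@dataclass
class PlmConfig:
    """Hyperparameters of the pseudolikelihood fit.

    ``reg_scale`` selects the regularization convention: ``"per_meff"``
    normalizes the weighted negative log-likelihood by m_eff so that
    λ_h/λ_J act on the same scale regardless of alignment depth;
    ``"per_sum"`` leaves the weighted sum unnormalized.
    """

    lambda_h: float = 0.01
    lambda_J: float = 0.01
    theta: float = 0.2
    tol: float = 1e-5
    max_iter: int = 500
    symmetrize: bool = True
    reg_scale: str = "per_meff"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_h < 0 or self.lambda_J < 0:
            raise ValueError("regularization strengths must be ≥ 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SiteFitReport:
    site: int  # 1-based
    converged: bool
    grad_norm: float
    n_iter: int


def fit_ind(msa: MSA, weights: SequenceWeights, pseudocount: float = 0.01) -> IndependentModel:
    """Reweighted per-site frequency model over the 21 states."""
    w = weights.vector(msa)
    q = msa.alphabet.q
    f = np.zeros((msa.L, q))
    for s in range(q):
        f[:, s] = (w[:, None] * (msa.matrix == s)).sum(axis=0)
    f /= weights.m_eff
    return IndependentModel(
        f=f,
        alphabet=msa.alphabet,
        pseudocount=pseudocount,
        metadata={"m_eff": weights.m_eff, "theta": weights.theta, "M": msa.M},
    )


def _site_objective(params, X, w, site, L, q, lam_h, lam_J, norm):
    """Weighted conditional NLL of column ``site`` plus L2 penalty; returns (f, grad)."""
    M = X.shape[0]
    h = params[:q]
    J = params[q:].reshape(L, q, q)  # J[site, ·, ·] is forced to stay zero

    logits = np.broadcast_to(h, (M, q)).copy()
    for j in range(L):
        if j == site:
            continue
        logits += J[j][:, X[:, j]].T
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    Z = expl.sum(axis=1)
    p = expl / Z[:, None]

    xi = X[:, site]
    ll = logits[np.arange(M), xi] - np.log(Z)
    nll = -(w * ll).sum() / norm

    D = (p - np.eye(q)[xi]) * w[:, None] / norm  # (M, q)
    grad_h = D.sum(axis=0)
    grad_J = np.zeros_like(J)
    for j in range(L):
        if j == site:
            continue
        onehot = np.zeros((M, q))
        onehot[np.arange(M), X[:, j]] = 1.0
        grad_J[j] = D.T @ onehot
    f = nll + lam_h * (h @ h) + lam_J * (J * J).sum()
    grad_h = grad_h + 2.0 * lam_h * h
    grad_J = grad_J + 2.0 * lam_J * J
    grad_J[site] = 0.0
    return f, np.concatenate([grad_h, grad_J.ravel()])


def fit_plm(
    msa: MSA, weights: SequenceWeights, config: PlmConfig | None = None
) -> PottsModel:
    """Fit a Potts model by per-site regularized pseudolikelihood maximization.

    Each site's conditional fit is a smooth convex problem solved with
    L-BFGS-B; the two directed estimates of every coupling block are averaged
    and the result is returned in the zero-sum gauge. Non-converged sites are
    logged and flagged in the model metadata.
    """
    config = config or PlmConfig()
    X = msa.matrix.astype(np.int64)
    w = weights.vector(msa)
    L, q = msa.L, msa.alphabet.q
    norm = weights.m_eff if config.reg_scale == "per_meff" else 1.0
    if config.reg_scale not in ("per_meff", "per_sum"):
        raise ValueError(f"unknown reg_scale {config.reg_scale!r}")

    h = np.zeros((L, q))
    J_dir = np.zeros((L, L, q, q))  # J_dir[i, j] = coupling estimated from site i's fit
    reports: list[SiteFitReport] = []
    for i in range(L):
        x0 = np.zeros(q + L * q * q)
        res = minimize(
            _site_objective,
            x0,
            args=(X, w, i, L, q, config.lambda_h, config.lambda_J, norm),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "gtol": config.tol, "ftol": 1e-12},
        )
        grad_norm = float(np.abs(res.jac).max())
        converged = bool(res.success or grad_norm <= config.tol * 10)
        if not converged:
            logger.warning("site %d pseudolikelihood fit did not converge: %s", i + 1, res.message)
        reports.append(SiteFitReport(i + 1, converged, grad_norm, int(res.nit)))
        h[i] = res.x[:q]
        J_dir[i] = res.x[q:].reshape(L, q, q)
        J_dir[i, i] = 0.0

    if config.symmetrize:
        J = 0.5 * (J_dir + np.transpose(J_dir, (1, 0, 3, 2)))
    else:
        J = J_dir
    model = PottsModel(
        h=h,
        J=J,
        alphabet=msa.alphabet,
        gauge="raw",
        metadata={
            "m_eff": weights.m_eff,
            "theta": weights.theta,
            "lambda_h": config.lambda_h,
            "lambda_J": config.lambda_J,
            "reg_scale": config.reg_scale,
            "M": msa.M,
            "all_converged": all(r.converged for r in reports),
        },
    )
    model = gauge_transform(model, "zero-sum")
    model.fit_reports = reports
    return model


def apc(scores: np.ndarray) -> np.ndarray:
    """Average-product correction: S_ij − S̄_i· S̄_·j / S̄_·· .

    Means are taken over the full matrix (a rank-one score matrix is
    corrected exactly to zero).
    """
    row = scores.mean(axis=1, keepdims=True)
    col = scores.mean(axis=0, keepdims=True)
    grand = scores.mean()
    if grand == 0.0:
        return scores.copy()
    return scores - row @ col / grand


def frobenius_scores(model: PottsModel, apc_correct: bool = True) -> np.ndarray:
    """Per-pair Frobenius norms of the residue (gap-excluded) coupling blocks.

    Requires the zero-sum gauge so magnitudes are comparable across pairs.
    Returns a symmetric (L, L) matrix with zero diagonal; with
    ``apc_correct`` the average-product correction is applied.
    """
    if model.gauge != "zero-sum":
        raise ValueError("frobenius_scores requires a zero-sum gauge model")
    n = model.alphabet.n_residues
    blocks = model.J[:, :, :n, :n]
    scores = np.sqrt((blocks**2).sum(axis=(2, 3)))
    np.fill_diagonal(scores, 0.0)
    if apc_correct:
        scores = apc(scores)
        np.fill_diagonal(scores, 0.0)
    return scores


def top_pairs(scores: np.ndarray, k: int) -> list[tuple[int, int]]:
    """The k highest-scoring site pairs (0-based, i<j)."""
    L = scores.shape[0]
    iu = np.triu_indices(L, k=1)
    order = np.argsort(scores[iu])[::-1][:k]
    return [(int(iu[0][o]), int(iu[1][o])) for o in order]
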