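"""Truncated-Gaussian graphical model core.

The model for a non-negative observation vector ``y`` in R_+^p has
unnormalized log-density

    log p(y) = -1/2 y' Theta y + eta' (y - 1)    for y >= 0 componentwise,

i.e. a multivariate Gaussian with precision matrix ``Theta`` and linear
parameter ``eta`` (mean ``Theta^{-1} eta``), truncated to the non-negative
orthant.  Because the normalizing constant of the truncated density is
intractable, estimation uses a generalized (h-weighted) score-matching
loss, which is free of the constant and jointly quadratic in
``(Theta, eta)``.

The weight function is ``h(y) = min(y, C)`` applied componentwise; ``h(0)=0``
makes the boundary terms of the integration by parts vanish on the orthant,
and the cap ``C`` bounds the weight under heavy right tails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TGMParams",
    "HWeight",
    "log_density_unnorm",
    "h_eval",
    "sm_loss",
    "sm_loss_grad",
    "per_sample_grads",
    "sandwich_errors",
    "fit_unpenalized",
    "pooled_scale",
]

_SYM_TOL = 1e-10


@dataclass
class TGMParams:
    """Parameters of the truncated-Gaussian density.

    Theta is the symmetric p x p interaction (precision) matrix, eta the
    length-p linear term.  The power constants of the wider non-negative
    exponential family are fixed at a = b = 1 (the truncated-Gaussian case).
    """

    Theta: np.ndarray
    eta: np.ndarray
    a: int = 1
    b: int = 1

    def __post_init__(self) -> None:
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.a != 1 or self.b != 1:
            raise ValueError("only the truncated-Gaussian case a = b = 1 is supported")
        if self.Theta.ndim != 2 or self.Theta.shape[0] != self.Theta.shape[1]:
            raise ValueError("Theta must be a square matrix")
        if self.eta.shape != (self.Theta.shape[0],):
            raise ValueError("eta length must match Theta dimension")
        if not np.allclose(self.Theta, self.Theta.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("Theta must be symmetric (tolerance 1e-10)")
        # store exactly symmetric copy so downstream algebra is exact
        self.Theta = 0.5 * (self.Theta + self.Theta.T)

    @property
    def p(self) -> int:
        return self.Theta.shape[0]


@dataclass(frozen=True)
class HWeight:
    """Score-matching weight h(y) = min(y, cap); cap may be +inf."""

    cap: float = 3.0

    def __post_init__(self) -> None:
        if not self.cap > 0:
            raise ValueError("cap must be positive")


def log_density_unnorm(y: np.ndarray, params: TGMParams) -> float:
    """Unnormalized log-density; -inf outside the non-negative orthant."""
    y = np.asarray(y, dtype=float)
    if y.shape != (params.p,):
        raise ValueError(f"y has shape {y.shape}, expected ({params.p},)")
    if np.any(y < 0):
        return -math.inf
    return float(-0.5 * y @ params.Theta @ y + params.eta @ (y - 1.0))


def h_eval(y, hweight: HWeight):
    """Evaluate the weight function and its derivative at non-negative y.

    Returns ``(h, h')`` with h = min(y, C) and h' = 1 on y < C, 0 beyond.
    Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("h is only defined on non-negative arguments")
    h = np.minimum(y, hweight.cap)
    hp = (y < hweight.cap).astype(float)
    if y.ndim == 0:
        return float(h), float(hp)
    return h, hp


def _check_data(data: np.ndarray, p: int) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != p:
        raise ValueError(f"data must be n x {p}")
    if data.shape[0] < 1:
        raise ValueError("need at least one observation")
    if np.any(~np.isfinite(data)):
        raise ValueError("data contains NaN or infinite entries")
    if np.any(data < 0):
        raise ValueError("data must be non-negative")
    return data


def sm_loss(data: np.ndarray, params: TGMParams, hweight: HWeight = HWeight()) -> float:
    """Empirical h-weighted score-matching loss.

    J = (1/n) sum_i sum_j [ 1/2 h(y_ij) s_ij^2 - h'(y_ij) s_ij - h(y_ij) theta_jj ],

    with s_ij = (Theta y_i)_j - eta_j.  This is the integration-by-parts form
    of the Hyvarinen score objective for the truncated-Gaussian density; it is
    a convex quadratic in (Theta, eta).
    """
    Y = _check_data(data, params.p)
    H, Hp = h_eval(Y, hweight)
    S = Y @ params.Theta - params.eta  # n x p, row i is Theta y_i - eta
    n = Y.shape[0]
    val = 0.5 * np.sum(H * S * S) - np.sum(Hp * S) - H.sum(axis=0) @ np.diag(params.Theta)
    return float(val / n)


def sm_loss_grad(data: np.ndarray, params: TGMParams, hweight: HWeight = HWeight()):
    """Exact gradient of :func:`sm_loss` in the symmetric parameterization.

    Off-diagonal entries of the returned ``grad_Theta`` accumulate both the
    (l, j) and (j, l) partials, since theta_lj = theta_jl is one parameter.
    """
    Y = _check_data(data, params.p)
    H, Hp = h_eval(Y, hweight)
    S = Y @ params.Theta - params.eta
    n = Y.shape[0]
    W = H * S - Hp  # n x p
    G = (W.T @ Y - np.diag(H.sum(axis=0))) / n  # unconstrained dJ/dTheta
    grad_Theta = G + G.T
    np.fill_diagonal(grad_Theta, np.diag(G))
    grad_eta = -W.sum(axis=0) / n
    return grad_Theta, grad_eta


def fit_unpenalized(
    data: np.ndarray,
    hweight: HWeight = HWeight(),
    *,
    diagonal_only: bool = False,
    ridge: float = 0.0,
) -> TGMParams:
    """Minimize the score-matching loss without penalties.

    The loss is quadratic, so the minimizer solves one linear system in the
    stacked parameters (upper triangle of Theta plus eta).  With
    ``diagonal_only`` the off-diagonal of Theta is pinned at zero and the
    problem decouples into p independent 2 x 2 systems (used for the lasso
    null model).  ``ridge`` adds a small Tikhonov term for nearly singular
    designs (rank-deficient data at tiny n).
    """
    data = np.asarray(data, dtype=float)
    p = data.shape[1]
    if diagonal_only:
        Theta = np.zeros((p, p))
        eta = np.zeros(p)
        hw = hweight
        for j in range(p):
            col = data[:, j : j + 1]
            prm = fit_unpenalized(col, hw, ridge=ridge)
            Theta[j, j] = prm.Theta[0, 0]
            eta[j] = prm.eta[0]
        return TGMParams(Theta, eta)

    k = _n_free(p)
    A = np.zeros((k, k))
    b = np.zeros(k)
    zero = TGMParams(np.zeros((p, p)), np.zeros(p))
    g0 = _pack_grad(*sm_loss_grad(data, zero, hweight))
    basis = np.eye(k)
    for i in range(k):  # Hessian column via gradient of the quadratic
        Ti, ei = unpack_params(basis[i], p)
        gi = _pack_grad(*sm_loss_grad(data, TGMParams(Ti, ei), hweight))
        A[:, i] = gi - g0
    b = -g0
    if ridge > 0:
        A = A + ridge * np.eye(k)
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
    Theta, eta = unpack_params(x, p)
    prm = TGMParams(Theta, eta)
    if p <= 50:
        try:
            if np.min(np.linalg.eigvalsh(prm.Theta)) <= 0:
                warnings.warn("unpenalized Theta estimate is not positive definite")
        except np.linalg.LinAlgError:
            pass
    return prm


# ---------------------------------------------------------------------------
# parameter packing: vech(Theta) (upper triangle incl. diagonal) then eta

def _n_free(p: int) -> int:
    return p * (p + 1) // 2 + p


def pack_params(Theta: np.ndarray, eta: np.ndarray) -> np.ndarray:
    p = len(eta)
    iu = np.triu_indices(p)
    return np.concatenate([np.asarray(Theta)[iu], eta])


def unpack_params(x: np.ndarray, p: int):
    iu = np.triu_indices(p)
    Theta = np.zeros((p, p))
    m = p * (p + 1) // 2
    Theta[iu] = x[:m]
    Theta = Theta + np.triu(Theta, 1).T
    return Theta, np.asarray(x[m:], dtype=float).copy()


def _pack_grad(grad_Theta: np.ndarray, grad_eta: np.ndarray) -> np.ndarray:
    # grad_Theta already accumulates symmetric partials; its upper triangle
    # is exactly the gradient wrt the packed free parameters
    p = len(grad_eta)
    iu = np.triu_indices(p)
    return np.concatenate([grad_Theta[iu], grad_eta])


def per_sample_grads(data: np.ndarray, params: TGMParams, hweight: HWeight = HWeight()) -> np.ndarray:
    """Per-observation gradients of the loss, stacked as an n x k matrix in
    packed (vech Theta, eta) coordinates; their mean is :func:`sm_loss_grad`.
    Used for sandwich (robust) variance estimation."""
    Y = _check_data(data, params.p)
    p = params.p
    H, Hp = h_eval(Y, hweight)
    S = Y @ params.Theta - params.eta
    W = H * S - Hp
    # symmetric-accumulated dTheta per sample: W_a Y_b + W_b Y_a, diag W_a Y_a - H_a
    O = W[:, :, None] * Y[:, None, :]
    Gfull = O + np.transpose(O, (0, 2, 1))
    diag = W * Y - H
    n = Y.shape[0]
    idx = np.arange(p)
    Gfull[:, idx, idx] = diag
    iu = np.triu_indices(p)
    return np.concatenate([Gfull[:, iu[0], iu[1]], -W], axis=1)


def sandwich_errors(data: np.ndarray, params: TGMParams, hweight: HWeight = HWeight()) -> np.ndarray:
    """Sandwich standard errors of the unpenalized estimates.

    Returns a symmetric p x p matrix of standard errors for the entries of
    Theta (computed at ``params``, normally the unpenalized minimizer):
    Var = A^{-1} K A^{-1} / n with A the loss Hessian and K the
    per-observation gradient covariance.
    """
    Y = _check_data(data, params.p)
    p = params.p
    n = Y.shape[0]
    Gs = per_sample_grads(Y, params, hweight)
    Gs = Gs - Gs.mean(axis=0)
    K = Gs.T @ Gs / n
    k = _n_free(p)
    zero = TGMParams(np.zeros((p, p)), np.zeros(p))
    g0 = _pack_grad(*sm_loss_grad(Y, zero, hweight))
    A = np.empty((k, k))
    basis = np.eye(k)
    for i in range(k):
        Ti, ei = unpack_params(basis[i], p)
        A[:, i] = _pack_grad(*sm_loss_grad(Y, TGMParams(Ti, ei), hweight)) - g0
    Ainv = np.linalg.pinv(A)
    V = Ainv @ K @ Ainv / n
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    SE = np.zeros((p, p))
    iu = np.triu_indices(p)
    SE[iu] = se[: p * (p + 1) // 2]
    SE = SE + np.triu(SE, 1).T
    return SE


def pooled_scale(matrices) -> np.ndarray:
    """Column scales for standardization: the pooled (all-periods) standard
    deviation per keyword.  Columns are divided by their scale but never
    centered, so non-negativity is preserved.  All-constant columns get
    scale 1 to stay finite.
    """
    stacked = np.vstack([np.asarray(m, dtype=float) for m in matrices])
    sd = stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else np.ones(stacked.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return sd
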