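"""Collaborative-filtering core: latent factors, targets, and the row QP solver.

Each gene i carries a feature vector x_i and each TF j a feature vector y_j,
both constrained to the unit ball so that x_i' y_j lies in [-1, 1] (Cauchy-
Schwarz). The CF objective pushes x_i' y_j toward a binary target Theta_ij
(observed-or-confirmed edge) with per-pair confidence Omega_ij.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .priors import PenaltyMatrices

__all__ = [
    "LatentFactors",
    "CFTargets",
    "init_factors",
    "update_cf_targets",
    "cf_objective",
    "solve_unit_ball_qp",
    "update_X",
    "update_Y",
    "fit_cf",
]

#: unit-ball feasibility tolerance; rows exceeding 1 by more are renormalized
BALL_EPS = 1e-8
MU_MIN = 1e-6


@dataclass
class LatentFactors:
    """X: n x h gene features, Y: m x h TF features, rows in the unit ball."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = _clip_rows(np.asarray(self.X, dtype=float))
        self.Y = _clip_rows(np.asarray(self.Y, dtype=float))
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("X and Y must share the latent dimension")

    def dot(self) -> np.ndarray:
        """x_i' y_j for every pair, an n x m matrix in [-1, 1] (+ tolerance)."""
        return self.X @ self.Y.T


@dataclass
class CFTargets:
    """Theta: binary n x m prediction target; Omega: positive n x m confidence."""

    Theta: np.ndarray
    Omega: np.ndarray

    def __post_init__(self) -> None:
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.Omega = np.asarray(self.Omega, dtype=float)
        if self.Theta.shape != self.Omega.shape:
            raise ValueError("Theta and Omega must share one shape")
        if not np.isin(self.Theta, (0.0, 1.0)).all():
            raise ValueError("Theta must be binary")
        if (self.Omega <= 0).any():
            raise ValueError("Omega must be positive")


def _clip_rows(M: np.ndarray) -> np.ndarray:
    """Renormalize any row whose squared norm exceeds 1 + BALL_EPS."""
    nrm2 = (M**2).sum(axis=1)
    over = nrm2 > 1.0 + BALL_EPS
    if over.any():
        M = M.copy()
        M[over] /= np.sqrt(nrm2[over])[:, None]
    return M


def init_factors(n: int, m: int, h: int, rng: np.random.Generator) -> LatentFactors:
    """Uniform init in [-1/sqrt(h), 1/sqrt(h)] per coordinate (rows feasible)."""
    s = 1.0 / np.sqrt(h)
    return LatentFactors(rng.uniform(-s, s, (n, h)), rng.uniform(-s, s, (m, h)))


def update_cf_targets(S: np.ndarray, pen: PenaltyMatrices) -> CFTargets:
    """Refresh (Theta, Omega) from the current network support.

    Theta_ij = ||S_ij||_0 + (1 - ||S_ij||_0) B_ij — the logical OR of the
    confirmed support and the prior observation. Omega_ij switches to the
    elevated penalty Cbar_ij on confirmed pairs.
    """
    s0 = (np.asarray(S) != 0).astype(float)
    Theta = s0 + (1.0 - s0) * pen.B
    Omega = np.where(s0 > 0, pen.Cbar, pen.C)
    return CFTargets(Theta=Theta, Omega=Omega)


def cf_objective(factors: LatentFactors, targets: CFTargets) -> float:
    """sum_ij Omega_ij (Theta_ij - x_i' y_j)^2."""
    R = targets.Theta - factors.dot()
    return float((targets.Omega * R**2).sum())


def solve_unit_ball_qp(phi: np.ndarray, varphi: np.ndarray) -> np.ndarray:
    """Global minimizer of v' phi v - varphi . v subject to ||v||^2 <= 1.

    phi must be symmetric PSD. Either the unconstrained stationary point
    phi^{-1} varphi / 2 (when feasible) or the KKT boundary point
    (phi + nu I)^{-1} varphi / 2 with the multiplier nu >= 0 found by
    monotone scalar root-finding on ||v(nu)|| = 1.
    """
    phi = np.asarray(phi, dtype=float)
    varphi = np.asarray(varphi, dtype=float).ravel()
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(varphi))):
        raise ValueError("non-finite inputs to solve_unit_ball_qp")
    lam, Q = np.linalg.eigh((phi + phi.T) / 2.0)
    w = Q.T @ (varphi / 2.0)
    if np.allclose(w, 0.0):
        return np.zeros_like(varphi)
    tiny = 1e-12 * max(1.0, lam.max())
    # interior candidate: pseudo-inverse stationary point, valid only when
    # varphi has no component in the null space of phi
    if np.all(np.abs(w[lam <= tiny]) <= 1e-12):
        coef = np.where(lam > tiny, w / np.where(lam > tiny, lam, 1.0), 0.0)
        if coef @ coef <= 1.0 + BALL_EPS:
            return Q @ coef

    def norm2(nu: float) -> float:
        return float(((w / (lam + nu)) ** 2).sum())

    lo = max(0.0, -lam.min()) + 1e-14
    hi = max(lo * 2, np.linalg.norm(w) - lam.min() + 1e-9)
    while norm2(hi) > 1.0:
        hi *= 2.0
    if norm2(lo) <= 1.0:  # boundary unreachable from nu >= 0: feasible stationary point
        return Q @ (w / (lam + lo))
    nu = brentq(lambda t: norm2(t) - 1.0, lo, hi, xtol=1e-14, rtol=1e-15)
    v = Q @ (w / (lam + nu))
    n = np.linalg.norm(v)
    if n > 1.0:
        v /= n
    return v


def _reweight(pen: PenaltyMatrices, S: np.ndarray, lam: float) -> np.ndarray:
    """lam * Omega_ij: the diagonal CF confidence entering the row QPs."""
    s0 = (np.asarray(S) != 0).astype(float)
    return lam * (pen.C + (pen.Cbar - pen.C) * s0)


def update_X(
    factors: LatentFactors,
    targets: CFTargets,
    S: np.ndarray,
    pen: PenaltyMatrices,
    lam: float,
    mu_x: float | None = None,
) -> LatentFactors:
    """Exact proximal update of every gene feature row.

    Row i minimizes lam * sum_j Omega_ij (Theta_ij - x' y_j)^2
    + (mu_x,i / 2) ||x - x_i^old||^2 over the unit ball, via the QP
    phi = (mu/2) I + Y' diag(lam Omega_i) Y,
    varphi = 2 Theta_i diag(lam Omega_i) Y + mu x_i^old.
    By default mu_x,i = max(||2 Y' diag(lam Omega_i) Y||_F, mu_min).
    """
    Y = factors.Y
    A_bar = _reweight(pen, S, lam)
    Xn = factors.X.copy()
    for i in range(Xn.shape[0]):
        ai = A_bar[i]
        G = (Y * ai[:, None]).T @ Y
        mu = max(2.0 * np.linalg.norm(G, "fro"), MU_MIN) if mu_x is None else mu_x
        phi = 0.5 * mu * np.eye(Y.shape[1]) + G
        varphi = 2.0 * ((targets.Theta[i] * ai) @ Y) + mu * Xn[i]
        Xn[i] = solve_unit_ball_qp(phi, varphi)
    return LatentFactors(Xn, Y.copy())


def update_Y(
    factors: LatentFactors,
    targets: CFTargets,
    S: np.ndarray,
    pen: PenaltyMatrices,
    lam: float,
    mu_y: float | None = None,
) -> LatentFactors:
    """Exact proximal update of every TF feature row (genes/TFs exchanged)."""
    X = factors.X
    A_bar = _reweight(pen, S, lam)
    Yn = factors.Y.copy()
    for j in range(Yn.shape[0]):
        aj = A_bar[:, j]
        G = (X * aj[:, None]).T @ X
        mu = max(2.0 * np.linalg.norm(G, "fro"), MU_MIN) if mu_y is None else mu_y
        phi = G + 0.5 * mu * np.eye(X.shape[1])
        varphi = 2.0 * ((targets.Theta[:, j] * aj) @ X) + mu * Yn[j]
        Yn[j] = solve_unit_ball_qp(phi, varphi)
    return LatentFactors(X.copy(), Yn)


def fit_cf(
    pen: PenaltyMatrices,
    h: int,
    rng: np.random.Generator,
    sweeps: int = 10,
    lam: float = 1.0,
    factors: LatentFactors | None = None,
) -> LatentFactors:
    """Pure CF fit on the priors alone (Theta = B, Omega = C).

    Used both to warm-start the joint loop and as the standalone CF
    baseline. ``lam`` only rescales the confidences; it does not change the
    constrained minimizer.
    """
    n, m = pen.B.shape
    if factors is None:
        factors = init_factors(n, m, h, rng)
    targets = CFTargets(Theta=pen.B, Omega=pen.C)
    S0 = np.zeros((n, m))
    if lam == 0:  # the prox of nothing: factors stay put
        return factors
    for _ in range(sweeps):
        factors = update_X(factors, targets, S0, pen, lam)
        factors = update_Y(factors, targets, S0, pen, lam)
    return factors
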