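"""Sparse network-component-analysis core.

Expression is modeled bilinearly, E ~ S A, where S is the weighted gene x TF
network and A the hidden per-sample TF activities. The smooth part

    H(S, A) = ||E - S A||_F^2 + lambda_A ||A||_F^2 + lambda_S ||S||_F^2

is minimized block-wise: A has a closed-form exact proximal update; S takes
a gradient step on H followed by an element-wise l0 hard threshold whose
per-pair radius c_ij folds in the CF confidences, so the expression model
acts as the gatekeeper for edges the CF component recommends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cf import LatentFactors
from .priors import PenaltyMatrices

__all__ = [
    "ProxWorkspace",
    "nca_objective",
    "update_A",
    "compute_S_threshold_inputs",
    "update_S",
]

MU_MIN = 1e-6


@dataclass
class ProxWorkspace:
    """Inputs of the S hard-threshold step."""

    mu_S: float
    U: np.ndarray  # gradient-step point S - (1/mu_S) grad_S H
    c: np.ndarray  # per-pair threshold radii, >= 0

    def __post_init__(self) -> None:
        if self.mu_S <= 0:
            raise ValueError("mu_S must be > 0")
        self.U = np.asarray(self.U, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.U.shape != self.c.shape:
            raise ValueError("U and c must share one shape")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.c))):
            raise ValueError("non-finite workspace")
        if (self.c < 0).any():
            raise ValueError("threshold radii must be >= 0")


def nca_objective(S: np.ndarray, A: np.ndarray, E: np.ndarray, lambda_A: float, lambda_S: float) -> float:
    """H(S, A) = ||E - SA||_F^2 + lambda_A ||A||_F^2 + lambda_S ||S||_F^2."""
    R = E - S @ A
    return float((R**2).sum() + lambda_A * (A**2).sum() + lambda_S * (S**2).sum())


def mu_A_of(S: np.ndarray, lambda_A: float) -> float:
    """Step constant for the A block: ||S'S + lambda_A I||_F, floored at mu_min."""
    m = S.shape[1]
    return max(float(np.linalg.norm(S.T @ S + lambda_A * np.eye(m), "fro")), MU_MIN)


def update_A(S: np.ndarray, A_prev: np.ndarray, E: np.ndarray, lambda_A: float) -> np.ndarray:
    """Closed-form exact prox of H(., S) at A_prev:

    A = (S'S + (2 lambda_A + mu_A)/2 I)^{-1} (S'E + (mu_A/2) A_prev),
    mu_A = ||S'S + lambda_A I||_F (floored so the step stays defined when S = 0).
    """
    S = np.asarray(S, dtype=float)
    A_prev = np.asarray(A_prev, dtype=float)
    m = S.shape[1]
    mu = mu_A_of(S, lambda_A)
    M = S.T @ S + 0.5 * (2.0 * lambda_A + mu) * np.eye(m)
    rhs = S.T @ E + 0.5 * mu * A_prev
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - M is PD by construction
        raise RuntimeError("singular system in A update despite regularization") from exc


def mu_S_of(A_new: np.ndarray, lambda_S: float) -> float:
    """Step constant for the S block: ||A A' + lambda_S I||_F, floored.

    This can undershoot the exact Lipschitz constant 2 ||A A' + lambda_S I||_2
    of grad_S H when the spectrum is concentrated; the outer loop therefore
    verifies descent after each S step and doubles the constant on the rare
    violation (see gpalm_fit).
    """
    m = A_new.shape[0]
    M = A_new @ A_new.T + lambda_S * np.eye(m)
    return max(float(np.linalg.norm(M, "fro")), MU_MIN)


def compute_S_threshold_inputs(
    S: np.ndarray,
    A_new: np.ndarray,
    E: np.ndarray,
    pen: PenaltyMatrices,
    factors: LatentFactors,
    lam: float,
    eta: np.ndarray | float,
    lambda_S: float,
    mu_S: float | None = None,
) -> ProxWorkspace:
    """Gradient-step point U and per-pair threshold radii c for the S update.

    U = S - (1/mu_S)(2 (S A - E) A' + 2 lambda_S S) and

    c_ij^2 = (2/mu_S) { lam [ Cbar_ij (1 - B_ij)(1 + 2(B_ij - x_i'y_j))
                              + (Cbar_ij - C_ij)(B_ij - x_i'y_j)^2 ] + eta_ij }

    with negative radicands clamped to 0 (a negative l0 price means removing
    the edge can never pay, so the edge is kept whenever U_ij != 0).
    """
    S = np.asarray(S, dtype=float)
    mu = mu_S_of(A_new, lambda_S) if mu_S is None else mu_S
    grad = 2.0 * (S @ A_new - E) @ A_new.T + 2.0 * lambda_S * S
    U = S - grad / mu
    T = factors.dot()
    D = pen.B - T
    bracket = pen.Cbar * (1.0 - pen.B) * (1.0 + 2.0 * D) + (pen.Cbar - pen.C) * D**2
    radicand = (2.0 / mu) * (lam * bracket + np.broadcast_to(np.asarray(eta, dtype=float), S.shape))
    c = np.sqrt(np.clip(radicand, 0.0, None))
    return ProxWorkspace(mu_S=mu, U=U, c=c)


def update_S(ws: ProxWorkspace) -> np.ndarray:
    """Element-wise hard threshold: S_ij = U_ij if |U_ij| > c_ij else 0.

    The measure-zero tie |U_ij| = c_ij resolves to 0 for a deterministic,
    sparser result.
    """
    return np.where(np.abs(ws.U) > ws.c, ws.U, 0.0)
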