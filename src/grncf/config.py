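"""Run configuration: every tunable of the joint model in one serializable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Hyperparameters of the coupled CF + sparse-NCA model.

    a:
        Confidence scale turning summed prior weight into the CF penalty
        C_ij = 1 + a * sum_k P_ij^k. Default 60, the value recommended for
        implicit-feedback collaborative filtering.
    h:
        Latent dimension of the gene/TF feature vectors.
    lam:
        Balance between the expression (NCA) term and the CF term.
    lambda_A, lambda_S:
        Ridge penalties on TF activities A and network weights S.
    eta:
        Scalar l0 price per retained edge (expanded to eta_ij uniformly).
    cbar_scale:
        Scale of the elevated confidence Cbar assigned to edges confirmed by
        the expression model.
    warm_start_sweeps:
        CF-only alternating sweeps (targets built from the priors alone)
        before the joint loop.
    max_iter, tol:
        Outer-loop cap and relative-objective convergence tolerance (the loop
        stops after 3 consecutive sub-tol drops).
    seed:
        Seed for factor initialization.
    center_expression:
        Subtract each gene's mean expression before fitting (the bilinear
        model has no intercept).
    """

    a: float = 60.0
    h: int = 50
    lam: float = 1.0
    lambda_A: float = 0.1
    lambda_S: float = 0.1
    eta: float = 1.0
    cbar_scale: float = 1.0
    warm_start_sweeps: int = 10
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0
    center_expression: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.h < 1:
            raise ValueError("h must be >= 1")
        for name in ("lam", "lambda_A", "lambda_S", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cbar_scale <= 0:
            raise ValueError("cbar_scale must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        for name in ("a", "lam", "lambda_A", "lambda_S", "eta", "cbar_scale", "tol"):
            import math

            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
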