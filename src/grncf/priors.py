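"""Prior networks and the CF penalty/observation matrices derived from them.

A prior network is any incomplete, noisy evidence source for TF-gene
regulation (motif scans, ChIP peaks, knockdown effects, co-expression),
encoded as a non-negative weight matrix on a shared gene x TF index. The CF
component consumes the priors only through three derived matrices:

* ``C``  — per-pair confidence penalty, ``C_ij = 1 + a * sum_k P_ij^k``;
* ``B``  — binary observation indicator, ``B_ij = 1`` iff any prior supports
  the pair;
* ``Cbar`` — the elevated penalty applied to pairs confirmed by the
  expression model, so confirmed edges are retained by the factorization
  even when no prior saw them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import EdgeList, ExpressionMatrix, RANKING_COLUMNS

__all__ = [
    "PriorSet",
    "PenaltyMatrices",
    "build_prior_set",
    "build_penalties",
    "priorsum_baseline",
    "build_coexpression_prior",
]


@dataclass
class PriorSet:
    """d prior weight matrices on one shared (genes, tfs) index.

    Each prior is max-rescaled to [0, 1] at construction so heterogeneous
    score scales (peak scores, motif scores, correlations) contribute
    comparably to the summed confidence.
    """

    matrices: list[np.ndarray]
    genes: list[str]
    tfs: list[str]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("PriorSet needs at least one prior network")
        shape = (len(self.genes), len(self.tfs))
        rescaled = []
        for k, P in enumerate(self.matrices):
            P = np.asarray(P, dtype=float)
            if P.shape != shape:
                raise ValueError(f"prior {k} has shape {P.shape}, expected {shape}")
            if not np.all(np.isfinite(P)):
                raise ValueError(f"prior {k} has non-finite entries")
            if (P < 0).any():
                raise ValueError(f"prior {k} has negative entries")
            peak = P.max()
            rescaled.append(P / peak if peak > 0 else P.copy())
        self.matrices = rescaled

    @property
    def d(self) -> int:
        return len(self.matrices)

    def total(self) -> np.ndarray:
        """sum_k P^k on the shared index."""
        return np.sum(self.matrices, axis=0)


@dataclass
class PenaltyMatrices:
    C: np.ndarray
    Cbar: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.Cbar = np.asarray(self.Cbar, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if not (self.C.shape == self.Cbar.shape == self.B.shape):
            raise ValueError("C, Cbar, B must share one shape")
        if (self.C < 1).any() or (self.Cbar < 1).any():
            raise ValueError("penalties must be >= 1")
        if not np.isin(self.B, (0.0, 1.0)).all():
            raise ValueError("B must be binary")


def build_prior_set(
    priors: Iterable[EdgeList],
    genes: Sequence[str] | None = None,
    tfs: Sequence[str] | None = None,
) -> PriorSet:
    """Union prior edge lists onto one shared index.

    ``genes``/``tfs`` fix the index explicitly (pairs outside it are
    dropped); by default the sorted union of ids observed across the priors
    is used, with zero-filled rows/columns where a prior lacks coverage.
    """
    priors = list(priors)
    if not priors:
        raise ValueError("no prior networks given")
    if genes is None:
        genes = sorted({g for p in priors for g in p.records["gene"]})
    if tfs is None:
        tfs = sorted({t for p in priors for t in p.records["tf"]})
    mats = [p.to_matrix(genes, tfs) for p in priors]
    return PriorSet(mats, list(genes), list(tfs))


def build_penalties(priors: PriorSet, a: float = 60.0, cbar_scale: float = 1.0) -> PenaltyMatrices:
    """Derive (C, Cbar, B) from the summed priors.

    ``Cbar_ij = 1 + a * cbar_scale * max(sum_k P_ij^k, 1/d)`` so a pair
    confirmed by the expression model always carries above-baseline
    confidence even when no prior supports it.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if cbar_scale <= 0:
        raise ValueError("cbar_scale must be > 0")
    total = priors.total()
    C = 1.0 + a * total
    B = (total != 0).astype(float)
    Cbar = 1.0 + a * cbar_scale * np.maximum(total, 1.0 / priors.d)
    return PenaltyMatrices(C=C, Cbar=Cbar, B=B)


def priorsum_baseline(priors: PriorSet) -> pd.DataFrame:
    """Rank pairs by summed prior weight; unsupported pairs get no prediction."""
    total = priors.total()
    ii, jj = np.nonzero(total)
    df = pd.DataFrame(
        {
            "gene": [priors.genes[i] for i in ii],
            "tf": [priors.tfs[j] for j in jj],
            "score": total[ii, jj],
        }
    )
    return df.sort_values(["score", "gene", "tf"], ascending=[False, True, True], kind="mergesort").reset_index(
        drop=True
    )[list(RANKING_COLUMNS)]


def build_coexpression_prior(
    expr: ExpressionMatrix,
    tf_ids: Sequence[str],
    threshold: float = 0.7,
    logger=None,
) -> EdgeList:
    """Pearson co-expression prior: keep (gene, tf) pairs with r >= threshold.

    TFs must be rows of the expression matrix; self-pairs are excluded, and
    zero-variance rows are skipped (logged if a logger is given).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [t for t in tf_ids if t not in idx]
    if missing:
        raise ValueError(f"TFs not in expression matrix: {missing[:5]}")
    V = expr.values - expr.values.mean(axis=1, keepdims=True)
    sd = np.sqrt((V**2).sum(axis=1))
    ok = sd > 0
    Z = np.where(ok[:, None], V / np.where(sd == 0, 1.0, sd)[:, None], 0.0)
    rows = []
    for t in tf_ids:
        j = idx[t]
        if not ok[j]:
            if logger is not None:
                logger.warning("constant expression for TF %s; skipped", t)
            continue
        r = Z @ Z[j]
        for i, g in enumerate(expr.gene_ids):
            if g == t:
                continue
            if not ok[i]:
                if logger is not None:
                    logger.warning("constant expression for gene %s vs TF %s; skipped", g, t)
                continue
            if r[i] >= threshold:
                rows.append((g, t, float(np.clip(r[i], -1.0, 1.0))))
    return EdgeList(pd.DataFrame(rows, columns=["gene", "tf", "weight"]), role="prior")
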