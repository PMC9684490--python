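"""Planted-network fixture generator.

Emulates the study design every stage of the pipeline needs: a sparse
ground-truth network S_true with signed weights bounded away from zero,
hidden TF activities A_true, expression E = S_true A_true + Gaussian noise
(the generative form of the NCA model), several partially overlapping
degraded priors (each sees a random subset of the true edges plus spurious
pairs), and the gold standard = support(S_true).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import GoldStandard
from .io import EdgeList, ExpressionMatrix, write_edge_list
from .priors import PriorSet

__all__ = ["SimSpec", "SimBundle", "simulate", "write_bundle"]


@dataclass
class SimSpec:
    """Generator knobs; the defaults are the study conditions used throughout.

    density: fraction of the n x m pairs planted as true edges.
    noise_sd: sd of the additive Gaussian expression noise (activity scale 1).
    prior_recall: probability each prior observes a given true edge.
    prior_fpr: probability a non-edge leaks into a prior as a spurious pair.
    """

    n_genes: int = 60
    m_tfs: int = 10
    l_samples: int = 30
    density: float = 0.1
    noise_sd: float = 0.5
    prior_recall: float = 0.7
    prior_fpr: float = 0.02
    n_priors: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.m_tfs, self.l_samples, self.n_priors) < 1:
            raise ValueError("sizes must be >= 1")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.prior_recall <= 1):
            raise ValueError("prior_recall must be in [0, 1]")
        if not (0 <= self.prior_fpr < 1):
            raise ValueError("prior_fpr must be in [0, 1)")
        if self.density * self.n_genes * self.m_tfs < 1:
            raise ValueError("expected planted network is empty")


@dataclass
class SimBundle:
    spec: SimSpec
    S_true: np.ndarray
    A_true: np.ndarray
    expression: ExpressionMatrix
    priors: PriorSet
    gold: GoldStandard

    @property
    def genes(self) -> list[str]:
        return self.priors.genes

    @property
    def tfs(self) -> list[str]:
        return self.priors.tfs


def simulate(spec: SimSpec) -> SimBundle:
    """Draw one reproducible bundle from ``spec.seed``.

    One seed stream per component (network, activities, noise, each prior)
    so e.g. changing ``n_priors`` does not perturb the expression draw.
    """
    n, m, l = spec.n_genes, spec.m_tfs, spec.l_samples
    ss = np.random.SeedSequence(spec.seed)
    r_net, r_act, r_noise, r_prior = [np.random.default_rng(c) for c in ss.spawn(4)]
    prior_rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(spec.seed + 1).spawn(spec.n_priors)]

    support = r_net.random((n, m)) < spec.density
    if not support.any():
        raise ValueError("no edge planted; raise density or sizes")
    # signed weights with |w| in [0.5, 2] so support is unambiguous under noise
    mag = r_net.uniform(0.5, 2.0, (n, m))
    sign = np.where(r_net.random((n, m)) < 0.5, -1.0, 1.0)
    S_true = np.where(support, sign * mag, 0.0)

    A_true = r_act.standard_normal((m, l))
    E = S_true @ A_true + spec.noise_sd * r_noise.standard_normal((n, l))

    genes = [f"g{i:04d}" for i in range(n)]
    tfs = [f"tf{j:03d}" for j in range(m)]
    samples = [f"s{k:03d}" for k in range(l)]
    expr = ExpressionMatrix(E, genes, samples)

    mats = []
    for rng in prior_rngs:
        seen = support & (rng.random((n, m)) < spec.prior_recall)
        false = (~support) & (rng.random((n, m)) < spec.prior_fpr)
        weights = rng.uniform(0.2, 1.0, (n, m))
        mats.append(np.where(seen | false, weights, 0.0))
    priors = PriorSet(mats, genes, tfs)

    ii, jj = np.nonzero(support)
    gold = GoldStandard(
        pd.DataFrame({"gene": [genes[i] for i in ii], "tf": [tfs[j] for j in jj]}),
        provenance="planted",
    )
    return SimBundle(spec=spec, S_true=S_true, A_true=A_true, expression=expr, priors=priors, gold=gold)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write the bundle as the standard TSVs consumed by fit/evaluate."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.expression.to_frame().to_csv(out / "expression.tsv", sep="\t")
    for k, P in enumerate(bundle.priors.matrices):
        ii, jj = np.nonzero(P)
        df = pd.DataFrame(
            {
                "gene": [bundle.genes[i] for i in ii],
                "tf": [bundle.tfs[j] for j in jj],
                "weight": P[ii, jj],
            }
        )
        write_edge_list(EdgeList(df, role="prior"), out / f"prior_{k + 1}.tsv")
    gold = bundle.gold.edges.assign(weight=1.0)
    write_edge_list(EdgeList(gold, role="gold_standard"), out / "gold.tsv")
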