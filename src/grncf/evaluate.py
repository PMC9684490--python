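"""Average Rank Score (ARS) benchmarking of ranked edge predictions.

For each gene, the TFs a method predicts are ordered by confidence and the
percentile-ranking r_ij of TF j within the ordered list of all m TFs is
0% for the top prediction, 100·(pos-1)/(m-1) in general, and 100% for a TF
the method never predicts. The ARS averages these percentiles over the
gold-standard edges, first within each gene, then across genes that have at
least one gold edge; 50% is the level of a uniform random ranking and lower
is better. The TF-centric score is the transpose analogue (genes ranked
within each TF's target list).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import RANKING_COLUMNS

__all__ = [
    "GoldStandard",
    "RankReport",
    "percentile_ranks",
    "ars",
    "evaluate_ranking",
    "random_baseline",
    "gold_from_de",
]


@dataclass
class GoldStandard:
    """Benchmark edge set, used only for evaluation, never for fitting."""

    edges: pd.DataFrame  # columns: gene, tf
    provenance: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.edges)
        df = df[["gene", "tf"]].astype(str).drop_duplicates().reset_index(drop=True)
        if df.empty:
            raise ValueError("gold standard must contain at least one edge")
        self.edges = df

    @property
    def genes(self) -> list[str]:
        return sorted(self.edges["gene"].unique())

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def indicator(self, genes: Sequence[str], tfs: Sequence[str]) -> np.ndarray:
        gi = {g: i for i, g in enumerate(genes)}
        ti = {t: j for j, t in enumerate(tfs)}
        I = np.zeros((len(genes), len(tfs)))
        for g, t in self.edges.itertuples(index=False):
            if g in gi and t in ti:
                I[gi[g], ti[t]] = 1.0
        return I


@dataclass
class RankReport:
    axis: str  # "gene" or "tf"
    percentiles: pd.DataFrame  # genes x tfs, percent
    per_entity: pd.Series  # mean percentile over gold edges, per entity with gold
    overall: float  # percent


def _universe(prediction: pd.DataFrame, gold: GoldStandard) -> tuple[list[str], list[str]]:
    """Evaluation index: gold's genes/TFs unioned with the prediction's.

    Fixed before ranking so a method is not rewarded for omitting hard TFs.
    """
    genes = sorted(set(gold.genes) | set(prediction["gene"].astype(str)))
    tfs = sorted(set(gold.tfs) | set(prediction["tf"].astype(str)))
    return genes, tfs


def percentile_ranks(
    prediction: pd.DataFrame,
    axis: str,
    genes: Sequence[str],
    tfs: Sequence[str],
) -> pd.DataFrame:
    """Percentile-ranking matrix (genes x tfs, in percent).

    ``axis="gene"``: TFs are ranked within each gene's list; ``axis="tf"``:
    genes are ranked within each TF's list. Predicted entries get
    100·(pos-1)/(M-1) with tied scores receiving the mean of their
    positions (M = size of the ranked universe); absent entries get 100%.
    """
    if axis not in ("gene", "tf"):
        raise ValueError("axis must be 'gene' or 'tf'")
    df = pd.DataFrame(prediction, columns=list(RANKING_COLUMNS)).copy()
    df["gene"] = df["gene"].astype(str)
    df["tf"] = df["tf"].astype(str)
    if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
        raise ValueError("prediction scores must be finite")
    M = len(tfs) if axis == "gene" else len(genes)
    if M < 2:
        raise ValueError("ranking needs at least 2 candidates")
    R = pd.DataFrame(100.0, index=list(genes), columns=list(tfs))
    group_key, item_key = ("gene", "tf") if axis == "gene" else ("tf", "gene")
    known = {"gene": set(genes), "tf": set(tfs)}
    df = df[df["gene"].isin(known["gene"]) & df["tf"].isin(known["tf"])]
    for key, sub in df.groupby(group_key, sort=False):
        pos = rankdata(-sub["score"].to_numpy(dtype=float), method="average")
        r = 100.0 * (pos - 1.0) / (M - 1.0)
        if axis == "gene":
            R.loc[key, sub[item_key].to_numpy()] = r
        else:
            R.loc[sub[item_key].to_numpy(), key] = r
    return R


def ars(percentiles: pd.DataFrame, gold: GoldStandard, axis: str) -> RankReport:
    """Average the percentile matrix over the gold edges.

    Per-entity means are taken only over that entity's gold edges; the
    overall score averages entities possessing at least one gold edge.
    """
    I = gold.indicator(list(percentiles.index), list(percentiles.columns))
    R = percentiles.to_numpy(dtype=float)
    if axis == "gene":
        counts = I.sum(axis=1)
        sums = (R * I).sum(axis=1)
        labels = list(percentiles.index)
    elif axis == "tf":
        counts = I.sum(axis=0)
        sums = (R * I).sum(axis=0)
        labels = list(percentiles.columns)
    else:
        raise ValueError("axis must be 'gene' or 'tf'")
    has = counts > 0
    if not has.any():
        raise ValueError("gold standard shares no entity with the evaluation index")
    per = pd.Series(sums[has] / counts[has], index=[l for l, h in zip(labels, has) if h])
    return RankReport(axis=axis, percentiles=percentiles, per_entity=per, overall=float(per.mean()))


def evaluate_ranking(prediction: pd.DataFrame, gold: GoldStandard, axis: str = "gene") -> RankReport:
    """Convenience wrapper: build the universe, rank, and average."""
    genes, tfs = _universe(prediction, gold)
    R = percentile_ranks(prediction, axis, genes, tfs)
    return ars(R, gold, axis)


def random_baseline(genes: Sequence[str], tfs: Sequence[str], seed: int) -> pd.DataFrame:
    """Uniform(0, 1) confidence for every pair — the ARS ~ 50% reference."""
    rng = np.random.default_rng(seed)
    n, m = len(genes), len(tfs)
    return pd.DataFrame(
        {
            "gene": np.repeat(list(genes), m),
            "tf": np.tile(list(tfs), n),
            "score": rng.uniform(0.0, 1.0, n * m),
        }
    )[list(RANKING_COLUMNS)]


def gold_from_de(
    de_table: pd.DataFrame,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    provenance: str = "differential-expression",
    logger=None,
) -> GoldStandard:
    """Knockdown-style gold standard from a differential-expression table.

    A (gene, tf) pair becomes a gold edge if |log2fc| > lfc_cut OR
    padj < padj_cut. Rows with missing padj are kept only on the fold-change
    condition (and logged).
    """
    df = pd.DataFrame(de_table, columns=["gene", "tf", "log2fc", "padj"]).copy()
    lfc = pd.to_numeric(df["log2fc"], errors="raise")
    padj = pd.to_numeric(df["padj"], errors="coerce")
    missing = padj.isna()
    if missing.any() and logger is not None:
        logger.warning("%d DE rows lack padj; kept on fold change only", int(missing.sum()))
    keep = (lfc.abs() > lfc_cut) | (~missing & (padj < padj_cut))
    return GoldStandard(df.loc[keep, ["gene", "tf"]], provenance=provenance)
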