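"""Tabular readers/writers for expression matrices and TF-gene edge lists.

All exchange formats are plain TSV: expression is genes x samples with a
header row of sample ids and gene ids in the first column; edge lists are
``gene<TAB>tf<TAB>weight`` (weight optional, defaulting to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "read_expression",
    "read_edge_list",
    "write_edge_list",
    "write_ranked_edges",
]

RANKING_COLUMNS = ("gene", "tf", "score")


@dataclass
class ExpressionMatrix:
    """Expression of ``n`` genes across ``l`` samples (arbitrary units)."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, l = self.values.shape
        if n < 1 or l < 1:
            raise ValueError("expression matrix must be at least 1x1")
        if len(self.gene_ids) != n or len(self.sample_ids) != l:
            raise ValueError("id lists do not match matrix shape")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def centered(self) -> "ExpressionMatrix":
        """Return a copy with each gene row mean-subtracted."""
        v = self.values - self.values.mean(axis=1, keepdims=True)
        return ExpressionMatrix(v, list(self.gene_ids), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class EdgeList:
    """Weighted TF-gene pairs with a role tag (prior / gold_standard / prediction)."""

    records: pd.DataFrame  # columns: gene, tf, weight
    role: str = "prior"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["gene", "tf", "weight"]).copy()
        df["gene"] = df["gene"].astype(str)
        df["tf"] = df["tf"].astype(str)
        df["weight"] = df["weight"].astype(float)
        if len(df) and not np.all(np.isfinite(df["weight"].to_numpy())):
            raise ValueError("edge weights must be finite")
        if len(df) and (df["weight"].to_numpy() < 0).any():
            bad = df.loc[df["weight"] < 0].iloc[0]
            raise ValueError(f"negative weight for pair ({bad['gene']}, {bad['tf']})")
        dup = df.duplicated(subset=["gene", "tf"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValueError(f"duplicate pair ({bad['gene']}, {bad['tf']})")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def tfs(self) -> list[str]:
        return sorted(self.records["tf"].unique())

    def to_matrix(self, genes: Sequence[str], tfs: Sequence[str]) -> np.ndarray:
        """Dense weight matrix on a given (genes, tfs) index; missing pairs are 0."""
        gi = {g: i for i, g in enumerate(genes)}
        ti = {t: j for j, t in enumerate(tfs)}
        M = np.zeros((len(genes), len(tfs)))
        for g, t, w in self.records.itertuples(index=False):
            if g in gi and t in ti:
                M[gi[g], ti[t]] = w
        return M


def read_expression(path: str | Path, center: bool = False) -> ExpressionMatrix:
    """Load a genes x samples TSV; optionally subtract each gene's mean."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    em = ExpressionMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))
    return em.centered() if center else em


def read_edge_list(path: str | Path, role: str = "prior") -> EdgeList:
    """Load ``gene<TAB>tf[<TAB>weight]`` records; a missing weight column means 1."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return EdgeList(pd.DataFrame(columns=["gene", "tf", "weight"]), role=role)
    # tolerate a header row naming the columns
    first = [str(v).lower() for v in df.iloc[0]]
    if first[0] in {"gene", "gene_id"}:
        df = df.iloc[1:]
    if df.shape[1] == 2:
        df = df.assign(weight=1.0)
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
    df.columns = ["gene", "tf", "weight"]
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    return EdgeList(df, role=role)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    edges.records.to_csv(path, sep="\t", header=False, index=False)


def write_ranked_edges(ranking: pd.DataFrame, path: str | Path) -> None:
    """Write a ``gene/tf/score`` ranking as TSV, best first.

    Sorted by descending score; ties broken by (gene, tf) lexicographic order
    so output is byte-stable.
    """
    df = pd.DataFrame(ranking, columns=list(RANKING_COLUMNS))
    df = df.sort_values(["score", "gene", "tf"], ascending=[False, True, True], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_ranked_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tf": str})
    return df[list(RANKING_COLUMNS)]
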