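"""HR-conditioned step-function gene scoring.

Each key gene's expression row is centered on its median, then binarized
into the step matrix D: for a gene whose univariate hazard ratio exceeds 1,
D marks the samples at or above the median (the risk-increasing side); for
HR < 1 it marks the samples below the median.  The association matrix
E = D C^T couples that risk pattern with the CNN feature-weight matrix C,
and each gene's score GS is the mean of its row of E.  Genes are ranked by
descending score to pick candidates for Cox screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnn_features import FeatureWeightMatrix

__all__ = [
    "CenteredExpression",
    "StepMatrix",
    "GeneScores",
    "median_center",
    "step_matrix",
    "association_matrix",
    "gene_scores",
    "top_k",
]


@dataclass
class CenteredExpression:
    """Gene-by-sample matrix with every row median-centered.

    Even sample counts use the midpoint of the two central order statistics,
    so a centered row's median is exactly zero.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        med = np.median(self.values.to_numpy(), axis=1)
        if len(med) and np.abs(med).max() > 1e-10:
            raise ValueError("rows are not median-centered")


@dataclass
class StepMatrix:
    """Binary gene-by-sample matrix D (entries 0/1)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("step matrix entries must be 0/1")


@dataclass
class GeneScores:
    gene_ids: list[str]
    score: np.ndarray
    rank: list[str]  # gene ids in descending-score order


def median_center(values: pd.DataFrame) -> CenteredExpression:
    """Subtract each gene's median across samples."""
    arr = values.to_numpy(dtype=float)
    centered = arr - np.median(arr, axis=1, keepdims=True)
    return CenteredExpression(
        pd.DataFrame(centered, index=values.index, columns=values.columns)
    )


def step_matrix(centered: CenteredExpression, hr: pd.Series) -> StepMatrix:
    """Binarize B by the gene's hazard-ratio direction.

    HR > 1: D_ij = 1 iff B_ij >= 0 (at/above the median is the risky side);
    HR < 1: D_ij = 1 iff B_ij < 0.  HR exactly 1 falls to the first branch.
    """
    b = centered.values
    missing = [g for g in b.index if g not in hr.index]
    if missing:
        raise ValueError(f"no hazard ratio for gene(s) {missing[:5]}")
    hr = hr.reindex(b.index).astype(float)
    bad = hr.index[~np.isfinite(hr) | (hr <= 0)]
    if len(bad):
        raise ValueError(f"non-positive or non-finite HR for gene(s) {list(bad[:5])}")
    nonneg = b.to_numpy() >= 0
    risky_high = (hr.to_numpy() >= 1.0)[:, None]
    d = np.where(risky_high, nonneg, ~nonneg).astype(float)
    return StepMatrix(pd.DataFrame(d, index=b.index, columns=b.columns))


def association_matrix(d: StepMatrix, c: FeatureWeightMatrix) -> pd.DataFrame:
    """E = D C^T: genes x features, E[g, f] = sum_s D[g, s] * C[f, s]."""
    d_samples = list(d.values.columns)
    if d_samples != list(c.sample_ids):
        extra = set(d_samples) ^ set(c.sample_ids)
        raise ValueError(
            f"step matrix and weight matrix disagree on samples: {sorted(extra)[:6]}"
            if extra
            else "step matrix and weight matrix order samples differently"
        )
    e = d.values.to_numpy() @ c.values.T
    return pd.DataFrame(e, index=d.values.index)


def gene_scores(e: pd.DataFrame) -> GeneScores:
    """GS_i = mean of gene i's row of E; rank descending, ties by gene id."""
    arr = e.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("association matrix must be finite")
    gs = arr.mean(axis=1) if arr.shape[1] else np.zeros(len(e))
    order = sorted(range(len(e)), key=lambda i: (-gs[i], str(e.index[i])))
    return GeneScores(
        gene_ids=[str(g) for g in e.index],
        score=gs,
        rank=[str(e.index[i]) for i in order],
    )


def top_k(scores: GeneScores, k: int) -> list[str]:
    """First ``k`` genes of the ranking."""
    if k > len(scores.rank):
        raise ValueError(f"k={k} exceeds the {len(scores.rank)} scored genes")
    return scores.rank[:k]
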