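"""Differential expression / methylation calling and the key-gene intersection.

A gene is a DEG when |log2 fold change| >= 1.5 (inclusive) with BH-adjusted
p < 0.05; a probe is a DMP when |delta beta| > 0.2 (strict) with BH-adjusted
p < 0.05.  Key genes are the DEGs supported by at least one passing DMP
through the probe-to-gene map.  Per-feature p-values come from a Welch
t-test on log2(x+1) expression (respectively raw beta values) — a documented
stand-in for the dedicated count/array pipelines used on real cohorts —
or can be supplied pre-computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffResult",
    "call_degs",
    "call_dmps",
    "intersect_key_genes",
    "results_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffResult:
    feature_id: str
    effect: float     # log2 FC for genes, delta beta for probes
    p_raw: float
    p_adj: float
    passed: bool


def _group_masks(groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    tumor = g == "tumor"
    normal = g == "normal"
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("need at least 2 samples per group for differential calling")
    return tumor, normal


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; constant rows yield p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    return np.where(np.isfinite(p), p, 1.0)


def call_degs(
    values: pd.DataFrame,
    groups: pd.Series,
    logfc_cut: float = 1.5,
    alpha: float = 0.05,
    p_values: np.ndarray | None = None,
) -> list[DiffResult]:
    """Differential expression on a gene-by-sample matrix of non-negative values.

    Effect size is log2 of the tumor/normal ratio of means with a pseudo-count
    of 1, so zero-expression genes stay defined. ``p_values`` overrides the
    built-in Welch test (e.g. with externally computed statistics).
    """
    if values.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    tumor, normal = _group_masks(groups)
    mat = values.to_numpy(dtype=float)
    log_t = np.log2(mat[:, tumor] + 1.0)
    log_n = np.log2(mat[:, normal] + 1.0)
    effect = np.log2(mat[:, tumor].mean(axis=1) + 1.0) - np.log2(
        mat[:, normal].mean(axis=1) + 1.0
    )
    p_raw = np.asarray(p_values, float) if p_values is not None else _welch_p(log_t, log_n)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    passed = (np.abs(effect) >= logfc_cut) & (p_adj < alpha)
    return [
        DiffResult(str(g), float(e), float(pr), float(pa), bool(ok))
        for g, e, pr, pa, ok in zip(values.index, effect, p_raw, p_adj, passed)
    ]


def call_dmps(
    values: pd.DataFrame,
    groups: pd.Series,
    delta_cut: float = 0.2,
    alpha: float = 0.05,
    p_values: np.ndarray | None = None,
) -> list[DiffResult]:
    """Differential methylation on a probe-by-sample beta matrix.

    Effect size is the tumor-minus-normal difference of mean beta; the
    magnitude cutoff is strict (``> delta_cut``).
    """
    if values.index.duplicated().any():
        raise ValueError("duplicate probe ids")
    mat = values.to_numpy(dtype=float)
    if mat.min() < 0 or mat.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    tumor, normal = _group_masks(groups)
    effect = mat[:, tumor].mean(axis=1) - mat[:, normal].mean(axis=1)
    p_raw = (
        np.asarray(p_values, float)
        if p_values is not None
        else _welch_p(mat[:, tumor], mat[:, normal])
    )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    passed = (np.abs(effect) > delta_cut) & (p_adj < alpha)
    return [
        DiffResult(str(p), float(e), float(pr), float(pa), bool(ok))
        for p, e, pr, pa, ok in zip(values.index, effect, p_raw, p_adj, passed)
    ]


def intersect_key_genes(
    degs: list[DiffResult],
    dmps: list[DiffResult],
    probe_map: pd.DataFrame,
) -> list[str]:
    """Sorted DEG genes supported by at least one passing DMP probe.

    ``probe_map`` has columns ``probe`` and ``gene``, one row per mapping; a
    probe annotated to several genes supports each of them.  Passing probes
    absent from the map are dropped with a warning.
    """
    deg_genes = {r.feature_id for r in degs if r.passed}
    dmp_probes = {r.feature_id for r in dmps if r.passed}
    mapped = probe_map[probe_map["probe"].isin(dmp_probes)]
    unmapped = dmp_probes - set(mapped["probe"])
    if unmapped:
        logger.warning(
            "%d passing DMP probes have no gene mapping and were dropped",
            len(unmapped),
        )
    dmp_genes = set(mapped["gene"])
    return sorted(deg_genes & dmp_genes)


def results_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Tabular view (feature, effect, p_raw, p_adj, passed) for TSV export."""
    return pd.DataFrame(
        [(r.feature_id, r.effect, r.p_raw, r.p_adj, r.passed) for r in results],
        columns=["feature", "effect", "p_raw", "p_adj", "passed"],
    )
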