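"""Count normalization, stage-to-stage correlation, and per-gene-set
expression summaries.

Normalization is median-of-ratios: each library's size factor is the median,
over genes expressed in every stage, of the ratio of that gene's count to its
geometric mean across stages (the pseudo-reference).  Stage similarity is
Pearson correlation on log2(normalized + 1).  Gene-set expression
distributions are compared pairwise with two-sample Kolmogorov-Smirnov
tests, with a significance grid at p < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CountTable

logger = logging.getLogger("locaset")

MIN_SET_SIZE_FOR_KS = 8
KS_ALPHA = 0.01


def compute_size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors, one per stage/library.

    Genes with a zero in any stage are excluded from the pseudo-reference.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two stages")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every stage")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors.name = "size_factor"
    return factors


def normalize(table: CountTable) -> CountTable:
    """Attach normalized counts (raw / size factor) to the table."""
    factors = compute_size_factors(table)
    table.normalized = table.counts / factors
    return table


@dataclass(frozen=True)
class StageCorrelation:
    stage_a: str
    stage_b: str
    pearson_r: float
    n_genes: int


def stage_correlation(
    table: CountTable,
    stage_a: str,
    stage_b: str,
    detection_threshold: float = 0.0,
    log_transform: bool = True,
) -> StageCorrelation:
    """Pearson correlation of two stages on log2(normalized + 1), over genes
    detected (normalized count > threshold) in at least one of the two."""
    if table.normalized is None:
        raise ValueError("normalize the table first")
    x = table.normalized[stage_a]
    y = table.normalized[stage_b]
    detected = (x > detection_threshold) | (y > detection_threshold)
    x, y = x[detected], y[detected]
    if len(x) < 3:
        raise ValueError("fewer than 3 genes detected in the stage pair")
    if log_transform:
        x, y = np.log2(x + 1), np.log2(y + 1)
    r, _ = stats.pearsonr(x, y)
    return StageCorrelation(stage_a, stage_b, float(r), int(len(x)))


@dataclass
class SetExpressionSummary:
    label: str
    per_gene_median: pd.Series     # median normalized expression per gene
    set_median: float
    n_genes: int


def set_expression_summary(
    table: CountTable,
    gene_sets: Mapping[str, Sequence[str]],
    stage: str | None = None,
) -> tuple[dict[str, SetExpressionSummary], pd.DataFrame, pd.DataFrame]:
    """Per-set expression summaries plus a pairwise KS comparison grid.

    Per-gene expression is the normalized count at ``stage``, or the median
    across stages when ``stage`` is None.  Returns (summaries, ks_p_values,
    significant) where ``significant`` marks p < 0.01 off-diagonal cells.
    Sets smaller than 8 genes are summarized but skipped in the KS grid.
    """
    if table.normalized is None:
        raise ValueError("normalize the table first")
    norm = table.normalized
    overlap = _report_overlap(gene_sets)
    if overlap:
        logger.info("gene sets overlap: %s", overlap)

    summaries: dict[str, SetExpressionSummary] = {}
    for label, genes in gene_sets.items():
        genes = [g for g in genes if g in norm.index]
        sub = norm.loc[genes]
        per_gene = sub[stage] if stage is not None else sub.median(axis=1)
        summaries[label] = SetExpressionSummary(
            label=label,
            per_gene_median=per_gene,
            set_median=float(per_gene.median()) if len(per_gene) else float("nan"),
            n_genes=len(per_gene),
        )

    labels = list(gene_sets)
    ks_p = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        ks_p.loc[la, la] = 1.0
        for lb in labels[i + 1 :]:
            va = summaries[la].per_gene_median
            vb = summaries[lb].per_gene_median
            if len(va) < MIN_SET_SIZE_FOR_KS or len(vb) < MIN_SET_SIZE_FOR_KS:
                logger.warning("KS skipped for (%s, %s): set smaller than %d",
                               la, lb, MIN_SET_SIZE_FOR_KS)
                continue
            p = float(stats.ks_2samp(va, vb).pvalue)
            ks_p.loc[la, lb] = p
            ks_p.loc[lb, la] = p
    significant = (ks_p < KS_ALPHA).fillna(False)
    np.fill_diagonal(significant.values, False)
    return summaries, ks_p, significant


def _report_overlap(gene_sets: Mapping[str, Sequence[str]]) -> dict[tuple[str, str], int]:
    labels = list(gene_sets)
    out = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            n = len(set(gene_sets[la]) & set(gene_sets[lb]))
            if n:
                out[(la, lb)] = n
    return out
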