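"""Gene-level expression screening: TPM normalisation, differential
expression, candidate set intersections, and over-representation testing.

Expression matrices are pandas DataFrames (genes x samples) of TPM values;
each sample column of a valid matrix sums to one million (within 0.1%).
Differential expression is tested on the log2(TPM + 1) scale with a
two-sided Wilcoxon rank-sum test; the fold change is the difference of
group means on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .config import ScreenThresholds, log_funnel

TPM_TOTAL = 1e6


def validate_tpm(matrix: pd.DataFrame, rel_tol: float = 1e-3) -> None:
    """Check TPM contract: non-negative, per-sample sum = 1e6 within rel_tol."""
    if (matrix.values < 0).any():
        raise ValueError("negative TPM values")
    sums = matrix.sum(axis=0)
    bad = sums[(sums - TPM_TOTAL).abs() > rel_tol * TPM_TOTAL]
    if len(bad):
        raise ValueError(
            f"samples whose TPM does not sum to 1e6: {list(bad.index[:5])}")


def log_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(TPM + 1); zero maps to zero."""
    if (matrix.values < 0).any():
        raise ValueError("negative TPM values")
    return np.log2(matrix + 1.0)


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p: float
    is_de: bool


def differential_expression(log_matrix: pd.DataFrame, labels: pd.Series,
                            thresholds: ScreenThresholds | None = None,
                            ) -> list[DEResult]:
    """Tumor-vs-normal differential expression on the log2(TPM+1) scale.

    ``labels`` maps sample -> {"tumor", "normal"}; both groups need >= 2
    samples.  log2FC = mean(tumor) - mean(normal); p from a two-sided
    Wilcoxon rank-sum (Mann-Whitney U) test.  ``is_de`` applies the strict
    thresholds |log2FC| > de_abs_log2fc AND p < de_p.
    """
    thresholds = thresholds or ScreenThresholds()
    labels = labels.reindex(log_matrix.columns)
    tumor_cols = labels.index[labels == "tumor"]
    normal_cols = labels.index[labels == "normal"]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    tumor = log_matrix[tumor_cols].values
    normal = log_matrix[normal_cols].values
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    # vectorised rank-sum across genes
    _, pvals = mannwhitneyu(tumor, normal, axis=1, alternative="two-sided")
    results = [
        DEResult(gene=g, log2fc=float(fc), p=float(p),
                 is_de=bool(abs(fc) > thresholds.de_abs_log2fc
                            and p < thresholds.de_p))
        for g, fc, p in zip(log_matrix.index, log2fc, pvals)
    ]
    log_funnel("differential expression", len(results),
               sum(r.is_de for r in results),
               f"|log2FC| > {thresholds.de_abs_log2fc}, p < {thresholds.de_p}")
    return results


def intersect_candidates(sgenes: set[str], de_genes: set[str],
                         splicing_factors: set[str]) -> pd.DataFrame:
    """Three-way intersection with per-filter provenance flags.

    Returns a DataFrame indexed by every gene in the union, with boolean
    columns ``is_sgene`` / ``is_de`` / ``is_splicing_factor`` and
    ``candidate`` (all three true).  Order-invariant.
    """
    sgenes, de_genes, splicing_factors = (
        set(sgenes), set(de_genes), set(splicing_factors))
    union = sorted(sgenes | de_genes | splicing_factors)
    df = pd.DataFrame(index=pd.Index(union, name="gene"))
    df["is_sgene"] = [g in sgenes for g in union]
    df["is_de"] = [g in de_genes for g in union]
    df["is_splicing_factor"] = [g in splicing_factors for g in union]
    df["candidate"] = df.is_sgene & df.is_de & df.is_splicing_factor
    log_funnel("candidate intersection", len(union), int(df.candidate.sum()))
    return df


def dual_function_screen(splice_altered: set[str], immune_set: set[str],
                         malignancy_set: set[str]) -> pd.DataFrame:
    """Dual-function (immune x malignancy) screen of splice-altered genes.

    Core candidates are genes with significant splicing alterations that are
    simultaneously immune-related and malignancy-related; set semantics, so
    duplicates in the inputs never inflate the result.
    """
    splice_altered, immune_set, malignancy_set = (
        set(splice_altered), set(immune_set), set(malignancy_set))
    union = sorted(splice_altered | immune_set | malignancy_set)
    df = pd.DataFrame(index=pd.Index(union, name="gene"))
    df["splice_altered"] = [g in splice_altered for g in union]
    df["immune"] = [g in immune_set for g in union]
    df["malignancy"] = [g in malignancy_set for g in union]
    df["core_candidate"] = df.splice_altered & df.immune & df.malignancy
    log_funnel("dual-function screen", len(splice_altered),
               int(df.core_candidate.sum()))
    return df


def ora_hypergeometric(query: set[str], gene_set: set[str],
                       universe: set[str]) -> float:
    """Upper-tail hypergeometric over-representation p for a gene set.

    p = P(X >= |query & gene_set|) under random draws of |query| genes from
    the universe.  Both query and gene set must be subsets of the universe
    (the gene set is intersected with the universe, the usual convention for
    annotation terms broader than the assayed genes; the query must be
    contained).
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    gene_set = set(gene_set) & universe
    k = len(query & gene_set)
    return float(min(1.0, hypergeom.sf(k - 1, len(universe), len(gene_set),
                                       len(query))))
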