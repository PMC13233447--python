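"""Variant-level triage: GWAS x sQTL x eQTL intersection and RBP-region enrichment.

A candidate sGene is a gene whose splicing is linked (via an sQTL) to a
variant that also shows a suggestive disease association (GWAS p below
threshold) and is an expression QTL.  "Co-localisation" here means shared
variant identity across the three tables — an intersection, not a Bayesian
colocalisation posterior.  Enrichment of qualifying variants inside
RNA-binding-protein (CLIP) regions is scored with a one-sided
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .config import ScreenThresholds, log, log_funnel
from .intervals import GenomicInterval


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's disease association plus its QTL gene links."""

    variant_id: str
    locus: GenomicInterval  # length-1 interval
    gwas_p: float
    sqtl_genes: frozenset[str] = frozenset()
    eqtl_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not 0 <= self.gwas_p <= 1:
            raise ValueError(f"gwas_p {self.gwas_p} outside [0, 1]")
        object.__setattr__(self, "sqtl_genes", frozenset(self.sqtl_genes))
        object.__setattr__(self, "eqtl_genes", frozenset(self.eqtl_genes))


@dataclass
class SGeneResult:
    genes: set[str]
    supporting_variants: dict[str, list[str]]
    n_input_variants: int
    n_pass_gwas: int
    n_colocalized: int


@dataclass
class EnrichmentResult:
    n_query: int
    n_query_overlap: int
    n_universe: int
    n_universe_overlap: int
    fold: float
    p: float


def nominate_sgenes(associations: list[VariantAssociation],
                    thresholds: ScreenThresholds | None = None,
                    include_eqtl_genes: bool = False) -> SGeneResult:
    """Intersect GWAS, sQTL and eQTL layers into candidate sGenes.

    A variant qualifies iff its GWAS p is strictly below ``thresholds.gwas_p``
    AND it has at least one sQTL gene AND at least one eQTL gene.  Candidate
    genes are the union of the sQTL genes of qualifying variants (sGenes are
    splice-linked by definition); set ``include_eqtl_genes`` to also union in
    their eQTL genes.  Duplicate variant rows (same ``variant_id``) are
    deduplicated first, so the result is order- and duplication-invariant.
    """
    if not associations:
        raise ValueError("empty association list")
    thresholds = thresholds or ScreenThresholds()
    unique = {a.variant_id: a for a in sorted(associations,
                                              key=lambda a: a.variant_id)}
    n_input = len(unique)
    pass_gwas = [a for a in unique.values() if a.gwas_p < thresholds.gwas_p]
    coloc = [a for a in pass_gwas if a.sqtl_genes and a.eqtl_genes]
    genes: set[str] = set()
    supporting: dict[str, list[str]] = {}
    for a in coloc:
        linked = a.sqtl_genes | a.eqtl_genes if include_eqtl_genes else a.sqtl_genes
        for g in linked:
            genes.add(g)
            supporting.setdefault(g, []).append(a.variant_id)
    for g in supporting:
        supporting[g].sort()
    log_funnel("gwas filter", n_input, len(pass_gwas),
               f"p < {thresholds.gwas_p}")
    log_funnel("sQTL+eQTL colocalization", len(pass_gwas), len(coloc))
    log_funnel("sGene nomination", len(coloc), len(genes), "genes")
    return SGeneResult(genes=genes, supporting_variants=supporting,
                       n_input_variants=n_input, n_pass_gwas=len(pass_gwas),
                       n_colocalized=len(coloc))


def rbp_overlap(variants: list[VariantAssociation],
                rbp: list[GenomicInterval],
                ) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Partition variants into (overlapping, non-overlapping) RBP regions.

    A variant overlaps iff its position falls inside at least one interval
    under half-open semantics; strand is ignored (CLIP peaks are used as
    plain regions).  Variants on chromosomes absent from the interval set
    are counted non-overlapping with a logged warning.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in rbp:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    inside: list[VariantAssociation] = []
    outside: list[VariantAssociation] = []
    missing_chroms: set[str] = set()
    for v in variants:
        tree = trees.get(v.locus.chrom)
        if tree is None:
            missing_chroms.add(v.locus.chrom)
            outside.append(v)
        elif tree.overlaps_point(v.locus.start):
            inside.append(v)
        else:
            outside.append(v)
    for chrom in sorted(missing_chroms):
        log.warning("chromosome %s absent from RBP intervals; "
                    "its variants counted non-overlapping", chrom)
    return inside, outside


def rbp_enrichment(n_query: int, n_query_overlap: int,
                   n_universe: int, n_universe_overlap: int) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of query variants in RBP regions.

    p = P(X >= n_query_overlap) when drawing ``n_query`` variants without
    replacement from a universe of ``n_universe`` containing
    ``n_universe_overlap`` overlapping ones.
    """
    if n_query == 0:
        raise ValueError("fold undefined for empty query")
    if not (n_query_overlap <= n_query <= n_universe
            and n_query_overlap <= n_universe_overlap <= n_universe):
        raise ValueError("overlap counts exceed totals")
    p = float(hypergeom.sf(n_query_overlap - 1, n_universe,
                           n_universe_overlap, n_query))
    universe_rate = n_universe_overlap / n_universe
    fold = (n_query_overlap / n_query) / universe_rate if universe_rate > 0 else float("nan")
    return EnrichmentResult(n_query=n_query, n_query_overlap=n_query_overlap,
                            n_universe=n_universe,
                            n_universe_overlap=n_universe_overlap,
                            fold=fold, p=min(p, 1.0))
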