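"""End-to-end driver triage: chains variant, gene, splicing, motif and
consequence stages over a cohort bundle and reports the surviving genes.

The funnel mirrors the multi-omics prioritisation logic: suggestive GWAS
variants colocalized with sQTLs and eQTLs nominate sGenes; tumor-vs-normal
differential expression and membership in the core splicing-factor set cut
these to a handful of candidates; direction-consistent prognostic value
across survival endpoints selects the driver.  Downstream, differential
splice events, the dual-function (immune x malignancy) screen, Sm-motif
scanning and exon-skip consequence mapping characterise the driver's
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import consequence as cq
from . import motifs as mt
from . import splice as sp
from .config import ScreenThresholds, log
from .expression import (differential_expression, dual_function_screen,
                         intersect_candidates, log_tpm)
from .intervals import GenomicInterval
from .survival import FitError, fit_ph, survival_triage
from .synth import CohortBundle
from .varscreen import (EnrichmentResult, SGeneResult, VariantAssociation,
                        nominate_sgenes, rbp_enrichment, rbp_overlap)


@dataclass
class PipelineResult:
    sgenes: SGeneResult
    enrichment: EnrichmentResult
    de_genes: set[str]
    candidates: set[str]
    stable_genes: set[str]
    splice_altered_genes: dict[str, int]
    dual_function: set[str]
    motif_hits: dict[str, list[mt.MotifHit]] = field(default_factory=dict)
    consequences: list[cq.ConsequenceReport] = field(default_factory=list)
    survival_fits: dict[str, list] = field(default_factory=dict)


def build_associations(gwas: pd.DataFrame, sqtl: pd.DataFrame,
                       eqtl: pd.DataFrame) -> list[VariantAssociation]:
    """Merge the three summary tables into per-variant association atoms.

    GWAS positions are 1-based (summary-statistic convention) and are
    converted to 0-based length-1 loci here.
    """
    sqtl_map = sqtl.groupby("variant_id")["gene"].agg(frozenset).to_dict()
    eqtl_map = eqtl.groupby("variant_id")["gene"].agg(frozenset).to_dict()
    out = []
    for row in gwas.itertuples(index=False):
        out.append(VariantAssociation(
            variant_id=row.variant_id,
            locus=GenomicInterval(row.chrom, int(row.pos) - 1, int(row.pos)),
            gwas_p=float(row.p),
            sqtl_genes=sqtl_map.get(row.variant_id, frozenset()),
            eqtl_genes=eqtl_map.get(row.variant_id, frozenset())))
    return out


def run_pipeline(bundle: CohortBundle, splicing_factors: set[str],
                 immune_set: set[str], malignancy_set: set[str],
                 thresholds: ScreenThresholds | None = None,
                 endpoints: tuple[str, ...] = ("os", "pfs"),
                 ) -> PipelineResult:
    """Run the full triage over one cohort bundle."""
    thr = thresholds or ScreenThresholds()

    # -- variant stage
    assoc = build_associations(bundle.gwas_table, bundle.sqtl_table,
                               bundle.eqtl_table)
    sgenes = nominate_sgenes(assoc, thr)
    qualifying = [a for a in assoc
                  if a.gwas_p < thr.gwas_p and a.sqtl_genes and a.eqtl_genes]
    q_in, _ = rbp_overlap(qualifying, bundle.rbp_intervals)
    u_in, _ = rbp_overlap(assoc, bundle.rbp_intervals)
    enrichment = rbp_enrichment(len(qualifying), len(q_in),
                                len(assoc), len(u_in))

    # -- gene stage
    logm = log_tpm(bundle.expression_matrix)
    de = differential_expression(logm, bundle.sample_labels, thr)
    de_genes = {r.gene for r in de if r.is_de}
    cand_df = intersect_candidates(sgenes.genes, de_genes, splicing_factors)
    candidates = set(cand_df.index[cand_df.candidate])

    # -- survival stage
    fits_by_gene: dict[str, list] = {}
    for gene in sorted(candidates):
        col = f"expr_{gene}"
        if col not in bundle.clinical_table.columns:
            log.warning("no patient-level expression for %s; "
                        "excluded from survival triage", gene)
            continue
        try:
            fits = []
            for ep in endpoints:
                fits.extend(fit_ph(bundle.clinical_table, [col], ep))
            fits_by_gene[gene] = fits
        except FitError as exc:
            log.warning("survival fit failed for %s: %s", gene, exc)
    stable = survival_triage(fits_by_gene, thr.survival_p) \
        if fits_by_gene else {}
    stable_genes = {g for g, ok in stable.items() if ok}

    # -- splicing stage
    results = sp.run_event_tests(bundle.splice_events, thresholds=thr)
    _, per_gene = sp.filter_events(results, thr)
    dual_df = dual_function_screen(set(per_gene), immune_set, malignancy_set)
    dual = set(dual_df.index[dual_df.core_candidate])

    # -- motif / consequence stage (events backed by a transcript model)
    motif_hits: dict[str, list[mt.MotifHit]] = {}
    consequences: list[cq.ConsequenceReport] = []
    for ev in bundle.splice_events:
        if ev.transcript_id is None or ev.exon is None:
            continue
        model = bundle.transcript_models[ev.transcript_id]
        exon = GenomicInterval(ev.chrom, *ev.exon, strand=ev.strand)
        window = mt.extract_scan_window(model, exon, bundle.genome_sequences,
                                        thr.flank_len)
        motif_hits[ev.event_id] = mt.scan_sm_motifs(window)
        report = cq.exon_skip_consequence(model, exon, event_id=ev.event_id)
        consequences.append(cq.domain_impact(
            report, bundle.domains.get(ev.transcript_id, [])))

    return PipelineResult(
        sgenes=sgenes, enrichment=enrichment, de_genes=de_genes,
        candidates=candidates, stable_genes=stable_genes,
        splice_altered_genes=per_gene, dual_function=dual,
        motif_hits=motif_hits, consequences=consequences,
        survival_fits=fits_by_gene)
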