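"""Exon-skipping consequence mapping onto protein primary structure.

Skipping an exon deletes its coding nucleotides from the CDS.  This module
projects that deletion into protein coordinates: whether the reading frame
is preserved (deleted length divisible by 3), which residues of the
reference protein are fully or partially removed, whether the new junction
splits a codon (the hybrid codon may encode a novel residue), and how the
deletion intersects annotated protein domains.

Residue bookkeeping is defined so that a codon counts as deleted when at
least one of its nucleotides is removed; this matches a
translate-and-compare of the full versus exon-removed CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval
from .transcripts import TranscriptModel


@dataclass
class DomainImpact:
    domain: str
    overlap_residues: int
    impact: str  # intact | truncated | full_loss


@dataclass
class ConsequenceReport:
    transcript: str
    cds_nt_deleted: int
    frame_preserved: bool
    # 1-based inclusive protein coordinates, or None when no CDS is touched
    deleted_residues: tuple[int, int] | None
    junction_codon_novel: bool
    protein_length: int
    event_id: str | None = None
    affected_domains: list[DomainImpact] = field(default_factory=list)


def _deleted_cds_block(model: TranscriptModel, exon: GenomicInterval,
                       ) -> tuple[int, int]:
    """CDS-relative half-open span ``[s, e)`` removed by skipping the exon.

    Walks the CDS intervals in transcription order, accumulating offsets,
    and collects the part overlapping the skipped exon.  Returns ``(0, 0)``
    when the exon is entirely non-coding.
    """
    minus = model.strand == "-"
    cds = sorted(model.cds, key=lambda iv: iv.start, reverse=minus)
    offset = 0
    s_rel: int | None = None
    e_rel: int | None = None
    for iv in cds:
        ov_start = max(iv.start, exon.start)
        ov_end = min(iv.end, exon.end)
        if ov_start < ov_end:
            if minus:
                rel_a = offset + (iv.end - ov_end)
                rel_b = offset + (iv.end - ov_start)
            else:
                rel_a = offset + (ov_start - iv.start)
                rel_b = offset + (ov_end - iv.start)
            s_rel = rel_a if s_rel is None else min(s_rel, rel_a)
            e_rel = rel_b if e_rel is None else max(e_rel, rel_b)
        offset += len(iv)
    if s_rel is None:
        return 0, 0
    return s_rel, e_rel


def exon_skip_consequence(model: TranscriptModel, exon: GenomicInterval,
                          event_id: str | None = None) -> ConsequenceReport:
    """Map an exon-skipping deletion to protein coordinates.

    ``deleted_residues`` spans every codon with at least one deleted
    nucleotide (1-based inclusive).  For frame-preserving deletions the
    span ends at the last touched codon; for frameshifts everything from
    the first touched codon onward is disrupted, so the span runs to the
    end of the reference protein.  An exon entirely in the UTR yields an
    empty report with ``frame_preserved`` True.
    """
    if not model.cds:
        raise ValueError(f"{model.transcript_id} has no annotated CDS")
    protein_length = model.cds_length // 3
    s_rel, e_rel = _deleted_cds_block(model, exon)
    n_del = e_rel - s_rel
    if n_del == 0:
        return ConsequenceReport(
            transcript=model.transcript_id, cds_nt_deleted=0,
            frame_preserved=True, deleted_residues=None,
            junction_codon_novel=False, protein_length=protein_length,
            event_id=event_id)
    frame_ok = n_del % 3 == 0
    first = s_rel // 3 + 1
    if frame_ok:
        last = (e_rel - 1) // 3 + 1
        junction_novel = s_rel % 3 != 0
    else:
        last = protein_length
        junction_novel = True
    return ConsequenceReport(
        transcript=model.transcript_id, cds_nt_deleted=n_del,
        frame_preserved=frame_ok, deleted_residues=(first, last),
        junction_codon_novel=junction_novel, protein_length=protein_length,
        event_id=event_id)


def domain_impact(report: ConsequenceReport,
                  domains: list[tuple[str, int, int]]) -> ConsequenceReport:
    """Annotate a consequence report with protein-domain impacts.

    Domains are 1-based inclusive intervals on the reference isoform.
    In-frame deletions truncate any overlapping domain (overlap size
    reported; a fully deleted domain reports an overlap equal to its
    length) and leave the rest intact.  A frameshift leaves only domains
    entirely upstream of the first deleted residue intact; all others are
    a full loss.
    """
    impacts = []
    for name, d_start, d_end in domains:
        if d_start < 1 or d_end < d_start or d_end > report.protein_length:
            raise ValueError(
                f"domain {name} [{d_start},{d_end}] exceeds protein "
                f"length {report.protein_length}")
        if report.deleted_residues is None:
            impacts.append(DomainImpact(name, 0, "intact"))
            continue
        first, last = report.deleted_residues
        if report.frame_preserved:
            ov = max(0, min(d_end, last) - max(d_start, first) + 1)
            impacts.append(DomainImpact(name, ov,
                                        "truncated" if ov else "intact"))
        else:
            if d_end < first:
                impacts.append(DomainImpact(name, 0, "intact"))
            else:
                ov = max(0, min(d_end, last) - max(d_start, first) + 1)
                impacts.append(DomainImpact(name, ov, "full_loss"))
    report.affected_domains = impacts
    return report


def read_domains(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a domains TSV (transcript, domain, start_aa, end_aa)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.transcript, []).append(
            (row.domain, int(row.start_aa), int(row.end_aa)))
    return out


def write_domains(domains: dict[str, list[tuple[str, int, int]]],
                  path: str | Path) -> None:
    rows = [{"transcript": t, "domain": n, "start_aa": s, "end_aa": e}
            for t, lst in domains.items() for n, s, e in lst]
    pd.DataFrame(rows, columns=["transcript", "domain", "start_aa",
                                "end_aa"]).to_csv(path, sep="\t", index=False)
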