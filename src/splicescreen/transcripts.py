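"""Transcript models: strand-aware exon/CDS structure bound to genome sequence.

Models are read from a GFF3 subset (``exon`` and ``CDS`` features sharing a
``transcript_id`` attribute) plus a FASTA genome.  Exons are stored in
ascending genomic order; transcription order is the reverse of that on the
minus strand.  Spliced and CDS sequences are reported on the sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .intervals import GenomicInterval

Genome = dict[str, str]


class ModelError(ValueError):
    """Structurally invalid transcript model (overlapping exons, missing chrom...)."""


@dataclass
class TranscriptModel:
    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ModelError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    @property
    def cds_frame_ok(self) -> bool:
        """True when the total CDS length is a multiple of 3."""
        return self.cds_length % 3 == 0

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand != "-" else list(reversed(self.exons))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _splice(intervals: list[GenomicInterval], genome: Genome, chrom: str,
            strand: str) -> str:
    if chrom not in genome:
        raise ModelError(f"chromosome {chrom!r} absent from genome")
    seq = "".join(genome[chrom][iv.start:iv.end] for iv in intervals)
    return reverse_complement(seq) if strand == "-" else seq


def spliced_sequence(model: TranscriptModel, genome: Genome) -> str:
    """Sense-strand mature transcript sequence (exons joined)."""
    return _splice(model.exons, genome, model.chrom, model.strand)


def cds_sequence(model: TranscriptModel, genome: Genome) -> str:
    """Sense-strand coding sequence (CDS intervals joined)."""
    return _splice(model.cds, genome, model.chrom, model.strand)


def read_genome(fasta_path: str | Path) -> Genome:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


def write_genome(genome: Genome, fasta_path: str | Path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_transcript_models(gff3_path: str | Path, fasta_path: str | Path,
                           ) -> tuple[dict[str, TranscriptModel], Genome]:
    """Load transcript models and genome; validate structure.

    Returns ``(models, genome)`` where ``models`` maps transcript_id to
    :class:`TranscriptModel`.  Raises :class:`ModelError` for exon overlap
    within a transcript or a chromosome missing from the FASTA.  A CDS whose
    total length is not a multiple of 3 is kept but flagged via
    ``cds_frame_ok``.
    """
    genome = read_genome(fasta_path)
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    collected: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            tid = feat.attributes.get("Parent", [None])[0]
        if tid is None:
            raise ModelError(f"{feat.featuretype} feature without transcript_id")
        gene = feat.attributes.get("gene_id", [tid])[0]
        entry = collected.setdefault(
            tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                  "exons": [], "cds": []})
        # GFF3 is 1-based inclusive; convert at the boundary
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                             strand=feat.strand or ".")
        entry["exons" if feat.featuretype == "exon" else "cds"].append(iv)

    models: dict[str, TranscriptModel] = {}
    for tid, entry in collected.items():
        if entry["chrom"] not in genome:
            raise ModelError(
                f"{tid}: chromosome {entry['chrom']!r} missing from FASTA")
        models[tid] = TranscriptModel(
            transcript_id=tid, gene=entry["gene"], chrom=entry["chrom"],
            strand=entry["strand"], exons=entry["exons"], cds=entry["cds"])
    return models, genome


def write_transcript_models(models: dict[str, TranscriptModel],
                            gff3_path: str | Path) -> None:
    """Write models as a GFF3 subset (exon + CDS rows, 1-based inclusive)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, m in models.items():
            for ftype, ivs in (("exon", m.exons), ("CDS", m.cds)):
                for iv in ivs:
                    attrs = f"transcript_id={tid};gene_id={m.gene}"
                    fh.write("\t".join([
                        m.chrom, "splicescreen", ftype,
                        str(iv.start + 1), str(iv.end), ".", m.strand, ".",
                        attrs]) + "\n")
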