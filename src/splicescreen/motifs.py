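"""Sm-binding-motif scanning over skipped exons with intronic flanks.

Sm-class spliceosomal proteins recognise uridine-rich elements on
pre-mRNA.  The canonical site is RAU(4-6)G — a purine (R = A or G),
an A, a run of four to six U's, then a G; a small set of physiological
variant strings is scanned alongside.  Scanning is sense-strand only
(antisense hits are biologically meaningless for a pre-mRNA binder), over
a window consisting of the skipped exon plus its flanking intronic
sequence in transcription order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import log
from .intervals import GenomicInterval
from .transcripts import Genome, TranscriptModel, reverse_complement

RNA_ALPHABET = set("ACGUN")

VARIANT_MOTIFS = ("GGUUUUA", "AAUUUUUA", "AGUUUUA", "GGUUCUUUG", "AGUUCUUG")


@dataclass(frozen=True)
class MotifPattern:
    """A scannable motif: IUPAC-R-aware literal over the RNA alphabet."""

    name: str
    klass: str  # "canonical" | "variant"
    pattern: str

    def regex(self) -> re.Pattern:
        return re.compile(self.pattern.replace("R", "[AG]"))


def default_patterns() -> list[MotifPattern]:
    """Canonical RAU(n)G for n in {4,5,6} plus the variant strings."""
    pats = [MotifPattern(f"RAU{n}G", "canonical", "RA" + "U" * n + "G")
            for n in (4, 5, 6)]
    pats += [MotifPattern(v, "variant", v) for v in VARIANT_MOTIFS]
    return pats


@dataclass
class MotifHit:
    pattern: str
    klass: str
    start: int  # 0-based half-open offsets within the scanned window
    end: int
    matched_seq: str
    region: str | None = None  # upstream_flank | exon | downstream_flank


@dataclass
class ScanWindow:
    """Sense-strand RNA window: upstream flank + exon + downstream flank."""

    sequence: str
    # region tag -> (start, end) offsets within the window
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    transcript_id: str | None = None
    genomic_span: tuple[str, int, int] | None = None

    def region_of(self, offset: int) -> str | None:
        for tag, (s, e) in self.regions.items():
            if s <= offset < e:
                return tag
        return None


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def scan_sm_motifs(window: str | ScanWindow,
                   patterns: list[MotifPattern] | None = None,
                   ) -> list[MotifHit]:
    """Report every motif match span in the window, overlaps included.

    Each canonical run length is its own pattern, so nested matches
    (an RAU4G inside a longer U run) are all reported; consumers may
    collapse.  ``N`` never matches.  Hits are sorted by start offset.
    """
    win = window if isinstance(window, ScanWindow) else None
    seq = window.sequence if win else window
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")
    patterns = patterns if patterns is not None else default_patterns()
    hits: list[MotifHit] = []
    seen: set[tuple[str, int, int]] = set()
    for pat in patterns:
        rx = pat.regex()
        width = len(pat.pattern)
        # lookahead so overlapping occurrences of the same pattern all report
        for m in re.finditer(f"(?=({rx.pattern}))", seq):
            s = m.start()
            key = (pat.name, s, s + width)
            if key in seen:
                continue
            seen.add(key)
            hits.append(MotifHit(
                pattern=pat.name, klass=pat.klass, start=s, end=s + width,
                matched_seq=seq[s:s + width],
                region=win.region_of(s) if win else None))
    hits.sort(key=lambda h: (h.start, h.end, h.pattern))
    return hits


def extract_scan_window(model: TranscriptModel, exon: GenomicInterval,
                        genome: Genome, flank_len: int = 200) -> ScanWindow:
    """Build the sense-strand RNA scan window for one skipped exon.

    The window is upstream intronic flank + exon + downstream intronic
    flank in transcription order; minus-strand transcripts are
    reverse-complemented.  Flanks are truncated at the neighbouring exon
    boundary (they never cross into an adjacent exon; truncation is
    logged) and a terminal exon's missing flank side is empty, with a
    warning.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    try:
        idx = next(i for i, e in enumerate(model.exons)
                   if (e.start, e.end) == (exon.start, exon.end))
    except StopIteration:
        raise ValueError(
            f"exon [{exon.start},{exon.end}) not in {model.transcript_id}"
        ) from None
    prev_exon = model.exons[idx - 1] if idx > 0 else None
    next_exon = model.exons[idx + 1] if idx + 1 < len(model.exons) else None

    left_start = exon.start if prev_exon is None else max(
        exon.start - flank_len, prev_exon.end)
    right_end = exon.end if next_exon is None else min(
        exon.end + flank_len, next_exon.start)
    if prev_exon is not None and exon.start - left_start < flank_len:
        log.info("%s: left flank truncated to %d nt", model.transcript_id,
                 exon.start - left_start)
    if next_exon is not None and right_end - exon.end < flank_len:
        log.info("%s: right flank truncated to %d nt", model.transcript_id,
                 right_end - exon.end)
    if prev_exon is None or next_exon is None:
        log.warning("%s: terminal exon, one intronic flank is empty",
                    model.transcript_id)

    dna = genome[model.chrom][left_start:right_end]
    left_len = exon.start - left_start
    right_len = right_end - exon.end
    exon_len = len(exon)
    if model.strand == "-":
        dna = reverse_complement(dna)
        up_len, down_len = right_len, left_len
    else:
        up_len, down_len = left_len, right_len
    regions = {}
    if up_len:
        regions["upstream_flank"] = (0, up_len)
    regions["exon"] = (up_len, up_len + exon_len)
    if down_len:
        regions["downstream_flank"] = (up_len + exon_len,
                                       up_len + exon_len + down_len)
    return ScanWindow(sequence=dna_to_rna(dna), regions=regions,
                      transcript_id=model.transcript_id,
                      genomic_span=(model.chrom, left_start, right_end))
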