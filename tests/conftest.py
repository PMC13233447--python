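"""Shared fixtures: a session-scoped synthetic cohort, a random transcript
factory, and independent oracles (brute-force motif matcher, per-nucleotide
translate-and-diff consequence oracle, textbook log-rank statistic)."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from Bio.Seq import Seq

from splicescreen.intervals import GenomicInterval
from splicescreen.motifs import VARIANT_MOTIFS
from splicescreen.synth import SimConfig, generate_cohort
from splicescreen.transcripts import (TranscriptModel, cds_sequence,
                                      reverse_complement)

logging.disable(logging.INFO)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@pytest.fixture(scope="session")
def cohort():
    """One full synthetic cohort (seed 1) shared across tests."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


# ---------------------------------------------------------------------------
# random transcript factory (independent of the generator's internals)

def _random_dna(rng, n):
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_cds(rng, n_codons):
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons + ["TAA"])


def make_random_transcript(rng, chrom="chrR", strand=None,
                           ) -> tuple[TranscriptModel, dict]:
    """A random multi-exon coding transcript embedded in a tiny genome."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_ex = int(rng.integers(3, 7))
    exon_lens = [int(rng.integers(30, 160)) for _ in range(n_ex)]
    intron_lens = [int(rng.integers(60, 300)) for _ in range(n_ex - 1)]
    total = sum(exon_lens)
    u5 = int(rng.integers(0, 40))
    u3 = int(rng.integers(3, 40))
    cds_len = total - u5 - u3
    cds_len -= cds_len % 3
    if cds_len < 9:
        u5, u3 = 0, 3
        cds_len = total - 3 - (total - 3) % 3
        u3 = total - cds_len
    exonic = _random_dna(rng, u5) + _random_cds(rng, cds_len // 3) \
        + _random_dna(rng, total - u5 - cds_len)

    pieces, exon_spans, pos, epos = [], [], 0, 0
    for i, L in enumerate(exon_lens):
        pieces.append(exonic[epos:epos + L])
        exon_spans.append((pos, pos + L))
        epos += L
        pos += L
        if i < n_ex - 1:
            pieces.append(_random_dna(rng, intron_lens[i]))
            pos += intron_lens[i]
    sense = "".join(pieces)
    pad = 50
    if strand == "+":
        chrom_seq = _random_dna(rng, pad) + sense + _random_dna(rng, pad)
        def to_g(sp):
            return (pad + sp[0], pad + sp[1])
    else:
        chrom_seq = _random_dna(rng, pad) + reverse_complement(sense) \
            + _random_dna(rng, pad)
        def to_g(sp):
            return (pad + len(sense) - sp[1], pad + len(sense) - sp[0])

    exons = [GenomicInterval(chrom, *to_g(sp), strand=strand)
             for sp in exon_spans]
    cds_ivs, acc = [], 0
    for (s, _), L in zip(exon_spans, exon_lens):
        lo, hi = max(u5, acc), min(u5 + cds_len, acc + L)
        if lo < hi:
            cds_ivs.append(GenomicInterval(
                chrom, *to_g((s + lo - acc, s + hi - acc)), strand=strand))
        acc += L
    model = TranscriptModel(
        transcript_id="T_rand", gene="G_rand", chrom=chrom, strand=strand,
        exons=sorted(exons, key=lambda iv: iv.start),
        cds=sorted(cds_ivs, key=lambda iv: iv.start))
    return model, {chrom: chrom_seq}


# ---------------------------------------------------------------------------
# oracles

def motif_oracle(seq: str) -> set[tuple[str, int, int]]:
    """Brute-force literal matcher over every canonical expansion and
    variant string, at every start position."""
    literals: dict[str, list[str]] = {}
    for n in (4, 5, 6):
        literals[f"RAU{n}G"] = [r + "A" + "U" * n + "G" for r in "AG"]
    for v in VARIANT_MOTIFS:
        literals[v] = [v]
    hits = set()
    for name, pats in literals.items():
        for p in pats:
            for i in range(len(seq) - len(p) + 1):
                if seq[i:i + len(p)] == p:
                    hits.add((name, i, i + len(p)))
    return hits


def translate_diff_oracle(model: TranscriptModel, exon: GenomicInterval,
                          genome: dict):
    """Per-nucleotide provenance + translation oracle for exon skipping.

    Walks the CDS base by base in transcription order, marks bases lying in
    the skipped exon as deleted, and derives the frame call and the 1-based
    residue interval (codons with >= 1 deleted base; frameshifts disrupt
    everything downstream).  Translation of the reference vs the
    exon-removed CDS verifies that, in frame-preserving cases, the proteins
    agree outside the reported interval.
    """
    minus = model.strand == "-"
    cds_ivs = sorted(model.cds, key=lambda iv: iv.start, reverse=minus)
    deleted_idx = []
    idx = 0
    kept = []
    ref_cds = cds_sequence(model, genome)
    for iv in cds_ivs:
        positions = range(iv.end - 1, iv.start - 1, -1) if minus \
            else range(iv.start, iv.end)
        for gpos in positions:
            if exon.start <= gpos < exon.end:
                deleted_idx.append(idx)
            else:
                kept.append(ref_cds[idx])
            idx += 1
    n_del = len(deleted_idx)
    protein_len = len(ref_cds) // 3
    if n_del == 0:
        return 0, True, None
    residues = sorted({i // 3 + 1 for i in deleted_idx})
    frame_ok = n_del % 3 == 0
    if frame_ok:
        interval = (residues[0], residues[-1])
        first, last = interval
        ref_prot = str(Seq(ref_cds).translate())
        mut_prot = str(Seq("".join(kept)).translate())
        d = n_del // 3
        assert ref_prot[:first - 1] == mut_prot[:first - 1]
        assert ref_prot[last:] == mut_prot[last - d:]
    else:
        interval = (residues[0], protein_len)
    return n_del, frame_ok, interval


def logrank_oracle(time_a, event_a, time_b, event_b) -> float:
    """Textbook two-group log-rank chi-square (1 df)."""
    times = sorted({t for t, e in zip(list(time_a) + list(time_b),
                                      list(event_a) + list(event_b)) if e})
    o_minus_e = 0.0
    var = 0.0
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    for t in times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0
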