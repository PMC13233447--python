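"""Splice events, PSI quantification, and differential dPSI testing.

An event is described by its inclusion- and skipping-form junctions in
genomic coordinates (a junction ``(a, b)`` is the excised intron
``[a, b)``), plus per-replicate inclusion/skipping junction read counts for
two conditions.  PSI is reported in percent; dPSI on the fraction scale, so
the conventional |dPSI| > 0.1 cutoff means 10 percentage points.

The differential test is a two-sided Fisher's exact test on the pooled
2x2 (inclusion/skipping x condition) count table — a transparent stand-in
for likelihood-ratio splicing tests, and deliberately replaceable.
Q-values are Benjamini-Hochberg across all events tested in one batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .config import ScreenThresholds, log

MODES = ("ES", "IR", "A5SS", "A3SS", "MXE")

Junction = tuple[int, int]


class UnclassifiedEventError(ValueError):
    """Event structure matches none of the five canonical AS modes."""


@dataclass
class SpliceEvent:
    event_id: str
    gene: str
    chrom: str
    strand: str
    inclusion_junctions: tuple[Junction, ...] = ()
    skipping_junctions: tuple[Junction, ...] = ()
    retained_intron: Junction | None = None
    exon: Junction | None = None  # cassette exon for ES events
    transcript_id: str | None = None
    mode: str | None = None
    # condition -> [(inclusion, skipping) per replicate]
    counts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        self.inclusion_junctions = tuple(
            sorted(tuple(j) for j in self.inclusion_junctions))
        self.skipping_junctions = tuple(
            sorted(tuple(j) for j in self.skipping_junctions))
        for a, b in self.inclusion_junctions + self.skipping_junctions:
            if a >= b:
                raise ValueError(f"{self.event_id}: invalid junction ({a},{b})")


@dataclass
class EventTestResult:
    event_id: str
    gene: str
    psi_a: list[float]
    psi_b: list[float]
    delta_psi: float  # fraction scale, mean(B) - mean(A)
    p: float
    q: float | None = None
    significant: bool | None = None


def compute_psi(inclusion: int, skipping: int) -> float | None:
    """Percent spliced-in: 100 * inclusion / (inclusion + skipping).

    Returns ``None`` (undefined) when both counts are zero — never 0 or
    100, which would fabricate a measurement from no reads.
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("negative junction counts")
    total = inclusion + skipping
    if total == 0:
        return None
    return 100.0 * inclusion / total


def psi_from_gel_bands(upper: float, lower: float) -> float | None:
    """PSI from gel band intensities: the upper (longer, exon-included)
    band over the total.  Mirrors :func:`compute_psi` on intensities."""
    if upper < 0 or lower < 0:
        raise ValueError("negative band intensities")
    total = upper + lower
    if total == 0:
        return None
    return 100.0 * upper / total


def classify_event(event: SpliceEvent) -> str:
    """Assign one of the five canonical AS modes from event structure.

    Labels are transcript-relative: an alternative left-hand intron
    boundary is a 5' splice-site choice (A5SS) on the plus strand but a
    3' splice-site choice (A3SS) on the minus strand.
    """
    inc, skp = event.inclusion_junctions, event.skipping_junctions
    if (event.retained_intron is not None and not inc
            and skp == (tuple(event.retained_intron),)):
        return "IR"
    if len(inc) == 2 and len(skp) == 1:
        (a1, b1), (a2, b2) = inc
        (sa, sb) = skp[0]
        if sa == a1 and sb == b2 and b1 <= a2:
            return "ES"
    if len(inc) == 1 and len(skp) == 1 and inc != skp:
        (ia, ib), (sa, sb) = inc[0], skp[0]
        if ib == sb and ia != sa:  # alternative left boundary
            return "A5SS" if event.strand != "-" else "A3SS"
        if ia == sa and ib != sb:  # alternative right boundary
            return "A3SS" if event.strand != "-" else "A5SS"
    if len(inc) == 2 and len(skp) == 2:
        (a1, b1s), (b1e, c1) = inc
        (a2, b2s), (b2e, c2) = skp
        outer_match = a1 == a2 and c1 == c2
        disjoint = b1e <= b2s or b2e <= b1s
        if outer_match and disjoint and b1s < b1e and b2s < b2e:
            return "MXE"
    raise UnclassifiedEventError(
        f"{event.event_id}: junction structure matches no canonical mode")


def event_group_test(event: SpliceEvent,
                     counts_a: list[tuple[int, int]],
                     counts_b: list[tuple[int, int]]) -> EventTestResult:
    """Differential inclusion test between two conditions.

    dPSI = mean PSI(B) - mean PSI(A) over replicates with defined PSI,
    on the fraction scale.  p is a two-sided Fisher's exact test on the
    pooled inclusion/skipping counts.  Zero-total replicates are excluded
    from the mean (and logged); a group whose replicates are all
    zero-total is an error.
    """
    def group_psi(counts, label):
        psis = []
        for inc, skp in counts:
            psi = compute_psi(inc, skp)
            if psi is None:
                log.info("%s: zero-total replicate excluded (group %s)",
                         event.event_id, label)
            else:
                psis.append(psi)
        if not psis:
            raise ValueError(
                f"{event.event_id}: all replicates zero-total in group {label}")
        return psis

    psi_a = group_psi(counts_a, "A")
    psi_b = group_psi(counts_b, "B")
    delta = (float(np.mean(psi_b)) - float(np.mean(psi_a))) / 100.0
    pooled_a = (sum(i for i, _ in counts_a), sum(s for _, s in counts_a))
    pooled_b = (sum(i for i, _ in counts_b), sum(s for _, s in counts_b))
    _, p = fisher_exact([list(pooled_a), list(pooled_b)],
                        alternative="two-sided")
    return EventTestResult(event_id=event.event_id, gene=event.gene,
                           psi_a=psi_a, psi_b=psi_b, delta_psi=delta,
                           p=float(p))


def fdr_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    arr = np.asarray(pvals, float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def run_event_tests(events: list[SpliceEvent], group_a: str = "control",
                    group_b: str = "knockdown",
                    thresholds: ScreenThresholds | None = None,
                    ) -> list[EventTestResult]:
    """Run the group test on every event and BH-adjust in one batch."""
    thresholds = thresholds or ScreenThresholds()
    results = [event_group_test(ev, ev.counts[group_a], ev.counts[group_b])
               for ev in events]
    qvals = fdr_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = q
        r.significant = (abs(r.delta_psi) > thresholds.dpsi_min
                         and q < thresholds.fdr_max)
    return results


def filter_events(results: list[EventTestResult],
                  thresholds: ScreenThresholds | None = None,
                  ) -> tuple[list[EventTestResult], dict[str, int]]:
    """Apply strict |dPSI| and FDR cutoffs; roll up genes.

    An event is significant iff |dPSI| > dpsi_min AND q < fdr_max (both
    strict).  Returns the significant events and a per-gene count of
    significant events (genes with >= 1 appear).
    """
    thresholds = thresholds or ScreenThresholds()
    sig = []
    per_gene: dict[str, int] = {}
    for r in results:
        if r.q is None:
            raise ValueError(f"{r.event_id}: q not computed")
        r.significant = (abs(r.delta_psi) > thresholds.dpsi_min
                         and r.q < thresholds.fdr_max)
        if r.significant:
            sig.append(r)
            per_gene[r.gene] = per_gene.get(r.gene, 0) + 1
    return sig, per_gene


# ---------------------------------------------------------------------------
# events.json I/O

def write_events(events: list[SpliceEvent], path: str | Path) -> None:
    payload = []
    for ev in events:
        payload.append({
            "event_id": ev.event_id, "gene": ev.gene, "chrom": ev.chrom,
            "strand": ev.strand, "mode": ev.mode,
            "transcript_id": ev.transcript_id,
            "exon": list(ev.exon) if ev.exon else None,
            "retained_intron": (list(ev.retained_intron)
                                if ev.retained_intron else None),
            "inclusion_junctions": [list(j) for j in ev.inclusion_junctions],
            "skipping_junctions": [list(j) for j in ev.skipping_junctions],
            "counts": {g: [list(c) for c in reps]
                       for g, reps in ev.counts.items()},
        })
    with open(path, "w") as fh:
        json.dump({"events": payload}, fh, indent=1)


def read_events(path: str | Path) -> list[SpliceEvent]:
    with open(path) as fh:
        payload = json.load(fh)
    events = []
    for d in payload["events"]:
        events.append(SpliceEvent(
            event_id=d["event_id"], gene=d["gene"], chrom=d["chrom"],
            strand=d["strand"], mode=d.get("mode"),
            transcript_id=d.get("transcript_id"),
            exon=tuple(d["exon"]) if d.get("exon") else None,
            retained_intron=(tuple(d["retained_intron"])
                             if d.get("retained_intron") else None),
            inclusion_junctions=tuple(tuple(j)
                                      for j in d["inclusion_junctions"]),
            skipping_junctions=tuple(tuple(j)
                                     for j in d["skipping_junctions"]),
            counts={g: [tuple(c) for c in reps]
                    for g, reps in d.get("counts", {}).items()}))
    return events
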