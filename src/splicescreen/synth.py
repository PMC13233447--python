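"""Synthetic multi-omics cohort generator with a ground-truth ledger.

Generates every data layer the triage pipeline consumes — GWAS summary
statistics, sQTL/eQTL association tables, RBP-binding intervals, a
tumor/normal TPM matrix, a clinical table with survival endpoints, splice
events with per-replicate junction counts, transcript models with planted
Sm motifs and protein domains, and bench-assay plates — with one planted
driver gene carrying signal in every layer and a set of decoy genes each
engineered to fail exactly one filter.  Every planted effect is recorded
in a :class:`TruthLedger`, the oracle for parameter-recovery tests.

Randomness comes from a single root seed; each layer draws from its own
named child stream, so adding a layer never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import write_domains
from .intervals import GenomicInterval, write_bed
from .splice import SpliceEvent, write_events
from .transcripts import (TranscriptModel, reverse_complement, write_genome,
                          write_transcript_models)

_LAYERS = {"variants": 0, "rbp": 1, "expression": 2, "clinical": 3,
           "splicing": 4, "sequence": 5, "assays": 6}

_STOPS = {"TAA", "TAG", "TGA"}
_DNA = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DriverEffects:
    """Planted effect sizes for the driver gene."""

    gwas_p_target: float = 1e-4
    eqtl_effect: float = 2.0  # tumor-vs-normal log2FC
    hazard_log_hr: float = float(np.log(2.0))  # per-SD log hazard ratio
    true_dpsi_list: tuple[float, ...] = (0.3, -0.3, 0.2)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_variants: int = 500
    n_genes: int = 200
    n_tumor: int = 60
    n_normal: int = 60
    n_patients: int = 400
    driver_gene: str = "G0001"
    driver_effects: DriverEffects = field(default_factory=DriverEffects)
    n_events: int = 60
    n_replicates: int = 3
    mean_junction_coverage: int = 100
    flank_len: int = 200
    n_dual_function: int = 14
    missingness_rates: dict = field(default_factory=lambda: {
        "age": 0.002, "stage": 0.0, "grade": 0.0, "race": 0.06})

    def __post_init__(self):
        counts = {"n_variants": self.n_variants, "n_genes": self.n_genes,
                  "n_tumor": self.n_tumor, "n_normal": self.n_normal,
                  "n_patients": self.n_patients, "n_events": self.n_events,
                  "n_replicates": self.n_replicates,
                  "mean_junction_coverage": self.mean_junction_coverage}
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.n_genes < 80:
            raise ConfigError("n_genes must be >= 80 (role assignment "
                              "reserves the first ~70 gene slots)")
        for k, v in self.missingness_rates.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"missingness rate {k}={v} outside [0,1]")
        if self.driver_gene not in gene_names(self):
            raise ConfigError(
                f"driver gene {self.driver_gene!r} not among the "
                f"{self.n_genes} generated genes")
        n_planted = (len(self.driver_effects.true_dpsi_list)
                     + self.n_dual_function + 10)
        if self.n_events < n_planted + 5:
            raise ConfigError(
                f"n_events={self.n_events} too small for {n_planted} "
                "planted events plus nulls")


@dataclass
class TruthLedger:
    planted_driver: str
    colocalized_variants: list[str]
    true_hr: float
    true_log2fc: float
    true_dpsi: dict[str, float] = field(default_factory=dict)
    planted_de_log2fc: dict[str, float] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[dict]] = field(default_factory=dict)
    skipped_motif_plantings: list[dict] = field(default_factory=list)
    decoys: dict[str, str] = field(default_factory=dict)  # gene -> failed filter
    splicing_factors: list[str] = field(default_factory=list)
    immune_set: list[str] = field(default_factory=list)
    malignancy_set: list[str] = field(default_factory=list)
    dual_function_genes: list[str] = field(default_factory=list)
    splice_altered_genes: list[str] = field(default_factory=list)
    qpcr_true_fold: dict[str, float] = field(default_factory=dict)
    ldh_true_cytotoxicity: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortBundle:
    gwas_table: pd.DataFrame
    sqtl_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    rbp_intervals: list[GenomicInterval]
    expression_matrix: pd.DataFrame  # genes x samples, TPM
    sample_labels: pd.Series  # sample -> tumor|normal
    clinical_table: pd.DataFrame
    splice_events: list[SpliceEvent]
    transcript_models: dict[str, TranscriptModel]
    genome_sequences: dict[str, str]
    domains: dict[str, list[tuple[str, int, int]]]
    qpcr_table: pd.DataFrame
    ldh_table: pd.DataFrame


def layer_rng(seed: int, layer: str) -> np.random.Generator:
    """Named child stream of the root seed for one data layer."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_LAYERS[layer],)))


def gene_names(config: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def assign_roles(config: SimConfig) -> dict:
    """Deterministic gene-role assignment (no randomness).

    Decoys each fail exactly one pipeline filter:

    - ``gwas``: QTL-linked variant but weak disease association
    - ``coloc``: GWAS + sQTL variant lacking an eQTL link
    - ``de``: colocalized splicing factor that is not differentially expressed
    - ``splicing_factor``: colocalized + DE but not a splicing factor
    - ``survival``: full expression-layer signal but null hazard
    - ``survival_direction``: significant but protective hazard (HR < 1)
    """
    genes = gene_names(config)
    driver = config.driver_gene
    pool = [g for g in genes if g != driver]
    decoys = {"gwas": pool[0], "coloc": pool[1], "de": pool[2],
              "splicing_factor": pool[3], "survival": pool[4],
              "survival_direction": pool[5]}
    sf_fillers = pool[6:11]
    nd = config.n_dual_function
    dual = pool[11:11 + nd]
    immune_only_spliced = pool[11 + nd:16 + nd]
    immune_only = pool[16 + nd:21 + nd]
    malig_only_spliced = pool[21 + nd:26 + nd]
    malig_only = pool[26 + nd:31 + nd]
    de_background = pool[31 + nd:51 + nd]
    return {
        "genes": genes,
        "driver": driver,
        "decoys": decoys,
        "splicing_factors": sorted(
            [driver, decoys["de"], decoys["survival"],
             decoys["survival_direction"]] + sf_fillers),
        "dual_function": dual,
        "immune_set": sorted(dual + immune_only_spliced + immune_only),
        "malignancy_set": sorted(dual + malig_only_spliced + malig_only),
        "spliced_non_dual": immune_only_spliced + malig_only_spliced,
        "de_background": de_background,
        "reserved": set([driver] + list(decoys.values()) + sf_fillers),
    }


# ---------------------------------------------------------------------------
# variant layer

def generate_variant_layer(config: SimConfig, rng: np.random.Generator,
                           roles: dict):
    n = config.n_variants
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=n,
                                   replace=False))
    ids = [f"rs{i:06d}" for i in range(1, n + 1)]
    pvals = rng.uniform(0, 1, size=n)

    sqtl_links: list[tuple[str, str]] = []
    eqtl_links: list[tuple[str, str]] = []

    # background QTL links to non-reserved genes (some will pass the GWAS
    # filter and become background sGenes, as in a real funnel)
    linkable = [g for g in roles["genes"] if g not in roles["reserved"]]
    n_bg = max(4, n // 10)
    bg_idx = rng.choice(np.arange(6, n), size=n_bg, replace=False)
    for i in bg_idx:
        g = linkable[int(rng.integers(len(linkable)))]
        sqtl_links.append((ids[i], g))
        if rng.random() < 0.5:
            eqtl_links.append((ids[i], g))

    de = config.driver_effects
    planted = {
        0: (roles["driver"], de.gwas_p_target, True, True),
        1: (roles["decoys"]["gwas"], 0.5, True, True),
        2: (roles["decoys"]["coloc"], de.gwas_p_target, True, False),
        3: (roles["decoys"]["de"], de.gwas_p_target, True, True),
        4: (roles["decoys"]["splicing_factor"], de.gwas_p_target, True, True),
        5: (roles["decoys"]["survival"], de.gwas_p_target, True, True),
        6: (roles["decoys"]["survival_direction"], de.gwas_p_target, True, True),
    }
    coloc_variants = []
    for i, (gene, p, has_sqtl, has_eqtl) in planted.items():
        pvals[i] = p
        if has_sqtl:
            sqtl_links.append((ids[i], gene))
        if has_eqtl:
            eqtl_links.append((ids[i], gene))
        if p < 0.05 and has_sqtl and has_eqtl:
            coloc_variants.append(ids[i])

    gwas = pd.DataFrame({"variant_id": ids, "chrom": "chr1",
                         "pos": positions, "p": pvals})
    sqtl = pd.DataFrame(sorted(sqtl_links), columns=["variant_id", "gene"])
    eqtl = pd.DataFrame(sorted(eqtl_links), columns=["variant_id", "gene"])
    return gwas, sqtl, eqtl, coloc_variants


def generate_rbp_layer(config: SimConfig, rng: np.random.Generator,
                       gwas: pd.DataFrame, sqtl: pd.DataFrame,
                       ) -> list[GenomicInterval]:
    """CLIP-style binding intervals enriched around sQTL variants."""
    pos_by_id = dict(zip(gwas.variant_id, gwas.pos))
    intervals = []
    sqtl_ids = sorted(set(sqtl.variant_id))
    n_cover = max(1, int(0.7 * len(sqtl_ids)))
    covered = list(rng.choice(sqtl_ids, size=n_cover, replace=False))
    for k, vid in enumerate(covered):
        center = pos_by_id[vid] - 1  # 0-based
        start = max(0, center - int(rng.integers(20, 100)))
        intervals.append(GenomicInterval("chr1", start, center + int(
            rng.integers(20, 100)), name=f"RBP_peak_{k:03d}"))
    for k in range(30):
        start = int(rng.integers(0, 10_000_000))
        intervals.append(GenomicInterval("chr1", start,
                                         start + int(rng.integers(50, 300)),
                                         name=f"RBP_bg_{k:03d}"))
    intervals.sort(key=lambda iv: (iv.start, iv.end))
    return intervals


# ---------------------------------------------------------------------------
# expression layer

def generate_expression_layer(config: SimConfig, rng: np.random.Generator,
                              roles: dict):
    genes = roles["genes"]
    n_s = config.n_tumor + config.n_normal
    samples = ([f"tumor_{i:03d}" for i in range(config.n_tumor)]
               + [f"normal_{i:03d}" for i in range(config.n_normal)])
    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_normal)

    mu = rng.uniform(3.0, 8.0, size=len(genes))
    fc = np.zeros(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    planted_fc: dict[str, float] = {}

    de = config.driver_effects
    fc[idx[roles["driver"]]] = de.eqtl_effect
    planted_fc[roles["driver"]] = de.eqtl_effect
    # DE decoys: colocalized and differentially expressed
    for key in ("splicing_factor", "survival", "survival_direction"):
        g = roles["decoys"][key]
        fc[idx[g]] = 2.0
        planted_fc[g] = 2.0
    planted_fc[roles["decoys"]["de"]] = 0.0  # explicitly null
    signs = rng.choice([-2.0, 2.0], size=len(roles["de_background"]))
    for g, s in zip(roles["de_background"], signs):
        fc[idx[g]] = s
        planted_fc[g] = float(s)
    # planted genes get a fixed moderate baseline: high enough that the +1
    # pseudocount does not compress the fold, low enough that the planted
    # raw mass barely perturbs the per-sample TPM renormalisation
    for g in planted_fc:
        mu[idx[g]] = 5.0

    log2x = (mu[:, None] + fc[:, None] * is_tumor[None, :]
             + rng.normal(0, 0.5, size=(len(genes), n_s)))
    raw = np.exp2(log2x)
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    matrix = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"),
                          columns=samples)
    labels = pd.Series(["tumor"] * config.n_tumor
                       + ["normal"] * config.n_normal,
                       index=samples, name="group")
    return matrix, labels, planted_fc


# ---------------------------------------------------------------------------
# clinical / survival layer

def simulate_survival_endpoint(rng: np.random.Generator, eta: np.ndarray,
                               h0: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard h0*exp(eta) and independent
    uniform censoring tuned to roughly 30% censoring at eta = 0."""
    n = len(eta)
    t_event = rng.exponential(1.0 / (h0 * np.exp(eta)), size=n)
    censor = rng.uniform(0, 3.2 / h0, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event


def simulate_survival_cohort(n: int, log_hr: float,
                             rng: np.random.Generator,
                             two_group: bool = False) -> pd.DataFrame:
    """Small stand-alone survival cohort for parameter-recovery studies.

    ``two_group`` draws a balanced binary covariate; otherwise a standard
    normal one.  Returns columns ``x``, ``time``, ``event``.
    """
    x = (rng.integers(0, 2, size=n).astype(float) if two_group
         else rng.standard_normal(n))
    time, event = simulate_survival_endpoint(rng, log_hr * x)
    return pd.DataFrame({"x": x, "time": time, "event": event})


def generate_clinical_layer(config: SimConfig, rng: np.random.Generator,
                            roles: dict) -> pd.DataFrame:
    n = config.n_patients
    beta = config.driver_effects.hazard_log_hr
    z_driver = rng.standard_normal(n)
    z_null = rng.standard_normal(n)
    z_prot = -0.8 * z_driver + 0.6 * rng.standard_normal(n)

    records = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
        "age": np.clip(rng.normal(64, 10, size=n).round(), 31, 90),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n,
                            p=[0.62, 0.10, 0.23, 0.05]),
        "grade": rng.choice(["G1/2", "G3"], size=n, p=[0.42, 0.58]),
        "race": rng.choice(["White", "Others"], size=n, p=[0.73, 0.27]),
    }).set_index("patient_id", drop=False)

    # per-candidate continuous expression (standardised log scale)
    records[f"expr_{roles['driver']}"] = z_driver
    records[f"expr_{roles['decoys']['survival']}"] = z_null
    records[f"expr_{roles['decoys']['survival_direction']}"] = z_prot
    records[f"expr_{roles['decoys']['de']}"] = rng.standard_normal(n)
    records["expression"] = z_driver  # the driver, by convention

    for ep in ("os", "pfs", "dfs"):
        time, event = simulate_survival_endpoint(rng, beta * z_driver)
        records[f"{ep}_time"] = np.round(time, 1)
        records[f"{ep}_event"] = event
    # a few zero-day follow-ups and missing endpoints, per real-cohort quirks
    zero_idx = records.index[rng.choice(n, size=2, replace=False)]
    records.loc[zero_idx, "os_time"] = 0.0
    miss_idx = records.index[rng.choice(n, size=max(2, n // 50),
                                        replace=False)]
    records.loc[miss_idx, "dfs_time"] = np.nan
    records.loc[miss_idx, "dfs_event"] = np.nan

    for col, rate in config.missingness_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            records.loc[mask, col] = np.nan
    return records


# ---------------------------------------------------------------------------
# splicing layer

def draw_event_counts(rng: np.random.Generator, psi: float, coverage: int,
                      reps: int) -> list[tuple[int, int]]:
    """Per-replicate (inclusion, skipping) counts: total ~ Poisson(coverage),
    inclusion ~ Binomial(total, psi)."""
    totals = rng.poisson(coverage, size=reps)
    incl = rng.binomial(totals, psi)
    return [(int(i), int(t - i)) for i, t in zip(incl, totals)]


def simulate_psi_events(n_events: int, dpsi: float, coverage: int,
                        reps: int, rng: np.random.Generator,
                        psi_range: tuple[float, float] = (0.35, 0.65),
                        ) -> list[tuple[list, list, float]]:
    """Count-only splice events for calibration studies.

    Each event draws a control PSI uniformly from ``psi_range`` and a
    second condition shifted by ``dpsi`` (clipped to [0, 1]), then
    per-replicate counts from the same generative model as the full
    cohort.  Returns ``[(counts_control, counts_other, psi_control), ...]``.
    """
    out = []
    for _ in range(n_events):
        psi_c = float(rng.uniform(*psi_range))
        psi_k = float(np.clip(psi_c + dpsi, 0.0, 1.0))
        out.append((draw_event_counts(rng, psi_c, coverage, reps),
                    draw_event_counts(rng, psi_k, coverage, reps), psi_c))
    return out


def _event_structure(rng: np.random.Generator, mode: str,
                     anchor: int) -> dict:
    """Arbitrary well-formed junction coordinates for one event mode."""
    a = anchor + int(rng.integers(0, 200))
    l1, l2, l3 = (int(rng.integers(80, 200)) for _ in range(3))
    if mode == "ES":
        b, c = a + l1, a + l1 + l2
        return {"inclusion_junctions": ((a, b), (b + 60, c + 60)),
                "skipping_junctions": ((a, c + 60),),
                "exon": (b, b + 60)}
    if mode == "IR":
        return {"retained_intron": (a, a + l1),
                "skipping_junctions": ((a, a + l1),),
                "inclusion_junctions": ()}
    if mode == "A5SS":
        return {"inclusion_junctions": ((a + 30, a + l1),),
                "skipping_junctions": ((a, a + l1),)}
    if mode == "A3SS":
        return {"inclusion_junctions": ((a, a + l1 - 30),),
                "skipping_junctions": ((a, a + l1),)}
    # MXE
    b1, c = a + 50, a + 400
    b2 = a + 200
    return {"inclusion_junctions": ((a, b1), (b1 + 80, c)),
            "skipping_junctions": ((a, b2), (b2 + 80, c))}


def generate_splicing_layer(config: SimConfig, rng: np.random.Generator,
                            roles: dict | None = None,
                            ) -> tuple[list[SpliceEvent], dict[str, float]]:
    """Splice events with per-replicate counts; returns (events, true dPSI).

    Planted events: the driver-effect dPSI values land on the first
    dual-function genes (the experimentally validated targets); remaining
    dual-function and immune/malignancy-only genes get |dPSI| = 0.3 events;
    everything else is null (dPSI = 0).  Control-condition PSI is drawn
    uniformly in [0.35, 0.65] so planted shifts stay inside [0, 1].
    """
    roles = roles or assign_roles(config)
    de = config.driver_effects
    plan: list[tuple[str, float]] = []
    dpsi_iter = list(de.true_dpsi_list)
    for i, g in enumerate(roles["dual_function"]):
        dpsi = dpsi_iter[i] if i < len(dpsi_iter) else \
            (0.3 if i % 2 == 0 else -0.3)
        plan.append((g, dpsi))
    for g in roles["spliced_non_dual"]:
        plan.append((g, 0.3))
    n_null = config.n_events - len(plan)
    null_genes = [g for g in roles["genes"]
                  if g not in {p[0] for p in plan}]
    for i in range(n_null):
        plan.append((null_genes[int(rng.integers(len(null_genes)))], 0.0))

    modes = ["ES", "ES", "ES", "IR", "A5SS", "A3SS", "MXE"]
    events: list[SpliceEvent] = []
    true_dpsi: dict[str, float] = {}
    for i, (gene, dpsi) in enumerate(plan):
        event_id = f"E{i + 1:04d}"
        # validated driver targets are exon-skipping events
        mode = "ES" if dpsi != 0 else modes[i % len(modes)]
        struct = _event_structure(rng, mode, anchor=20_000 + 2_000 * i)
        psi_ctrl = float(rng.uniform(0.35, 0.65))
        psi_kd = float(np.clip(psi_ctrl + dpsi, 0.0, 1.0))
        counts = {
            "control": draw_event_counts(rng, psi_ctrl,
                                         config.mean_junction_coverage,
                                         config.n_replicates),
            "knockdown": draw_event_counts(rng, psi_kd,
                                           config.mean_junction_coverage,
                                           config.n_replicates)}
        events.append(SpliceEvent(event_id=event_id, gene=gene, chrom="chr1",
                                  strand="+", mode=mode, counts=counts,
                                  **struct))
        true_dpsi[event_id] = dpsi
    return events, true_dpsi


# ---------------------------------------------------------------------------
# sequence layer

def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, size=n)])


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal codons without stops + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _cds_has_internal_stop(cds: str) -> bool:
    return any(cds[i:i + 3] in _STOPS for i in range(0, len(cds) - 3, 3))


def plant_motif(sense_seq: str, exon_span: tuple[int, int],
                motif_rna: str, region: str, flank_len: int,
                rng: np.random.Generator, validate=None,
                ) -> tuple[str, int] | None:
    """Write a motif (RNA alphabet) into a sense-strand gene sequence.

    ``exon_span`` is the cassette exon's span within ``sense_seq`` (which
    covers the whole transcription unit in sense orientation); ``region``
    chooses the exon or one of its intronic flanks.  Candidate offsets are
    tried in random order; ``validate`` (candidate sequence -> bool) can
    veto placements, e.g. exonic plantings that would write an in-frame
    stop codon into the CDS.  Returns the modified sequence and the sense
    offset of the motif, or ``None`` when the target region is shorter
    than the motif or no acceptable placement exists.
    """
    motif_dna = motif_rna.replace("U", "T")
    s, e = exon_span
    if region == "exon":
        lo, hi = s, e
    elif region == "upstream_flank":
        lo, hi = max(0, s - flank_len), s
    elif region == "downstream_flank":
        lo, hi = e, min(len(sense_seq), e + flank_len)
    else:
        raise ValueError(f"unknown region {region!r}")
    if hi - lo < len(motif_dna):
        return None
    offsets = list(rng.permutation(np.arange(lo, hi - len(motif_dna) + 1)))
    for off in offsets:
        off = int(off)
        cand = sense_seq[:off] + motif_dna + sense_seq[off + len(motif_dna):]
        if validate is not None and not validate(cand):
            continue
        return cand, off
    return None


def _build_transcript(rng: np.random.Generator, tid: str, gene: str,
                      chrom: str, strand: str, config: SimConfig,
                      motif_rna: str, motif_region: str):
    """One 5-exon transcript with a coding cassette exon and a planted motif.

    Returns (model, chrom_seq, domains, motif_record_or_None, event_struct).
    """
    n_ex = 5
    exon_lens = [int(rng.integers(90, 150)) for _ in range(n_ex)]
    intron_lens = [int(rng.integers(2 * config.flank_len + 50,
                                    2 * config.flank_len + 400))
                   for _ in range(n_ex - 1)]
    total_exon = sum(exon_lens)
    u5 = 30
    cds_len = total_exon - u5 - 30
    cds_len -= cds_len % 3
    u3 = total_exon - u5 - cds_len

    # sense-orientation layout: exons and introns in transcription order
    exonic = random_dna(rng, u5) + random_cds(rng, cds_len // 3) \
        + random_dna(rng, u3)
    pieces, exon_spans, pos, epos = [], [], 0, 0
    for i, L in enumerate(exon_lens):
        pieces.append(exonic[epos:epos + L])
        exon_spans.append((pos, pos + L))
        epos += L
        pos += L
        if i < n_ex - 1:
            pieces.append(random_dna(rng, intron_lens[i]))
            pos += intron_lens[i]
    sense = "".join(pieces)

    # transcript coordinate of the CDS -> sense-sequence span bookkeeping
    def tx_to_sense(tpos: int) -> int:
        acc = 0
        for (s, e), L in zip(exon_spans, exon_lens):
            if tpos < acc + L:
                return s + (tpos - acc)
            acc += L
        return exon_spans[-1][1]

    cassette = exon_spans[2]  # middle exon in transcription order

    def frame_safe(cand: str) -> bool:
        tx_cds = "".join(cand[s:e] for s, e in exon_spans)[u5:u5 + cds_len]
        return not _cds_has_internal_stop(tx_cds)

    planted = plant_motif(sense, cassette, motif_rna, motif_region,
                          config.flank_len, rng,
                          validate=frame_safe if motif_region == "exon"
                          else None)
    motif_off = None
    if planted is not None:
        sense, motif_off = planted

    pad = 300
    region_len = len(sense)
    if strand == "+":
        chrom_seq = random_dna(rng, pad) + sense + random_dna(rng, pad)
        def to_genomic(span):
            return (pad + span[0], pad + span[1])
    else:
        chrom_seq = random_dna(rng, pad) + reverse_complement(sense) \
            + random_dna(rng, pad)
        def to_genomic(span):
            return (pad + region_len - span[1], pad + region_len - span[0])

    exon_ivs = [GenomicInterval(chrom, *to_genomic(sp), strand=strand)
                for sp in exon_spans]
    # CDS genomic intervals: intersect the CDS transcript range with exons
    cds_ivs = []
    acc = 0
    for (s, e), L in zip(exon_spans, exon_lens):
        lo_t, hi_t = max(u5, acc), min(u5 + cds_len, acc + L)
        if lo_t < hi_t:
            sense_span = (s + (lo_t - acc), s + (hi_t - acc))
            cds_ivs.append(GenomicInterval(chrom, *to_genomic(sense_span),
                                           strand=strand))
        acc += L
    model = TranscriptModel(transcript_id=tid, gene=gene, chrom=chrom,
                            strand=strand, exons=sorted(
                                exon_ivs, key=lambda iv: iv.start),
                            cds=sorted(cds_ivs, key=lambda iv: iv.start))

    # two protein domains: one hit by the cassette exon, one upstream
    protein_len = cds_len // 3
    cass_tx = (sum(exon_lens[:2]), sum(exon_lens[:3]))
    cass_cds = (max(0, cass_tx[0] - u5), min(cds_len, cass_tx[1] - u5))
    hit_first = cass_cds[0] // 3 + 1
    hit_last = min(protein_len, (cass_cds[1] - 1) // 3 + 1)
    domains = [
        (f"{gene}_dom_core", max(1, hit_first - 5),
         min(protein_len, hit_last + 5)),
        (f"{gene}_dom_nterm", 2, max(3, hit_first // 2 + 2)),
    ]

    motif_record = None
    if motif_off is not None:
        g_span = to_genomic((motif_off, motif_off + len(motif_rna)))
        motif_record = {
            "pattern": motif_rna, "region": motif_region, "chrom": chrom,
            "start": int(g_span[0]), "end": int(g_span[1]), "strand": strand,
            "sense_seq": motif_rna}
    # cassette-exon event structure in genomic coordinates
    g_exons = sorted(to_genomic(sp) for sp in exon_spans[1:4])
    (_, a_e), (b_s, b_e), (c_s, _) = g_exons
    struct = {"inclusion_junctions": ((a_e, b_s), (b_e, c_s)),
              "skipping_junctions": ((a_e, c_s),),
              "exon": (b_s, b_e)}
    return model, chrom_seq, domains, motif_record, struct


def generate_sequence_layer(config: SimConfig, rng: np.random.Generator,
                            events: list[SpliceEvent],
                            max_models: int = 8):
    """Transcript models + genome with planted Sm motifs for ES events.

    The first ``max_models`` planted (non-null dPSI is implied by event
    order) exon-skipping events get a dedicated transcript model; their
    junction coordinates are rewritten to the model's cassette exon.
    Strands and motif regions alternate so both orientations and all three
    window regions are exercised.
    """
    from .motifs import VARIANT_MOTIFS  # local to avoid a cycle at import

    canonical = ["GAUUUUG", "AAUUUUUG", "GAUUUUUUG"]
    motif_cycle = canonical + list(VARIANT_MOTIFS)
    regions = ["upstream_flank", "exon", "downstream_flank"]

    es_events = [ev for ev in events if ev.mode == "ES"][:max_models]
    models: dict[str, TranscriptModel] = {}
    genome: dict[str, str] = {}
    domains: dict[str, list[tuple[str, int, int]]] = {}
    motif_truth: dict[str, list[dict]] = {}
    skipped: list[dict] = []
    for i, ev in enumerate(es_events):
        tid = f"T_{ev.gene}"
        chrom = f"chrT{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        motif = motif_cycle[i % len(motif_cycle)]
        region = regions[i % len(regions)]
        model, chrom_seq, doms, motif_rec, struct = _build_transcript(
            rng, tid, ev.gene, chrom, strand, config, motif, region)
        models[tid] = model
        genome[chrom] = chrom_seq
        domains[tid] = doms
        ev.transcript_id = tid
        ev.chrom = chrom
        ev.strand = strand
        ev.inclusion_junctions = tuple(sorted(struct["inclusion_junctions"]))
        ev.skipping_junctions = tuple(struct["skipping_junctions"])
        ev.exon = struct["exon"]
        if motif_rec is None:
            skipped.append({"event_id": ev.event_id, "pattern": motif,
                            "region": region, "reason": "no valid placement"})
        else:
            motif_rec["event_id"] = ev.event_id
            motif_truth[ev.event_id] = [motif_rec]
    return models, genome, domains, motif_truth, skipped


# ---------------------------------------------------------------------------
# assay layer

def generate_assay_layer(config: SimConfig, rng: np.random.Generator,
                         roles: dict):
    driver = roles["driver"]
    qpcr_rows, true_fold = [], {}
    for cond, fold in (("si-NC", 1.0), ("si-driver#1", 0.25),
                       ("si-driver#2", 0.35)):
        ct_ref_ctrl = 15.0
        ct_ref_case = float(np.round(ct_ref_ctrl + rng.normal(0, 0.1), 3))
        dct_ctrl = 5.0
        ct_tgt_ctrl = ct_ref_ctrl + dct_ctrl
        ddct = -np.log2(fold)
        ct_tgt_case = float(np.round(ct_ref_case + dct_ctrl + ddct, 3))
        qpcr_rows.append({"gene": driver, "condition": cond,
                          "ct_target_case": ct_tgt_case,
                          "ct_ref_case": ct_ref_case,
                          "ct_target_ctrl": ct_tgt_ctrl,
                          "ct_ref_ctrl": ct_ref_ctrl})
        true_fold[cond] = fold
    qpcr = pd.DataFrame(qpcr_rows)

    ldh_rows, true_cyto = [], {}
    for cond, cyto in (("si-NC", 20.0), ("si-driver", 45.0)):
        low, high, eff = 0.20, 1.20, 0.15
        mix = eff + low + cyto / 100.0 * (high - low)
        bg = 0.05
        for well, net in (("mix", mix), ("effector_control", eff),
                          ("low_control", low), ("high_control", high)):
            ldh_rows.append({"condition": cond, "well_class": well,
                             "od490": float(np.round(net + bg, 4)),
                             "od680": bg})
        true_cyto[cond] = cyto
    ldh = pd.DataFrame(ldh_rows)
    return qpcr, ldh, true_fold, true_cyto


# ---------------------------------------------------------------------------
# top-level generation and serialization

def generate_cohort(config: SimConfig) -> tuple[CohortBundle, TruthLedger]:
    """Generate the full synthetic cohort plus its truth ledger.

    Deterministic given ``config`` (byte-identical bundles for identical
    configs).  The driver gene carries a colocalized suggestive GWAS
    variant, tumor overexpression at the configured log2FC, the configured
    hazard ratio on every endpoint, and planted splice-event shifts on its
    validated targets; every decoy fails at least one filter, as recorded
    in the ledger.
    """
    roles = assign_roles(config)
    gwas, sqtl, eqtl, coloc = generate_variant_layer(
        config, layer_rng(config.seed, "variants"), roles)
    rbp = generate_rbp_layer(config, layer_rng(config.seed, "rbp"),
                             gwas, sqtl)
    matrix, labels, planted_fc = generate_expression_layer(
        config, layer_rng(config.seed, "expression"), roles)
    clinical = generate_clinical_layer(
        config, layer_rng(config.seed, "clinical"), roles)
    events, true_dpsi = generate_splicing_layer(
        config, layer_rng(config.seed, "splicing"), roles)
    models, genome, domains, motif_truth, skipped = generate_sequence_layer(
        config, layer_rng(config.seed, "sequence"), events)
    qpcr, ldh, true_fold, true_cyto = generate_assay_layer(
        config, layer_rng(config.seed, "assays"), roles)

    bundle = CohortBundle(
        gwas_table=gwas, sqtl_table=sqtl, eqtl_table=eqtl,
        rbp_intervals=rbp, expression_matrix=matrix, sample_labels=labels,
        clinical_table=clinical, splice_events=events,
        transcript_models=models, genome_sequences=genome, domains=domains,
        qpcr_table=qpcr, ldh_table=ldh)
    decoy_failures = {
        roles["decoys"]["gwas"]: "gwas",
        roles["decoys"]["coloc"]: "coloc",
        roles["decoys"]["de"]: "de",
        roles["decoys"]["splicing_factor"]: "splicing_factor",
        roles["decoys"]["survival"]: "survival",
        roles["decoys"]["survival_direction"]: "survival_direction"}
    ledger = TruthLedger(
        planted_driver=roles["driver"],
        colocalized_variants=coloc,
        true_hr=float(np.exp(config.driver_effects.hazard_log_hr)),
        true_log2fc=config.driver_effects.eqtl_effect,
        true_dpsi=true_dpsi,
        planted_de_log2fc=planted_fc,
        planted_motif_positions=motif_truth,
        skipped_motif_plantings=skipped,
        decoys=decoy_failures,
        splicing_factors=roles["splicing_factors"],
        immune_set=roles["immune_set"],
        malignancy_set=roles["malignancy_set"],
        dual_function_genes=roles["dual_function"],
        splice_altered_genes=sorted(
            {ev.gene for ev in events if true_dpsi[ev.event_id] != 0}),
        qpcr_true_fold=true_fold,
        ldh_true_cytotoxicity=true_cyto)
    return bundle, ledger


def write_bundle(bundle: CohortBundle, ledger: TruthLedger,
                 outdir: str | Path) -> None:
    """Serialize a bundle and its ledger to plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.gwas_table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    bundle.sqtl_table.to_csv(out / "sqtl.tsv", sep="\t", index=False)
    bundle.eqtl_table.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    write_bed(bundle.rbp_intervals, out / "rbp.bed")
    bundle.expression_matrix.to_csv(out / "expression.tsv", sep="\t")
    bundle.clinical_table.to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_events(bundle.splice_events, out / "events.json")
    write_transcript_models(bundle.transcript_models, out / "models.gff3")
    write_genome(bundle.genome_sequences, out / "genome.fa")
    write_domains(bundle.domains, out / "domains.tsv")
    bundle.qpcr_table.to_csv(out / "qpcr.tsv", sep="\t", index=False)
    bundle.ldh_table.to_csv(out / "ldh.tsv", sep="\t", index=False)
    for name, genes in (("splicing_factors", ledger.splicing_factors),
                        ("immune_set", ledger.immune_set),
                        ("malignancy_set", ledger.malignancy_set)):
        (out / f"{name}.txt").write_text("\n".join(genes) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(ledger), fh, indent=1)


def read_ledger(path: str | Path) -> TruthLedger:
    with open(path) as fh:
        return TruthLedger(**json.load(fh))
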