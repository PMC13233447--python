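# Methods

## The triage model

The package implements a funnel prioritisation over candidate disease
genes.  Its stages are intersection filters, not a joint statistical
model, and each stage has an explicit, strict decision rule:

1. **Variant stage.**  A variant qualifies when its GWAS p-value is
   strictly below `gwas_p` (default 0.05, the conventional *suggestive*
   threshold — deliberately far above genome-wide significance, because
   the QTL layers do the specificity work) and the variant is
   simultaneously an sQTL and an eQTL.  "Co-localisation" is shared
   variant identity across the three tables; no Bayesian colocalisation
   posterior is computed.  Candidate sGenes are the sQTL genes of
   qualifying variants — splicing linkage defines the class — with the
   eQTL layer acting as a presence filter; a flag
   (`nominate_sgenes(include_eqtl_genes=True)`) switches to the union for
   sensitivity analyses.  Enrichment of qualifying variants inside
   RBP-binding intervals is a one-sided (upper-tail) hypergeometric test
   with the full GWAS variant list as the universe.
2. **Gene stage.**  Differential expression is tested on log₂(TPM + 1)
   with a two-sided Wilcoxon rank-sum test per gene; the reported log₂FC
   is the difference of group means on that scale.  A rank test was
   chosen because the upstream DE resource in this setting does not
   document its test, and a distribution-free choice is robust to the
   heavy tails of TPM data.  Candidates are the three-way intersection of
   sGenes, DE genes (|log₂FC| > 1 and p < 0.05, both strict), and a
   user-supplied core splicing-factor list.
3. **Survival stage.**  Expression enters Cox proportional-hazards models
   as a continuous covariate (no dichotomisation bias); each model applies
   its own complete-case filter, additionally dropping zero-day
   follow-ups.  Ties use the Breslow approximation; inference is Wald.
   A candidate is *stable* when HR > 1 and p < `survival_p` on **all**
   supplied endpoints — direction-consistent significance.  The default
   endpoint set is (OS, PFS); DFS is generated and can be added.
   Median-split stratification (ties to the low group, a deterministic
   convention) and the log-rank test serve the descriptive
   Kaplan–Meier-style comparisons; baseline characteristic tables use
   available-case denominators (each characteristic's denominator is its
   own non-missing count per group) with chi-square tests, falling back
   to Fisher's exact for 2×2 tables with any expected cell below 5.
4. **Splicing stage.**  PSI = 100·I/(I+S); undefined (not 0) when both
   counts are zero, and zero-total replicates are excluded rather than
   imputed.  ΔPSI is the difference of per-group replicate means on the
   fraction scale, so the printed 0.1 threshold means 10 percentage
   points.  The p-value is a two-sided Fisher's exact test on the pooled
   2×2 inclusion/skipping × condition table — a transparent, exact
   stand-in for likelihood-ratio splicing tests (rMATS-style models); it
   ignores replicate-level overdispersion and is deliberately isolated in
   `event_group_test` so it can be replaced.  FDR is Benjamini–Hochberg
   over all events tested in one batch; significance requires
   |ΔPSI| > 0.1 **and** q < 0.05, both strict.
5. **Motif stage.**  The scanner matches the canonical Sm site RAU₄₋₆G
   (R = purine {A, G}; the run length n ∈ {4,5,6} is reported as its own
   pattern, so nested matches inside longer U-runs all appear) and five
   literal physiological variants, on the sense strand only — Sm proteins
   bind pre-mRNA, so antisense hits are meaningless.  Windows are the
   skipped exon plus up to `flank_len` (default 200 nt) of each adjacent
   intron, truncated at neighbouring exon boundaries and empty on a
   terminal exon's missing side.  No conservation filter is applied, so
   hit lists are a superset of conservation-filtered predictions; no
   affinity scoring or PWM is implied.
6. **Consequence stage.**  Skipping an exon removes its CDS nucleotides
   from the spliced transcript.  Frame is preserved iff the removed
   length is divisible by 3.  The deleted-residue interval covers every
   codon with at least one removed nucleotide (1-based, inclusive); a
   split codon at the junction is flagged `junction_codon_novel` because
   the hybrid codon may encode a novel residue.  Frameshifts disrupt
   everything downstream, so their interval runs to the end of the
   reference protein and domain impact distinguishes only
   upstream-intact from full loss; in-frame deletions truncate exactly
   the overlapping domains (a fully covered domain reports an overlap
   equal to its length).  The mapping is validated against an
   independent per-nucleotide provenance + translate-and-diff oracle.

Protein length is counted as CDS length / 3 codons (the terminal stop
codon occupies the last slot); generated domains never extend into it.

## The synthetic cohort generator

`synth.generate_cohort` emulates the data layers of the real study at
desk scale and records every planted effect in a `TruthLedger`.  A single
root seed feeds named child streams (fixed `spawn_key` per layer), so
adding a layer never perturbs the others and bundles are byte-identical
for identical configurations.

Default study conditions (`SimConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_variants` | 500 | enough background for a stable enrichment universe |
| `n_genes` | 200 | covers all planted roles plus background |
| `n_tumor` / `n_normal` | 60 / 60 | a scaled-down tumor/normal contrast with ample rank-sum power at log₂FC = 2 |
| `n_patients` | 400 | matches the hazard-recovery study size |
| `gwas_p_target` | 1e-4 | clearly suggestive without being genome-wide |
| `eqtl_effect` | 2.0 | log₂FC of the driver in tumors |
| `hazard_log_hr` | ln 2 | HR = 2 per SD of driver expression |
| `true_dpsi_list` | (0.3, −0.3, 0.2) | validated-target effect sizes |
| `n_events` / coverage / reps | 60 / 100 / 3 | typical junction coverage of a knockdown RNA-seq experiment |
| missingness | age 0.2%, race 6% | mirrors the available-case gaps of the worked-example baseline table |

Layer models: GWAS p-values are Uniform(0,1) for background variants with
signal variants assigned their target p directly (the simplest faithful
null); expression is log-normal on the log₂ scale (per-gene baseline
µ ~ U(3,8), noise sd 0.5) exponentiated and renormalised so every sample
sums to 10⁶ TPM.  Planted genes get a fixed moderate baseline (µ = 5) so
the +1 pseudocount does not compress the fold while the planted raw mass
stays a small fraction of the per-sample total — TPM is compositional,
and large planted mass would attenuate realised fold changes through the
renormalisation.  Survival times are exponential with hazard
h₀·exp(β·z), h₀ = 0.01/day, with independent Uniform(0, 3.2/h₀)
censoring, which yields ≈30% censoring at β = 0; covariates
(age/stage/grade/race) are drawn to resemble an endometrial-carcinoma
cohort and are missing completely at random at the configured rates.
Junction counts are per-replicate totals ~ Poisson(coverage) with
inclusion ~ Binomial(total, PSI).  Transcript models are 5-exon genes
with a coding cassette exon, CDS assembled from stop-free random codons
(ATG…TAA), introns long enough to hold full 200-nt flanks, alternating
strands; Sm motifs are written into the exon or a flank at recorded
positions, with exonic placements re-validated against in-frame stops
and skipped (ledger-recorded) when no valid placement exists.

Decoys each fail exactly one filter — weak GWAS p, missing eQTL link, no
differential expression, absent from the splicing-factor set, null
hazard, or significant-but-protective hazard — so the pipeline's
specificity is testable stage by stage.  The protective decoy's
expression is negatively correlated with the driver's (r ≈ −0.8) so its
univariate HR is reliably below 1 without attenuating the driver's
marginal hazard.

What the generator does **not** emulate: linkage disequilibrium between
variants, read-level RNA-seq (events enter as junction counts),
overdispersion beyond binomial sampling in junction counts, informative
missingness, correlated gene-gene expression structure, and copy-number
or mutation layers.  Passing recovery tests therefore demonstrates the
pipeline's correctness under clean generative assumptions, not its
robustness to those real-data complications.

## Calibration studies and problem sizes

`splicescreen.calibration` re-runs the machinery over fresh simulations:
null-FDR (20 seeds × 2,000 null events), ΔPSI recovery (20 seeds × 200
planted events), two-group hazard recovery (100 seeds, n = 400, HR = 2,
≈30% censoring), null-covariate CI coverage (200 seeds), and end-to-end
driver recovery (50 seeds at the default conditions).  These sizes give
stable rates while keeping each study in the seconds-to-a-minute range.

A consequence of the default splicing conditions worth stating: at
coverage 100 with 3 replicates per group, the per-event ΔPSI estimator's
standard error is √(p₁q₁/300 + p₂q₂/300) ≈ 0.037, so roughly 83% of
per-event estimates fall within ±0.05 of a planted ΔPSI = 0.3 — the
estimator is unbiased (the seed-averaged estimate sits on the planted
value) but a ±0.05 per-event band is below the sampling noise floor of
that design; tightening it requires coverage ≈260+ or ≈8 replicates.
The acceptance script reports both the per-event rate and the mean
estimate.

## Known limitations

- The Fisher-on-pooled-counts splicing test treats replicates as
  exchangeable reads; with real biological replicates it is
  anti-conservative relative to likelihood-ratio models.
- The motif scanner is a literal pattern engine: no conservation filter,
  no affinity scoring, no claim of physical binding.
- The hypergeometric RBP enrichment ignores variant clustering (no LD in
  the generator, and none modelled in the test).
- r×c baseline tables with sparse cells fall back to chi-square (an
  exact r×c test is not implemented); 2×2 tables use Fisher's exact.
- The generic over-representation test (`ora_hypergeometric`) is the
  statistical core only; annotation databases are out of scope.
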