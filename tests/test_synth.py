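"""Generator contracts: determinism, planted-signal faithfulness, and
ledger completeness."""

import numpy as np
import pytest

from splicescreen.splice import compute_psi
from splicescreen.synth import (ConfigError, SimConfig, assign_roles,
                                draw_event_counts, generate_cohort,
                                generate_expression_layer, layer_rng,
                                plant_motif, simulate_psi_events)
from splicescreen.transcripts import reverse_complement


class TestConfig:
    def test_driver_must_be_a_generated_gene(self):
        with pytest.raises(ConfigError, match="driver gene"):
            SimConfig(driver_gene="NOT_A_GENE")

    def test_counts_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimConfig(n_patients=0)

    def test_missingness_rates_bounded(self):
        with pytest.raises(ConfigError):
            SimConfig(missingness_rates={"age": 1.5})


class TestDeterminism:
    def test_same_config_gives_identical_bundles(self):
        cfg = SimConfig(seed=7, n_genes=90, n_patients=50, n_events=45,
                        n_tumor=10, n_normal=10)
        b1, l1 = generate_cohort(cfg)
        b2, l2 = generate_cohort(cfg)
        assert b1.gwas_table.equals(b2.gwas_table)
        assert b1.expression_matrix.equals(b2.expression_matrix)
        assert b1.clinical_table.equals(b2.clinical_table)
        assert b1.genome_sequences == b2.genome_sequences
        assert [e.counts for e in b1.splice_events] == \
            [e.counts for e in b2.splice_events]
        assert l1.true_dpsi == l2.true_dpsi

    def test_dimension_contract(self):
        cfg = SimConfig(seed=2, n_genes=120, n_tumor=8, n_normal=8,
                        n_patients=40, n_events=45)
        bundle, _ = generate_cohort(cfg)
        assert bundle.expression_matrix.shape == (120, 16)
        assert len(bundle.clinical_table) == 40
        assert len(bundle.splice_events) == 45


class TestLedgerContracts:
    def test_driver_appears_in_sqtl_table(self, cohort):
        bundle, ledger = cohort
        assert ledger.planted_driver in set(bundle.sqtl_table.gene)

    def test_colocalized_variants_exist_in_all_tables(self, cohort):
        bundle, ledger = cohort
        for vid in ledger.colocalized_variants:
            assert vid in set(bundle.gwas_table.variant_id)
            assert vid in set(bundle.sqtl_table.variant_id)
        driver_vids = set(bundle.sqtl_table.query(
            "gene == @ledger.planted_driver").variant_id)
        assert driver_vids & set(ledger.colocalized_variants)

    def test_planted_dpsi_recorded(self, cohort):
        bundle, ledger = cohort
        cfg_dpsi = SimConfig().driver_effects.true_dpsi_list
        recorded = sorted(v for v in ledger.true_dpsi.values() if v != 0)
        for d in cfg_dpsi:
            assert d in recorded
        assert 0.0 in ledger.true_dpsi.values()  # null events present

    def test_every_gene_set_references_generated_genes(self, cohort):
        bundle, ledger = cohort
        genes = set(bundle.expression_matrix.index)
        for s in (ledger.splicing_factors, ledger.immune_set,
                  ledger.malignancy_set, ledger.dual_function_genes):
            assert set(s) <= genes


class TestSplicingLayer:
    def test_psi_one_gives_zero_skipping(self, rng):
        counts = draw_event_counts(rng, psi=1.0, coverage=50, reps=10)
        assert all(s == 0 for _, s in counts)

    def test_null_events_have_mean_dpsi_near_zero(self, rng):
        events = simulate_psi_events(2000, 0.0, coverage=100, reps=3,
                                     rng=rng)
        deltas = []
        for ca, cb, _ in events:
            pa = np.mean([compute_psi(i, s) for i, s in ca])
            pb = np.mean([compute_psi(i, s) for i, s in cb])
            deltas.append((pb - pa) / 100)
        assert abs(float(np.mean(deltas))) < 0.02


class TestSequenceLayer:
    def test_planted_motifs_recovered_from_genome(self, cohort):
        bundle, ledger = cohort
        assert ledger.planted_motif_positions  # something was planted
        for recs in ledger.planted_motif_positions.values():
            for r in recs:
                sense_dna = r["sense_seq"].replace("U", "T")
                expected = sense_dna if r["strand"] == "+" else \
                    reverse_complement(sense_dna)
                sliced = bundle.genome_sequences[r["chrom"]][
                    r["start"]:r["end"]]
                assert sliced == expected

    def test_minus_strand_models_planted(self, cohort):
        bundle, ledger = cohort
        strands = {bundle.transcript_models[
            bundle.splice_events[int(eid[1:]) - 1].transcript_id].strand
            for eid in ledger.planted_motif_positions}
        assert strands == {"+", "-"}

    def test_exon_shorter_than_motif_skips_planting(self, rng):
        out = plant_motif("A" * 100, exon_span=(50, 54),
                          motif_rna="GAUUUUG", region="exon",
                          flank_len=200, rng=rng)
        assert out is None


class TestStatisticalFaithfulness:
    def test_driver_log2fc_matches_configuration_on_average(self):
        cfg = SimConfig()
        roles = assign_roles(cfg)
        fcs = []
        for seed in range(100):
            c = SimConfig(seed=seed, n_tumor=30, n_normal=30)
            m, labels, _ = generate_expression_layer(
                c, layer_rng(seed, "expression"), roles)
            logm = np.log2(m + 1)
            t = logm.loc[roles["driver"], labels == "tumor"].mean()
            n = logm.loc[roles["driver"], labels == "normal"].mean()
            fcs.append(t - n)
        assert abs(np.mean(fcs) - cfg.driver_effects.eqtl_effect) < 0.2

    def test_survival_separation_direction_matches_hazard_sign(self, cohort):
        bundle, ledger = cohort
        clin = bundle.clinical_table
        high = clin.expression > clin.expression.median()
        # higher expression -> higher hazard -> shorter observed times
        assert clin.loc[high, "os_time"].mean() < \
            clin.loc[~high, "os_time"].mean()


class TestClinicalLayer:
    def test_tpm_sums_to_one_million(self, cohort):
        bundle, _ = cohort
        sums = bundle.expression_matrix.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_missingness_applied(self, cohort):
        bundle, _ = cohort
        assert bundle.clinical_table.race.isna().sum() > 0

    def test_zero_day_followups_planted(self, cohort):
        bundle, _ = cohort
        assert (bundle.clinical_table.os_time == 0).sum() >= 1
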