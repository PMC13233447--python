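"""PSI arithmetic, event-mode classification, differential testing, and
BH-FDR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen.config import ScreenThresholds
from splicescreen.splice import (EventTestResult, SpliceEvent,
                                 UnclassifiedEventError, classify_event,
                                 compute_psi, event_group_test, fdr_adjust,
                                 filter_events, psi_from_gel_bands,
                                 read_events, run_event_tests, write_events)


class TestComputePsi:
    @pytest.mark.parametrize("inc, skp, expected", [
        (50, 50, 50.0), (100, 0, 100.0), (30, 90, 25.0)])
    def test_formula(self, inc, skp, expected):
        assert compute_psi(inc, skp) == pytest.approx(expected)

    def test_zero_total_is_undefined_not_zero(self):
        assert compute_psi(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 5)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10**4), st.integers(0, 10**4))
    def test_complementarity(self, a, b):
        if a + b == 0:
            assert compute_psi(a, b) is None
        else:
            assert compute_psi(a, b) + compute_psi(b, a) == \
                pytest.approx(100.0)
            assert 0 <= compute_psi(a, b) <= 100

    @pytest.mark.parametrize("up, low, expected", [
        (1000, 1000, 50.0), (0, 500, 0.0), (300, 100, 75.0)])
    def test_gel_band_psi(self, up, low, expected):
        assert psi_from_gel_bands(up, low) == pytest.approx(expected)
        assert psi_from_gel_bands(0, 0) is None


def ev(inc=(), skp=(), strand="+", retained=None, **kw):
    return SpliceEvent(event_id="e", gene="g", chrom="chr1", strand=strand,
                       inclusion_junctions=inc, skipping_junctions=skp,
                       retained_intron=retained, **kw)


class TestClassifyEvent:
    def test_cassette_exon_is_es(self):
        e = ev(inc=((100, 200), (260, 400)), skp=((100, 400),))
        assert classify_event(e) == "ES"

    def test_intron_retention(self):
        e = ev(skp=((100, 200),), retained=(100, 200))
        assert classify_event(e) == "IR"

    def test_alt_donor_plus_strand(self):
        # two left-boundary (donor) choices sharing the acceptor
        e = ev(inc=((130, 200),), skp=((100, 200),), strand="+")
        assert classify_event(e) == "A5SS"

    def test_strand_flip_swaps_a5ss_a3ss(self):
        plus = ev(inc=((130, 200),), skp=((100, 200),), strand="+")
        minus = ev(inc=((130, 200),), skp=((100, 200),), strand="-")
        assert classify_event(plus) == "A5SS"
        assert classify_event(minus) == "A3SS"
        plus_r = ev(inc=((100, 170),), skp=((100, 200),), strand="+")
        minus_r = ev(inc=((100, 170),), skp=((100, 200),), strand="-")
        assert classify_event(plus_r) == "A3SS"
        assert classify_event(minus_r) == "A5SS"

    def test_mutually_exclusive_exons(self):
        e = ev(inc=((100, 150), (230, 500)), skp=((100, 300), (380, 500)))
        assert classify_event(e) == "MXE"

    def test_unclassifiable_structure_raises(self):
        with pytest.raises(UnclassifiedEventError):
            classify_event(ev(inc=((1, 2), (3, 4), (5, 6))))

    def test_generated_events_classify_as_labelled(self, cohort):
        bundle, _ = cohort
        for e in bundle.splice_events:
            assert classify_event(e) == e.mode


class TestEventGroupTest:
    def test_balanced_pooled_tables_are_null(self):
        r = event_group_test(ev(), [(50, 50)], [(50, 50)])
        assert r.delta_psi == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_strong_shift(self):
        r = event_group_test(ev(), [(90, 10)], [(10, 90)])
        assert r.delta_psi == pytest.approx(-0.8)
        assert r.p < 1e-6

    def test_zero_total_replicate_excluded(self):
        r = event_group_test(ev(), [(50, 50), (0, 0)], [(60, 40)])
        assert r.psi_a == [50.0]
        assert r.delta_psi == pytest.approx(0.1)

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError):
            event_group_test(ev(), [(0, 0), (0, 0)], [(10, 10)])

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = [tuple(rng.integers(0, 200, 2)) for _ in range(3)]
            b = [tuple(rng.integers(0, 200, 2)) for _ in range(3)]
            if all(sum(c) == 0 for c in a) or all(sum(c) == 0 for c in b):
                continue
            fwd = event_group_test(ev(), a, b)
            rev = event_group_test(ev(), b, a)
            assert fwd.delta_psi == pytest.approx(-rev.delta_psi)
            assert fwd.p == pytest.approx(rev.p)


class TestFdrAdjust:
    def test_hand_computed_bh(self):
        # m=4: q_i = min over j>=i of p_(j)*m/j, all equal 0.04 here
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37]) == pytest.approx([0.37])

    def test_monotone_in_ranked_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 100))
        q = fdr_adjust(list(p))
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(q, q[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestFilterEvents:
    def result(self, dpsi, q):
        return EventTestResult("e", "g", [50.0], [50.0], dpsi, 0.01, q=q)

    @pytest.mark.parametrize("dpsi, q, expected", [
        (0.10, 1e-9, False),  # strict |dPSI| boundary
        (0.25, 0.01, True),
        (0.25, 0.06, False),
        (-0.25, 0.01, True),
    ])
    def test_strict_boundaries(self, dpsi, q, expected):
        sig, per_gene = filter_events([self.result(dpsi, q)])
        assert bool(sig) is expected
        assert ("g" in per_gene) is expected

    def test_missing_q_rejected(self):
        r = self.result(0.25, None)
        r.q = None
        with pytest.raises(ValueError):
            filter_events([r])

    def test_per_gene_rollup_counts_events(self):
        results = [self.result(0.3, 0.01) for _ in range(3)]
        _, per_gene = filter_events(results)
        assert per_gene == {"g": 3}


class TestEventsJson:
    def test_round_trip(self, tmp_path, cohort):
        bundle, _ = cohort
        p = tmp_path / "events.json"
        write_events(bundle.splice_events, p)
        back = read_events(p)
        assert len(back) == len(bundle.splice_events)
        for a, b in zip(bundle.splice_events, back):
            assert (a.event_id, a.gene, a.mode, a.strand) == \
                (b.event_id, b.gene, b.mode, b.strand)
            assert a.inclusion_junctions == b.inclusion_junctions
            assert a.counts == b.counts

    def test_batch_testing_flags_planted_events(self, cohort):
        bundle, ledger = cohort
        results = run_event_tests(bundle.splice_events)
        by_id = {r.event_id: r for r in results}
        strong = [e for e, d in ledger.true_dpsi.items() if abs(d) >= 0.3]
        flagged = sum(by_id[e].significant for e in strong)
        assert flagged >= 0.9 * len(strong)
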