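import numpy as np
import pandas as pd
import pytest

from exonsplice.consequence import (ALT_C, ALT_CODING, ALT_N, INTRON_RETENTION,
                                    NMD, TRUNCATION, ConsequenceParams,
                                    classify_event, partition_isoforms,
                                    ptc_status, summarize_consequences,
                                    ConsequenceCall)
from exonsplice.exprio import TranscriptModel


def _tm(tid, exons, cds, strand="+", gene="g1"):
    return TranscriptModel(gene_id=gene, transcript_id=tid, chrom="c",
                           strand=strand, exons=tuple(exons), cds=tuple(cds))


class _Ev:
    def __init__(self, direction, gene_id="g1", probeset_id="ps1"):
        self.direction = direction
        self.gene_id = gene_id
        self.probeset_id = probeset_id


def _stop_at_distance(dist):
    """Two-exon plus-strand transcript whose stop sits ``dist`` nt upstream
    of the (only) exon-exon junction; CDS length is kept a codon multiple."""
    l1 = dist + 120
    start = l1 - dist - 3 * ((l1 - dist) // 3)  # CDS start so length % 3 == 0
    return _tm("t", [(0, l1), (l1 + 200, l1 + 400)],
               [(start, l1 - dist)])


class TestPtcStatus:
    @pytest.mark.parametrize("dist,expected", [
        (0, False), (50, False), (51, True), (60, True)])
    def test_fifty_nt_rule_boundary(self, dist, expected):
        m = _stop_at_distance(dist)
        st = ptc_status(m, nmd_nt=50)
        assert st.distance_nt == dist
        assert st.has_ptc is expected

    def test_stop_in_last_exon_never_ptc(self):
        m = _tm("t", [(0, 90), (200, 500)], [(9, 90), (200, 320)])
        st = ptc_status(m)
        assert st.distance_nt <= 0 and not st.has_ptc

    def test_single_exon_never_ptc(self):
        m = _tm("t", [(0, 300)], [(0, 300)])
        st = ptc_status(m)
        assert not st.has_ptc and st.distance_nt is None

    def test_invalid_frame_excluded(self):
        m = _tm("t", [(0, 100), (200, 400)], [(0, 100)])  # 100 % 3 != 0
        st = ptc_status(m)
        assert not st.frame_valid and not st.has_ptc

    def test_threshold_monotonicity(self):
        """Raising the PTC distance threshold never adds NMD-eligible calls."""
        for dist in (0, 30, 51, 80, 200):
            m = _stop_at_distance(dist)
            flags = [ptc_status(m, nmd_nt=t).has_ptc for t in (25, 50, 100)]
            assert flags == sorted(flags, reverse=True)

    def test_minus_strand_distance(self):
        # mirror of a plus-strand 60-nt PTC layout
        m = _tm("t", [(0, 200), (400, 520)], [(460, 520)], strand="-")
        st = ptc_status(m)
        assert st.distance_nt == 60 and st.has_ptc


class TestPartition:
    def setup_method(self):
        self.a = _tm("tA", [(0, 100), (200, 300), (400, 500)],
                     [(9, 100), (200, 300), (400, 430)])
        self.b = _tm("tB", [(0, 100), (400, 500)], [(9, 100), (400, 433)])

    def test_cassette_exon_splits(self):
        w, wo = partition_isoforms([self.a, self.b], (200, 300))
        assert [m.transcript_id for m in w] == ["tA"]
        assert [m.transcript_id for m in wo] == ["tB"]

    def test_constitutive_region_all_with(self):
        w, wo = partition_isoforms([self.a, self.b], (0, 100))
        assert len(w) == 2 and not wo

    def test_majority_overlap_rule(self):
        # region straddling the cassette boundary: 60% inside exon
        w, _ = partition_isoforms([self.a, self.b], (240, 340))
        assert [m.transcript_id for m in w] == ["tA"]

    def test_region_outside_all_isoforms_gives_no_consequences(self):
        call = classify_event(_Ev("inclusion"), [self.a, self.b], (150, 190))
        assert call.consequences == frozenset()

    def test_constitutive_region_yields_empty_call(self):
        call = classify_event(_Ev("inclusion"), [self.a, self.b], (0, 100))
        assert call.consequences == frozenset()


class TestClassifyEvent:
    def test_nmd_and_truncation_fire_together(self):
        """Frameshifting exclusion: the skip drops the protein from 250 to
        66 aa and leaves the new stop 240 nt before the last junction, so
        both NMD and truncation fire by construction."""
        full = _tm("tA", [(0, 150), (300, 600), (700, 1000), (1200, 1400)],
                   [(9, 150), (300, 600), (700, 1000), (1200, 1212)])
        short = _tm("tB", [(0, 150), (700, 1000), (1200, 1400)],
                    [(9, 150), (700, 760)])      # 201 nt CDS, stop mid-gene
        call = classify_event(_Ev("exclusion"), [full, short], (300, 600))
        assert NMD in call.consequences
        assert TRUNCATION in call.consequences
        ev = call.evidence[0]
        assert ev.ptc_distance_nt == 240
        assert ev.protein_ratio == pytest.approx(66 / 250)

    @pytest.mark.parametrize("ratio,fires", [(0.5, True), (0.49, True),
                                             (0.51, False)])
    def test_truncation_boundary(self, ratio, fires):
        n_other = 100
        n_fav = int(round(ratio * n_other))
        other = _tm("tA", [(0, 400), (600, 1000)],
                    [(0, 3 * (n_other + 1))])
        fav = _tm("tB", [(0, 300), (600, 1000)], [(0, 3 * (n_fav + 1))])
        # silence the PTC rule so only the length-ratio rule is probed
        params = ConsequenceParams(nmd_nt=10**9)
        call = classify_event(_Ev("exclusion"), [other, fav], (310, 390),
                              params)
        assert (TRUNCATION in call.consequences) is fires

    def test_alternative_first_exon_altn_only(self):
        a = _tm("tA", [(0, 90), (500, 700), (900, 1100)],
                [(9, 90), (500, 700), (900, 955)])   # 81+200+55=336
        b = _tm("tB", [(200, 290), (500, 700), (900, 1100)],
                [(230, 290), (500, 700), (900, 955)])  # 60+200+55=315
        call = classify_event(_Ev("inclusion"), [a, b], (0, 90))
        assert call.consequences == {ALT_N}

    def test_both_termini_differ_gives_altn_and_altc(self):
        a = _tm("tA", [(0, 90), (500, 700)], [(9, 90), (500, 632)])
        b = _tm("tB", [(200, 290), (500, 700)], [(230, 290), (500, 656)])
        call = classify_event(_Ev("inclusion"), [a, b], (0, 90))
        assert {ALT_N, ALT_C}.issubset(call.consequences)
        assert ALT_CODING not in call.consequences

    def test_intron_retention_with_inframe_recoding(self):
        retained = _tm("tA", [(0, 450)], [(9, 345)])
        spliced = _tm("tB", [(0, 150), (300, 450)], [(9, 150), (300, 345)])
        call = classify_event(_Ev("inclusion"), [retained, spliced], (150, 300))
        assert INTRON_RETENTION in call.consequences
        assert ALT_CODING in call.consequences

    def test_inframe_cassette_alt_coding_only(self):
        a = _tm("tA", [(0, 150), (300, 390), (600, 900)],
                [(9, 150), (300, 390), (600, 690)])
        b = _tm("tB", [(0, 150), (600, 900)], [(9, 150), (600, 690)])
        call = classify_event(_Ev("exclusion"), [a, b], (300, 390))
        assert call.consequences == {ALT_CODING}

    def test_pure_function(self, strong_sim):
        from exonsplice.consequence import annotate_events
        truth = strong_sim.truth
        events = pd.DataFrame({"probeset_id": truth["probeset_id"],
                               "gene_id": truth["gene_id"],
                               "direction": truth["direction"]})
        c1 = annotate_events(events, strong_sim.models, strong_sim.probeset_map)
        c2 = annotate_events(events, strong_sim.models, strong_sim.probeset_map)
        assert [c.consequences for c in c1] == [c.consequences for c in c2]

    def test_truth_table_recovered_exactly(self, strong_sim):
        """Given true annotations and true events, the classifier returns
        exactly the planted consequence sets (100% concordance)."""
        from exonsplice.consequence import annotate_events
        truth = strong_sim.truth
        events = pd.DataFrame({"probeset_id": truth["probeset_id"],
                               "gene_id": truth["gene_id"],
                               "direction": truth["direction"]})
        calls = annotate_events(events, strong_sim.models,
                                strong_sim.probeset_map)
        for call, want in zip(calls, truth["consequences"]):
            assert "|".join(sorted(call.consequences)) == want


class TestSummary:
    def _call(self, ps, labels):
        return ConsequenceCall(probeset_id=ps, gene_id="g", direction="inclusion",
                               consequences=frozenset(labels))

    def test_counts_and_overlap(self):
        s = summarize_consequences([self._call("p1", {NMD}),
                                    self._call("p2", {NMD, TRUNCATION})])
        assert s.counts[NMD] == 2 and s.counts[TRUNCATION] == 1
        assert s.overlap.loc[NMD, TRUNCATION] == 1
        assert s.n_predictions == 3
        assert s.frac_multi == pytest.approx(0.5)

    def test_empty_input_all_zero(self):
        s = summarize_consequences([])
        assert s.n_events == 0 and s.n_predictions == 0
        assert all(v == 0 for v in s.counts.values())

    def test_planted_nmd_fraction_recovered(self):
        """With nmd_event_fraction=0.25 of planted events, the recovered NMD
        fraction matches within the binomial CI."""
        from exonsplice.consequence import annotate_events
        from exonsplice.synthdata import SimConfig, simulate
        sim = simulate(SimConfig(n_genes=200, event_fraction=0.5,
                                 nmd_event_fraction=0.25, seed=17))
        truth = sim.truth
        events = pd.DataFrame({"probeset_id": truth["probeset_id"],
                               "gene_id": truth["gene_id"],
                               "direction": truth["direction"]})
        calls = annotate_events(events, sim.models, sim.probeset_map)
        frac = np.mean([NMD in c.consequences for c in calls])
        n = len(calls)
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n) + 1 / n
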