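"""Consensus peaks, the four-state classifier and gain/loss comparison."""

import itertools

import numpy as np
import pytest

from endoepi.genomic_core import GeneModel, GenomicInterval, Peak, PeakSet
from endoepi.histone_states import (
    DifferentialEnrichment,
    HistoneState,
    HistoneStateCall,
    classify_gene_state,
    compare_states,
    consensus_peaks,
    differential_enrichment,
    differential_enrichment_run,
    state_expression_summary,
    state_from_flags,
)


def peakset(mark, intervals, cell="BEC", rep="rep1"):
    return PeakSet(mark, cell, rep, [Peak(GenomicInterval("chr1", s, e)) for s, e in intervals])


GENE = GeneModel("G1", GenomicInterval("chr1", 10_000, 20_000, "+"))
# promoter window is [8000, 11000)


class TestConsensus:
    def test_one_way_overlap_keeps_rep1_coordinates(self):
        cons = consensus_peaks(peakset("H3K4me3", [(0, 100)]), peakset("H3K4me3", [(50, 150)], rep="rep2"))
        assert [(p.interval.start, p.interval.end) for p in cons.peaks] == [(0, 100)]
        assert cons.replicate == "consensus"

    def test_disjoint_replicates_yield_empty_set(self):
        cons = consensus_peaks(peakset("H3K4me3", [(0, 100)]), peakset("H3K4me3", [(200, 300)], rep="rep2"))
        assert len(cons) == 0

    def test_only_supported_peaks_survive(self):
        cons = consensus_peaks(
            peakset("H3K4me3", [(0, 100), (500, 600)]),
            peakset("H3K4me3", [(90, 110)], rep="rep2"),
        )
        assert [(p.interval.start, p.interval.end) for p in cons.peaks] == [(0, 100)]

    def test_idempotent_on_identical_replicates(self):
        rep = peakset("H3K27me3", [(0, 100), (500, 600)])
        cons = consensus_peaks(rep, rep)
        assert [p.interval for p in cons.peaks] == [p.interval for p in rep.peaks]

    def test_mark_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks(peakset("H3K4me3", [(0, 10)]), peakset("H3K27me3", [(0, 10)]))


class TestClassifier:
    def test_rule_table_is_total_and_deterministic(self):
        """Every flag configuration maps to exactly one state."""
        expected = {}
        for k4p, k27p, body_high, extra_mark in itertools.product([False, True], repeat=4):
            any_mark = k4p or k27p or body_high or extra_mark
            if k4p and k27p:
                want = (HistoneState.BIVALENT, False)
            elif k4p and not body_high:
                want = (HistoneState.ACTIVE, False)
            elif (k27p and not k4p) or body_high:
                want = (HistoneState.REPRESSED, False)
            elif not any_mark:
                want = (HistoneState.UNMARKED, False)
            else:
                want = (HistoneState.UNMARKED, True)
            expected[(k4p, k27p, body_high, any_mark)] = want
        for (k4p, k27p, body_high, any_mark), want in expected.items():
            assert state_from_flags(k4p, k27p, body_high, any_mark) == want

    def test_k4_promoter_only_is_active(self):
        call = classify_gene_state(GENE, peakset("H3K4me3", [(9_000, 10_500)]), peakset("H3K27me3", []))
        assert call.state == HistoneState.ACTIVE and not call.atypical

    def test_body_repression_overrides_active_promoter(self):
        call = classify_gene_state(
            GENE,
            peakset("H3K4me3", [(9_000, 10_500)]),
            peakset("H3K27me3", [(11_000, 19_000)]),  # 80% of gene body
        )
        assert call.state == HistoneState.REPRESSED

    def test_no_peaks_is_unmarked(self):
        call = classify_gene_state(GENE, peakset("H3K4me3", []), peakset("H3K27me3", []))
        assert call.state == HistoneState.UNMARKED and not call.atypical

    def test_both_marks_at_promoter_is_bivalent(self):
        call = classify_gene_state(
            GENE, peakset("H3K4me3", [(9_000, 10_500)]), peakset("H3K27me3", [(8_500, 10_000)])
        )
        assert call.state == HistoneState.BIVALENT

    def test_k27_promoter_without_k4_is_repressed(self):
        call = classify_gene_state(GENE, peakset("H3K4me3", []), peakset("H3K27me3", [(8_500, 10_000)]))
        assert call.state == HistoneState.REPRESSED

    def test_body_only_k4_is_atypical_unmarked(self):
        call = classify_gene_state(GENE, peakset("H3K4me3", [(15_000, 16_000)]), peakset("H3K27me3", []))
        assert call.state == HistoneState.UNMARKED and call.atypical


def make_call(state, cell="BEC", gene="G1"):
    return HistoneStateCall(gene, cell, state, False, False, 0.0)


def diff(mark, lfc, q=0.001):
    d = DifferentialEnrichment("G1", mark, lfc, q)
    d.q_value = q
    return d


class TestCompareStates:
    def test_all_16_state_pairs_follow_rank_order(self):
        for sa, sb in itertools.product(HistoneState, repeat=2):
            cmp = compare_states(make_call(sa), make_call(sb, "LEC"))
            if sa.rank > sb.rank:
                assert (cmp.verdict, cmp.basis) == ("gain", "state_switch")
            elif sa.rank < sb.rank:
                assert (cmp.verdict, cmp.basis) == ("loss", "state_switch")
            else:
                assert cmp.verdict == "unchanged"

    def test_antisymmetry_under_swap(self):
        flip = {"gain": "loss", "loss": "gain", "unchanged": "unchanged"}
        for sa, sb in itertools.product(HistoneState, repeat=2):
            fwd = compare_states(make_call(sa), make_call(sb, "LEC"))
            rev = compare_states(make_call(sb), make_call(sa, "LEC"))
            assert rev.verdict == flip[fwd.verdict]

    def test_same_state_with_stronger_k4_is_gain(self):
        cmp = compare_states(
            make_call(HistoneState.ACTIVE),
            make_call(HistoneState.ACTIVE, "LEC"),
            k4_diff=diff("H3K4me3", +1.5),
        )
        assert (cmp.verdict, cmp.basis) == ("gain", "same_state_signal")

    def test_same_state_with_weaker_k27_is_gain(self):
        cmp = compare_states(
            make_call(HistoneState.BIVALENT),
            make_call(HistoneState.BIVALENT, "LEC"),
            k27_diff=diff("H3K27me3", -2.0),
        )
        assert cmp.verdict == "gain"

    def test_conflicting_signals_stay_unchanged(self):
        cmp = compare_states(
            make_call(HistoneState.ACTIVE),
            make_call(HistoneState.ACTIVE, "LEC"),
            k4_diff=diff("H3K4me3", +1.5),
            k27_diff=diff("H3K27me3", +2.0),
        )
        assert cmp.verdict == "unchanged"

    def test_no_signal_stays_unchanged(self):
        cmp = compare_states(make_call(HistoneState.UNMARKED), make_call(HistoneState.UNMARKED, "LEC"))
        assert (cmp.verdict, cmp.basis) == ("unchanged", "none")

    def test_gene_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_states(make_call(HistoneState.ACTIVE), make_call(HistoneState.ACTIVE, gene="G2"))


class TestDifferentialEnrichment:
    def test_identical_groups_give_zero_lfc(self):
        lfc, p = differential_enrichment([200, 200], [200, 200], [1e6, 1e6], [1e6, 1e6])
        assert lfc == 0.0
        assert p == pytest.approx(1.0)

    def test_fourfold_rate_gives_lfc_near_two(self):
        # 400 vs 100 per million with pseudocount 0.5: log2(400.5/100.5)
        lfc, _ = differential_enrichment([400], [100], [1e6], [1e6])
        assert lfc == pytest.approx(np.log2(400.5 / 100.5))
        assert lfc == pytest.approx(2.0, abs=0.01)

    def test_single_window_bh_identity(self):
        (res,) = differential_enrichment_run(
            [("G1", "H3K4me3", [400], [100], [1e6], [1e6])]
        )
        assert res.q_value == pytest.approx(res.p_value)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            differential_enrichment([1], [1], [0], [1e6])


class TestStateExpressionSummary:
    def test_counts_and_medians(self):
        calls = [make_call(HistoneState.ACTIVE, gene=f"G{i}") for i in range(3)]
        out = state_expression_summary(calls, {"G0": 1.0, "G1": 2.0, "G2": 3.0})
        assert out["active"] == {"n": 3, "median_tpm": 2.0}
        assert out["repressed"]["n"] == 0 and np.isnan(out["repressed"]["median_tpm"])

    def test_unexpressed_genes_excluded_by_default(self):
        calls = [make_call(HistoneState.ACTIVE, gene="G0"), make_call(HistoneState.ACTIVE, gene="G1")]
        out = state_expression_summary(calls, {"G0": 0.0, "G1": 4.0})
        assert out["active"]["n"] == 1
        out_all = state_expression_summary(calls, {"G0": 0.0, "G1": 4.0}, expressed_only=False)
        assert out_all["active"]["n"] == 2

    def test_medians_increase_with_planted_activity(self):
        calls, tpm = [], {}
        for i, state in enumerate(HistoneState):
            for j in range(5):
                gid = f"G{i}_{j}"
                calls.append(make_call(state, gene=gid))
                tpm[gid] = 10.0 ** state.rank + j
        out = state_expression_summary(calls, tpm)
        medians = [out[s.label]["median_tpm"] for s in HistoneState]
        assert medians == sorted(medians)
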