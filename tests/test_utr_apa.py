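import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locaset.io_core import ConservationTrack, GeneModel, UTRForm
from locaset.utr_apa import (
    APAConfig,
    UTRUsageProfile,
    assign_utr_forms,
    call_apa,
    extract_gene_architecture,
    mean_weighted_length,
    most_used_form,
    utr_conservation,
)


def _gene(forms, strand="+", span=(0, 5000), exons=None):
    return GeneModel(
        gene_id="g", chrom="chr1", strand=strand, gene_span=span,
        exons=exons or (span,), utr3_forms=tuple(forms),
    )


def _profile(weights, lengths, gene_id="g", stage="early"):
    return UTRUsageProfile(gene_id, stage, dict(weights), dict(lengths))


class TestAssignment:
    def test_read_within_window_is_assigned(self):
        gene = _gene([UTRForm("A", (1000, 1500), "+")])
        prof = assign_utr_forms([1650], gene)  # 150 nt from the end at 1500
        assert prof.weights["A"] == 1
        assert prof.unassigned_reads == 0

    def test_read_outside_window_unassigned(self):
        gene = _gene([UTRForm("A", (1000, 1500), "+")])
        prof = assign_utr_forms([1750], gene)  # 250 nt away
        assert prof.weights["A"] == 0
        assert prof.unassigned_reads == 1

    def test_equidistant_tie_goes_to_shorter_form(self):
        # ends at 1300 and 1500; a read at 1400 is 100 nt from both
        gene = _gene([
            UTRForm("long", (1000, 1500), "+"),
            UTRForm("short", (1000, 1300), "+"),
        ])
        prof = assign_utr_forms([1400], gene)
        assert prof.weights["short"] == 1
        assert prof.weights["long"] == 0

    def test_nearest_end_wins_when_not_tied(self):
        gene = _gene([
            UTRForm("long", (1000, 1500), "+"),
            UTRForm("short", (1000, 1300), "+"),
        ])
        prof = assign_utr_forms([1480], gene)
        assert prof.weights["long"] == 1

    def test_gene_without_forms_all_unassigned(self):
        gene = _gene([])
        prof = assign_utr_forms([100, 200], gene)
        assert prof.unassigned_reads == 2
        assert prof.weights == {}

    def test_minus_strand_distance_uses_low_end(self):
        gene = _gene([UTRForm("A", (1000, 1500), "-")], strand="-")
        prof = assign_utr_forms([900], gene)  # 100 nt from the 3' end at 1000
        assert prof.weights["A"] == 1


class TestMostUsedForm:
    def test_argmax(self):
        gene = _gene([UTRForm("A", (0, 300), "+"), UTRForm("B", (0, 200), "+")])
        prof = _profile({"A": 10, "B": 3}, {"A": 300, "B": 200})
        assert most_used_form(prof, gene).form_id == "A"

    def test_weight_tie_prefers_shorter(self):
        gene = _gene([UTRForm("A", (0, 300), "+"), UTRForm("B", (0, 200), "+")])
        prof = _profile({"A": 5, "B": 5}, {"A": 300, "B": 200})
        assert most_used_form(prof, gene).form_id == "B"

    def test_single_form_identity(self):
        gene = _gene([UTRForm("A", (0, 350), "+")])
        prof = _profile({"A": 2}, {"A": 350})
        assert most_used_form(prof, gene).form_id == "A"

    def test_all_zero_weights_rejected(self):
        gene = _gene([UTRForm("A", (0, 300), "+")])
        with pytest.raises(ValueError):
            most_used_form(_profile({"A": 0}, {"A": 300}), gene)

    def test_adding_reads_to_winner_never_changes_it(self):
        gene = _gene([UTRForm("A", (0, 300), "+"), UTRForm("B", (0, 200), "+")])
        prof = _profile({"A": 10, "B": 3}, {"A": 300, "B": 200})
        for extra in (1, 5, 100):
            boosted = _profile({"A": 10 + extra, "B": 3}, {"A": 300, "B": 200})
            assert most_used_form(boosted, gene).form_id == "A"


class TestMeanWeightedLength:
    def test_hand_computed_weighted_mean(self):
        # (3*100 + 1*500) / 4 = 200
        prof = _profile({"A": 3, "B": 1}, {"A": 100, "B": 500})
        assert mean_weighted_length(prof) == pytest.approx(200.0)

    def test_single_form_identity(self):
        assert mean_weighted_length(_profile({"A": 7}, {"A": 350})) == 350.0

    def test_equal_weights_arithmetic_mean(self):
        prof = _profile({"A": 2, "B": 2}, {"A": 100, "B": 300})
        assert mean_weighted_length(prof) == pytest.approx(200.0)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            mean_weighted_length(_profile({"A": 0}, {"A": 100}))

    @given(scale=st.floats(min_value=0.01, max_value=1e4),
           w1=st.integers(1, 1000), w2=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_weight_rescaling(self, scale, w1, w2):
        base = _profile({"A": w1, "B": w2}, {"A": 120, "B": 480})
        scaled = _profile({"A": w1 * scale, "B": w2 * scale}, {"A": 120, "B": 480})
        assert mean_weighted_length(scaled) == pytest.approx(mean_weighted_length(base))

    @given(w1=st.integers(1, 500), w2=st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_form_lengths(self, w1, w2):
        prof = _profile({"A": w1, "B": w2}, {"A": 150, "B": 900})
        assert 150 <= mean_weighted_length(prof) <= 900


class TestAPACall:
    def test_delta_at_threshold_is_apa(self):
        a = _profile({"A": 1}, {"A": 400})
        b = _profile({"B": 1}, {"B": 600})
        call = call_apa(a, b)
        assert call.decision == "APA"
        assert call.delta == pytest.approx(200.0)

    def test_delta_below_threshold_no_call(self):
        a = _profile({"A": 1}, {"A": 400})
        b = _profile({"B": 1}, {"B": 599})
        assert call_apa(a, b).decision == "no_call"

    def test_identical_profiles_delta_zero(self):
        a = _profile({"A": 2, "B": 2}, {"A": 100, "B": 300})
        call = call_apa(a, a)
        assert call.decision == "no_call"
        assert call.delta == 0.0

    def test_symmetric_decision_with_negated_delta(self):
        a = _profile({"A": 1}, {"A": 400})
        b = _profile({"B": 1}, {"B": 700})
        ab, ba = call_apa(a, b), call_apa(b, a)
        assert ab.decision == ba.decision == "APA"
        assert ab.delta == pytest.approx(-ba.delta)

    def test_zero_read_stage_gives_no_call_with_reason(self):
        a = _profile({"A": 0}, {"A": 400})
        b = _profile({"B": 1}, {"B": 700})
        call = call_apa(a, b)
        assert call.decision == "no_call"
        assert "stage A" in call.reason


class TestConservationAndArchitecture:
    def test_constant_track_median(self):
        track = ConservationTrack({
            "chr1": (np.array([0]), np.array([100]), np.array([1.5]))})
        form = UTRForm("u", (10, 60), "+")
        res = utr_conservation(form, "chr1", track)
        assert res.median == 1.5
        assert not res.low_coverage

    def test_per_base_median_by_hand(self):
        starts = np.arange(5)
        track = ConservationTrack({
            "chr1": (starts, starts + 1, np.array([0.0, 1.0, 2.0, 3.0, 4.0]))})
        res = utr_conservation(UTRForm("u", (0, 5), "+"), "chr1", track)
        assert res.median == 2.0

    def test_low_coverage_flagged(self):
        # only 4 of 10 bases covered -> 60% missing
        starts = np.arange(4)
        track = ConservationTrack({
            "chr1": (starts, starts + 1, np.ones(4))})
        res = utr_conservation(UTRForm("u", (0, 10), "+"), "chr1", track)
        assert res.low_coverage
        assert res.missing_fraction == pytest.approx(0.6)

    def test_uncovered_form_rejected(self):
        track = ConservationTrack({"chr1": (np.array([0]), np.array([5]), np.array([1.0]))})
        with pytest.raises(ValueError):
            utr_conservation(UTRForm("u", (100, 200), "+"), "chr1", track)

    def test_single_exon_architecture(self):
        gene = _gene([], span=(0, 1000), exons=((0, 1000),))
        feats = extract_gene_architecture(gene)
        assert feats["exon_proportion"] == 1.0
        assert feats["intron_count"] == 0
        assert feats["utr5_length"] == 0.0

    def test_intron_proportion_by_hand(self):
        # exons of 100 + 150 in a 350 bp gene -> intron 100/350
        gene = GeneModel("g", "c", "+", (0, 350),
                         exons=((0, 100), (200, 350)))
        feats = extract_gene_architecture(gene)
        assert feats["intron_proportion"] == pytest.approx(100 / 350)
        assert feats["exon_proportion"] == pytest.approx(250 / 350)
        assert feats["intron_count"] == 1
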