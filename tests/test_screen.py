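import itertools
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmrscreen.screen import (
    AllelePCR,
    CallOutcome,
    ClassificationError,
    ColonyCategory,
    ColonyObservation,
    ColonyPanel,
    EvaluationError,
    InsightClass,
    MergedCounts,
    PriorLabel,
    ProteinQuant,
    Round,
    ScreenCall,
    ScreenError,
    SequenceCall,
    VariantRecord,
    aggregate_rounds,
    call_variant,
    classify_colony,
    colony_fractions,
    relative_protein_level,
    screen_performance,
    zero_failure_bound,
)
from tests.conftest import make_panel


class TestClassifyColony:
    @pytest.mark.parametrize(
        "allele_pcr, sequence_call, expected",
        [
            (AllelePCR.WT_ALLELE_LOST, SequenceCall.NOT_TESTED, ColonyCategory.LOH),
            (
                AllelePCR.BOTH_ALLELES_PRESENT,
                SequenceCall.PLANNED_MUTATION,
                ColonyCategory.CONFIRMED_MUTANT,
            ),
            (
                AllelePCR.BOTH_ALLELES_PRESENT,
                SequenceCall.NO_MUTATION,
                ColonyCategory.BACKGROUND,
            ),
        ],
    )
    def test_categories(self, allele_pcr, sequence_call, expected):
        obs = ColonyObservation("c1", allele_pcr, sequence_call)
        assert classify_colony(obs) == expected

    def test_retained_colony_without_sequencing_is_an_error(self):
        obs = ColonyObservation(
            "c1", AllelePCR.BOTH_ALLELES_PRESENT, SequenceCall.NOT_TESTED
        )
        with pytest.raises(ClassificationError, match="no sequencing call"):
            classify_colony(obs)

    def test_loh_colony_with_sequencing_violates_invariant(self):
        with pytest.raises(ScreenError, match="not sequenced"):
            ColonyObservation(
                "c1", AllelePCR.WT_ALLELE_LOST, SequenceCall.PLANNED_MUTATION
            )


class TestColonyFractions:
    def test_seventeen_loh_one_background(self):
        fr = colony_fractions(make_panel("v", 17, 1, 0))
        assert fr.f_loh == Fraction(17, 18)
        assert fr.f_background == Fraction(1, 18)
        assert fr.f_confirmed == 0
        # the printed rounding of the derived example
        assert round(float(fr.f_loh), 3) == 0.944
        assert round(float(fr.f_background), 3) == 0.056

    def test_all_confirmed(self):
        fr = colony_fractions(make_panel("v", 0, 0, 18))
        assert (fr.f_loh, fr.f_background, fr.f_confirmed) == (0, 0, 1)

    def test_polymorphism_panel_has_zero_confirmed(self):
        # ~6% non-LOH background, nothing confirmed
        fr = colony_fractions(make_panel("v", 17, 1, 0))
        assert fr.f_confirmed == 0

    def test_empty_panel_is_error(self):
        with pytest.raises(ScreenError, match="empty"):
            colony_fractions(ColonyPanel("v", Round.ANTISENSE, ()))

    @given(
        n_loh=st.integers(0, 30),
        n_bg=st.integers(0, 30),
        n_conf=st.integers(0, 30),
    )
    def test_fractions_sum_to_one_exactly(self, n_loh, n_bg, n_conf):
        if n_loh + n_bg + n_conf == 0:
            return
        fr = colony_fractions(make_panel("v", n_loh, n_bg, n_conf))
        assert fr.f_loh + fr.f_background + fr.f_confirmed == 1


class TestAggregateRounds:
    def test_antisense_plus_sense_sum(self):
        merged = aggregate_rounds(
            [
                make_panel("v", 18, 0, 0, Round.ANTISENSE),
                make_panel("v", 12, 1, 5, Round.SENSE),
            ]
        )
        assert merged.n_confirmed == 5
        assert merged.n_loh == 30
        assert merged.n_background == 1
        assert merged.rounds_used == (Round.ANTISENSE, Round.SENSE)
        assert merged.n_total == 36

    def test_single_round_is_passthrough(self):
        merged = aggregate_rounds([make_panel("v", 11, 0, 7)])
        assert (merged.n_loh, merged.n_background, merged.n_confirmed) == (11, 0, 7)
        assert merged.rounds_used == (Round.ANTISENSE,)

    def test_one_confirmed_per_round_reaches_two(self):
        merged = aggregate_rounds(
            [
                make_panel("v", 17, 0, 1, Round.ANTISENSE),
                make_panel("v", 17, 0, 1, Round.SENSE),
            ]
        )
        assert merged.n_confirmed == 2

    def test_mixed_variant_ids_rejected(self):
        with pytest.raises(ScreenError, match="mix variant ids"):
            aggregate_rounds([make_panel("a", 1, 0, 0), make_panel("b", 1, 0, 0)])

    def test_duplicate_round_rejected(self):
        with pytest.raises(ScreenError, match="duplicate round"):
            aggregate_rounds([make_panel("v", 1, 0, 0), make_panel("v", 2, 0, 0)])

    def test_sense_without_antisense_rejected(self):
        with pytest.raises(ScreenError, match="sense panel without"):
            aggregate_rounds([make_panel("v", 1, 0, 0, Round.SENSE)])


class TestCallVariant:
    @pytest.mark.parametrize(
        "n_confirmed, expected",
        [
            (0, CallOutcome.NOT_DETECTED),
            (1, CallOutcome.INCONCLUSIVE),
            (2, CallOutcome.MMR_ABROGATING),
            (7, CallOutcome.MMR_ABROGATING),
        ],
    )
    def test_two_colony_rule(self, n_confirmed, expected):
        merged = MergedCounts("v", n_confirmed, 10, 1, (Round.ANTISENSE,))
        assert call_variant(merged).call == expected

    def test_two_of_five_non_loh_is_abrogating(self):
        # the weakest positive panels seen in the study: 2 confirmed among
        # 5 (resp. 4) colonies retaining both alleles
        merged = aggregate_rounds([make_panel("v", 13, 3, 2)])
        assert call_variant(merged).call == CallOutcome.MMR_ABROGATING

    def test_polymorphism_panel_not_detected(self):
        merged = aggregate_rounds([make_panel("v", 17, 1, 0)])
        assert call_variant(merged).call == CallOutcome.NOT_DETECTED

    def test_negative_counts_rejected(self):
        with pytest.raises(ScreenError):
            MergedCounts("v", -1, 0, 0, (Round.ANTISENSE,))

    @given(
        n_conf=st.integers(2, 40),
        n_loh=st.integers(0, 40),
        n_bg=st.integers(0, 40),
        extra=st.integers(1, 10),
    )
    def test_monotone_in_confirmed_colonies(self, n_conf, n_loh, n_bg, extra):
        before = call_variant(MergedCounts("v", n_conf, n_loh, n_bg, (Round.ANTISENSE,)))
        after = call_variant(
            MergedCounts("v", n_conf + extra, n_loh, n_bg, (Round.ANTISENSE,))
        )
        assert before.call == CallOutcome.MMR_ABROGATING
        assert after.call == CallOutcome.MMR_ABROGATING


class TestRelativeProteinLevel:
    def test_identical_lanes_give_100(self):
        lane = ProteinQuant(12.0, 8.0, 40.0)
        assert relative_protein_level(lane, lane) == pytest.approx(100.0)

    def test_ratio_arithmetic(self):
        variant = ProteinQuant(10.0, 1.0, 100.0)
        control = ProteinQuant(50.0, 1.0, 100.0)
        assert relative_protein_level(variant, control) == pytest.approx(20.0)

    def test_loading_normalization_cancels_loading_difference(self):
        variant = ProteinQuant(30.0, 1.0, 50.0)
        control = ProteinQuant(60.0, 1.0, 100.0)
        assert relative_protein_level(variant, control) == pytest.approx(100.0)

    def test_msh2_channel(self):
        variant = ProteinQuant(0.0, 30.0, 50.0)
        control = ProteinQuant(0.0, 60.0, 100.0)
        assert relative_protein_level(variant, control, "msh2") == pytest.approx(100.0)

    def test_zero_loading_is_error(self):
        good = ProteinQuant(1.0, 1.0, 1.0)
        bad = ProteinQuant(1.0, 1.0, 0.0)
        with pytest.raises(ScreenError, match="loading"):
            relative_protein_level(bad, good)

    @given(
        msh6=st.floats(0.1, 1e3),
        loading=st.floats(0.1, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    def test_invariant_under_lane_rescaling(self, msh6, loading, scale):
        control = ProteinQuant(5.0, 5.0, 10.0)
        lane = ProteinQuant(msh6, 0.0, loading)
        scaled = ProteinQuant(msh6 * scale, 0.0, loading * scale)
        assert relative_protein_level(scaled, control) == pytest.approx(
            relative_protein_level(lane, control), rel=1e-9
        )


def _variant(vid: str, label: PriorLabel) -> VariantRecord:
    return VariantRecord(vid, ".", ".", ".", InsightClass.UNCERTAIN, label)


def _call(vid: str, outcome: CallOutcome) -> ScreenCall:
    n_conf = {
        CallOutcome.MMR_ABROGATING: 2,
        CallOutcome.INCONCLUSIVE: 1,
        CallOutcome.NOT_DETECTED: 0,
    }[outcome]
    return ScreenCall(vid, outcome, n_conf, 10, 0, (Round.ANTISENSE,))


def brute_force_confusion(calls, truth):
    """Independent confusion-matrix oracle: explicit set arithmetic."""
    detected = {c.variant_id for c in calls if c.call == CallOutcome.MMR_ABROGATING}
    pos = {v.variant_id for v in truth if v.prior_label == PriorLabel.PATHOGENIC}
    neg = {v.variant_id for v in truth if v.prior_label == PriorLabel.NON_PATHOGENIC}
    tp = len(pos & detected)
    fp = len(neg & detected)
    sens = 100 * tp / len(pos)
    spec = 100 * (len(neg) - fp) / len(neg)
    sens_bound = 100 * (len(pos) - 1) / len(pos) if tp == len(pos) else sens
    spec_bound = 100 * (len(neg) - 1) / len(neg) if fp == 0 else spec
    return tp, fp, sens, spec, sens_bound, spec_bound


class TestScreenPerformance:
    def test_seven_of_seven_detected(self):
        truth = [_variant(f"p{i}", PriorLabel.PATHOGENIC) for i in range(7)]
        truth.append(_variant("n0", PriorLabel.NON_PATHOGENIC))
        calls = [_call(f"p{i}", CallOutcome.MMR_ABROGATING) for i in range(7)]
        calls.append(_call("n0", CallOutcome.NOT_DETECTED))
        report = screen_performance(calls, truth)
        assert report.sensitivity_point == pytest.approx(100.0)
        assert report.sensitivity_zero_failure_bound == pytest.approx(85.7, abs=0.05)

    def test_ten_clean_negatives(self):
        truth = [_variant(f"n{i}", PriorLabel.NON_PATHOGENIC) for i in range(10)]
        truth.append(_variant("p0", PriorLabel.PATHOGENIC))
        calls = [_call(f"n{i}", CallOutcome.NOT_DETECTED) for i in range(10)]
        calls.append(_call("p0", CallOutcome.MMR_ABROGATING))
        report = screen_performance(calls, truth)
        assert report.specificity_point == pytest.approx(100.0)
        assert report.specificity_zero_failure_bound == pytest.approx(90.0)

    def test_single_positive_bound_is_zero(self):
        truth = [
            _variant("p0", PriorLabel.PATHOGENIC),
            _variant("n0", PriorLabel.NON_PATHOGENIC),
        ]
        calls = [
            _call("p0", CallOutcome.MMR_ABROGATING),
            _call("n0", CallOutcome.NOT_DETECTED),
        ]
        report = screen_performance(calls, truth)
        assert report.sensitivity_point == pytest.approx(100.0)
        assert report.sensitivity_zero_failure_bound == pytest.approx(0.0)

    def test_inconclusive_counts_as_not_detected(self):
        truth = [
            _variant("p0", PriorLabel.PATHOGENIC),
            _variant("p1", PriorLabel.PATHOGENIC),
            _variant("n0", PriorLabel.NON_PATHOGENIC),
        ]
        calls = [
            _call("p0", CallOutcome.MMR_ABROGATING),
            _call("p1", CallOutcome.INCONCLUSIVE),
            _call("n0", CallOutcome.INCONCLUSIVE),
        ]
        report = screen_performance(calls, truth)
        assert report.n_detected == 1
        assert report.n_false_positive == 0
        # failure present -> bound equals point estimate
        assert report.sensitivity_zero_failure_bound == report.sensitivity_point == 50.0
        # single clean negative: zero-failure bound (n-1)/n is 0 at n=1
        assert report.specificity_point == pytest.approx(100.0)
        assert report.specificity_zero_failure_bound == pytest.approx(0.0)

    def test_uncertain_rows_excluded(self):
        truth = [
            _variant("p0", PriorLabel.PATHOGENIC),
            _variant("n0", PriorLabel.NON_PATHOGENIC),
            _variant("u0", PriorLabel.UNCERTAIN),
        ]
        calls = [_call(v.variant_id, CallOutcome.MMR_ABROGATING) for v in truth]
        report = screen_performance(calls, truth)
        assert report.excluded_uncertain == ("u0",)
        assert report.n_pathogenic_truth == 1
        assert report.n_nonpathogenic_truth == 1

    def test_empty_partition_named_in_error(self):
        truth = [_variant("p0", PriorLabel.PATHOGENIC)]
        calls = [_call("p0", CallOutcome.MMR_ABROGATING)]
        with pytest.raises(EvaluationError, match="non_pathogenic"):
            screen_performance(calls, truth)

    def test_missing_call_is_error(self):
        truth = [
            _variant("p0", PriorLabel.PATHOGENIC),
            _variant("n0", PriorLabel.NON_PATHOGENIC),
        ]
        with pytest.raises(EvaluationError, match="p0"):
            screen_performance([_call("n0", CallOutcome.NOT_DETECTED)], truth)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_all_call_patterns_match_brute_force(self, n):
        # all 2^n detection patterns over n/2 positives + rest negatives
        labels = [PriorLabel.PATHOGENIC] * (n // 2 + 1) + [
            PriorLabel.NON_PATHOGENIC
        ] * (n - n // 2 - 1 + 1)
        truth = [_variant(f"v{i}", lab) for i, lab in enumerate(labels)]
        for pattern in itertools.product([True, False], repeat=len(truth)):
            calls = [
                _call(
                    f"v{i}",
                    CallOutcome.MMR_ABROGATING if hit else CallOutcome.NOT_DETECTED,
                )
                for i, hit in enumerate(pattern)
            ]
            report = screen_performance(calls, truth)
            tp, fp, sens, spec, sens_b, spec_b = brute_force_confusion(calls, truth)
            assert report.n_detected == tp
            assert report.n_false_positive == fp
            assert report.sensitivity_point == pytest.approx(sens)
            assert report.specificity_point == pytest.approx(spec)
            assert report.sensitivity_zero_failure_bound == pytest.approx(sens_b)
            assert report.specificity_zero_failure_bound == pytest.approx(spec_b)

    @given(n=st.integers(1, 50))
    def test_zero_failure_bound_formula(self, n):
        assert zero_failure_bound(n) == pytest.approx(100.0 * (n - 1) / n)
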