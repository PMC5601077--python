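"""TdP score, binary classifiers and confusion metrics."""

import math
import warnings

import numpy as np
import pytest

from aptrial.drug import CompoundRecord
from aptrial.risk import (
    ClassificationOutcome, TdPScoreInput, classify_apd, classify_ra,
    confusion_metrics, log10_score, qt_equivalent_pct, tdp_score,
)
from aptrial.trial import TrialResult


def make_trial(nra, apd, n_mod=100, multiples=(1.0, 10.0, 30.0, 100.0),
               category="1"):
    compound = CompoundRecord("X", "I", (), 1.0, category)
    return TrialResult(
        compound=compound, multiples=multiples,
        doses_um={m: m for m in multiples}, n_mod=n_mod,
        nRA=dict(zip(multiples, nra)), nDA={m: 0 for m in multiples},
        n_failed={m: 0 for m in multiples},
        apd90_pct_change=dict(zip(multiples, apd)),
    )


class TestTdPScore:
    def test_no_ra_scores_zero(self):
        score = tdp_score(TdPScoreInput((1, 10, 30, 100), (0, 0, 0, 0), 100))
        assert score == 0.0

    def test_full_ra_everywhere_scores_one(self):
        score = tdp_score(TdPScoreInput((1, 10, 30, 100),
                                        (100, 100, 100, 100), 100))
        assert score == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # nRA = {0, 0, 10, 100} over {1,10,30,100}x with 100 models:
        # (10/30 + 100/100) / (100 * (1 + 1/10 + 1/30 + 1/100)) = 0.011662
        score = tdp_score(TdPScoreInput((1, 10, 30, 100), (0, 0, 10, 100), 100))
        assert score == pytest.approx(0.011662, abs=5e-6)

    def test_absolute_concentrations_match_multiples(self):
        eftpc = 0.25
        as_mult = tdp_score(TdPScoreInput((1, 10, 30, 100), (0, 5, 10, 50), 100))
        as_abs = tdp_score(TdPScoreInput(
            tuple(m * eftpc for m in (1, 10, 30, 100)), (0, 5, 10, 50), 100,
            eftpc_max_um=eftpc, as_multiples=False))
        assert as_abs == pytest.approx(as_mult)

    def test_monotone_in_each_count(self):
        base = tdp_score(TdPScoreInput((1, 10, 30, 100), (0, 1, 5, 20), 100))
        for i in range(4):
            nra = [0, 1, 5, 20]
            nra[i] += 1
            bumped = tdp_score(TdPScoreInput((1, 10, 30, 100), tuple(nra), 100))
            assert bumped > base

    def test_ra_free_high_concentration_dilutes_score(self):
        without = tdp_score(TdPScoreInput((1, 10, 30), (0, 0, 30), 100))
        with_extra = tdp_score(TdPScoreInput((1, 10, 30, 100), (0, 0, 30, 0), 100))
        assert 0 < with_extra < without

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            TdPScoreInput((1, 10), (5, 200), 100)
        with pytest.raises(ValueError):
            TdPScoreInput((1, 10), (0, 0), 0)

    def test_from_trial(self):
        trial = make_trial((0, 0, 10, 100), (0, 0, 0, 0))
        assert tdp_score(TdPScoreInput.from_trial(trial)) \
            == pytest.approx(0.011662, abs=5e-6)


class TestClassifyRA:
    def test_no_ra_is_safe(self):
        assert not classify_ra(make_trial((0, 0, 0, 0), (0,) * 4))

    def test_single_ra_at_top_dose_is_risky(self):
        # one model with RA only at 100x flips the call (the mechanism that
        # makes class Ib sodium blockers false positives at high dose)
        assert classify_ra(make_trial((0, 0, 0, 1), (0,) * 4))

    def test_lower_concentration_cap_restores_safe(self):
        trial = make_trial((0, 0, 0, 1), (0,) * 4)
        assert not classify_ra(trial, max_multiple=30)

    def test_monotone_in_max_multiple(self):
        trial = make_trial((0, 0, 2, 5), (0,) * 4)
        calls = [classify_ra(trial, max_multiple=m) for m in (1, 10, 30, 100)]
        # once risky, raising the cap never flips back to safe
        assert calls == sorted(calls)

    def test_min_fraction_threshold(self):
        trial = make_trial((0, 0, 0, 5), (0,) * 4, n_mod=100)
        assert classify_ra(trial, min_fraction=0.05)
        assert not classify_ra(trial, min_fraction=0.10)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            classify_ra(make_trial((0, 0, 0, 0), (0,) * 4), max_multiple=0.5)


class TestClassifyAPD:
    def test_six_percent_threshold_straddle(self):
        assert not classify_apd(make_trial((0,) * 4, (0, 5.9, 0, 0)))
        assert classify_apd(make_trial((0,) * 4, (0, 6.1, 0, 0)))

    def test_biphasic_low_dose_shortening_still_risky(self):
        # shortening at 1x but clearing the threshold at 10x: risky (the
        # calcium-blocker false-positive mechanism of APD-based calls)
        assert classify_apd(make_trial((0,) * 4, (-4.0, 8.0, 20.0, 40.0)))

    def test_zero_change_is_safe(self):
        assert not classify_apd(make_trial((0,) * 4, (0.0, 0.0, 0.0, 0.0)))

    def test_missing_ten_fold_concentration_rejected(self):
        trial = make_trial((0, 0), (0.0, 0.0), multiples=(1.0, 30.0))
        with pytest.raises(ValueError, match="10"):
            classify_apd(trial)


class TestConfusionMetrics:
    def test_perfect_sensitivity(self):
        predictions = {f"d{i}": True for i in range(24)}
        truth = {f"d{i}": 1 for i in range(24)}
        outcome = confusion_metrics(predictions, truth, {1})
        assert outcome.tp == 24 and outcome.fn == 0
        assert outcome.sensitivity == 1.0

    def test_balanced_two_by_two(self):
        predictions = {"a": True, "b": True, "c": False, "d": False}
        truth = {"a": 1, "b": 0, "c": 1, "d": 0}
        outcome = confusion_metrics(predictions, truth, {1})
        assert (outcome.tp, outcome.fp, outcome.fn, outcome.tn) == (1, 1, 1, 1)
        assert outcome.sensitivity == 0.5
        assert outcome.specificity == 0.5
        assert outcome.accuracy == 0.5

    def test_empty_positive_class_warns_nan(self):
        outcome = confusion_metrics({"a": False}, {"a": 0}, {1})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert math.isnan(outcome.sensitivity)
        assert any("sensitivity" in str(w.message) for w in caught)

    def test_cohort_selection_changes_truth(self):
        predictions = {"a": True}
        truth = {"a": 3}
        assert confusion_metrics(predictions, truth, {1}).fp == 1
        assert confusion_metrics(predictions, truth, {1, 2, 3}).tp == 1

    def test_mismatched_drug_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            confusion_metrics({"a": True}, {"b": 1}, {1})


class TestScaleHelpers:
    def test_qt_guideline_equivalent(self):
        # 20 ms on a 350 ms QT interval is a 5.7 % prolongation
        assert qt_equivalent_pct() == pytest.approx(5.7, abs=0.05)

    def test_log_score_clamps_zero(self):
        assert log10_score(0.0) == -16.0
        assert log10_score(0.1) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            log10_score(1.5)
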