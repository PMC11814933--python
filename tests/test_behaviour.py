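"""Scoring of the three diagnostic tests and the chronicity targets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neglectprog.behaviour import (
    CancellationResult,
    ControlNorms,
    CopyingResult,
    DegenerateNormsError,
    PatientRecord,
    TestBattery,
    UndefinedRecoveryError,
    apply_control_chronic_policy,
    classify_patient,
    composite_z,
    compute_coc,
    copying_percent_correct,
    fit_control_norms,
    is_pathological,
    score_copying,
    target_effectiveness,
    target_z_difference,
)


def sheet(positions, marked, test="letter"):
    return CancellationResult(target_x=tuple(positions), marked=tuple(marked), test_name=test)


class TestCentreOfCancellation:
    def test_symmetric_sheet_fully_marked_is_zero(self):
        xs = [-1, -0.5, 0.5, 1]
        assert compute_coc(sheet(xs, [True] * 4)) == 0.0

    def test_mean_of_marked_positions(self):
        s = sheet([-1, -0.5, 0.5, 1], [False, False, True, True])
        assert compute_coc(s) == pytest.approx(0.75)

    def test_zero_marked_returns_layout_maximum(self):
        s = sheet([-1, -0.25, 0.25, 0.9], [False] * 4)
        assert compute_coc(s) == pytest.approx(0.9)

    def test_mirroring_negates_coc(self):
        xs = [-1.0, -0.4, 0.1, 0.7]
        marked = [False, True, True, False]
        coc = compute_coc(sheet(xs, marked))
        mirrored = compute_coc(sheet([-x for x in xs], marked))
        assert mirrored == pytest.approx(-coc)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=30),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_coc_bounded_by_layout(self, xs, data):
        marked = data.draw(st.lists(st.booleans(), min_size=len(xs), max_size=len(xs)))
        coc = compute_coc(sheet(xs, marked))
        assert min(xs) - 1e-12 <= coc <= max(xs) + 1e-12

    def test_rejects_mismatched_lengths_and_empty(self):
        with pytest.raises(ValueError):
            sheet([0.1, 0.2], [True])
        with pytest.raises(ValueError):
            sheet([], [])


class TestCopying:
    def test_perfect_copy_scores_zero(self):
        r = CopyingResult(per_figure=("complete",) * 4)
        assert score_copying(r) == 0

    def test_whole_plus_feature_omission(self):
        r = CopyingResult(
            per_figure=("wholly_omitted", "contralateral_feature_omitted", "complete", "complete")
        )
        assert score_copying(r) == 3

    def test_maximum_capped_at_eight(self):
        r = CopyingResult(per_figure=("wholly_omitted",) * 4, misplaced_contralesional=True)
        assert score_copying(r) == 8

    def test_percent_correct_reporting(self):
        assert copying_percent_correct(0) == 100.0
        assert copying_percent_correct(8) == 0.0

    def test_requires_four_figures(self):
        with pytest.raises(ValueError):
            CopyingResult(per_figure=("complete",) * 3)


class TestCutoffs:
    @pytest.mark.parametrize(
        "test,score,expected",
        [
            ("letter", 0.081, False),
            ("letter", 0.082, True),
            ("bells", 0.083, False),
            ("bells", 0.084, True),
            ("copying", 1, False),
            ("copying", 2, True),
            ("letter", 0, False),
        ],
    )
    def test_pathological_cutoffs(self, test, score, expected):
        assert is_pathological(test, score) is expected

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            is_pathological("stars", 0.5)


def battery_from_scores(letter=None, bells=None, copying=None, phase="acute"):
    """Build a battery whose raw scores equal the given values."""
    kwargs = {}
    if letter is not None:
        kwargs["letter"] = sheet([letter, letter], [True, True], "letter")
    if bells is not None:
        kwargs["bells"] = sheet([bells, bells], [True, True], "bells")
    if copying is not None:
        states = []
        pts = copying
        for _ in range(4):
            take = min(pts, 2)
            states.append({0: "complete", 1: "contralateral_feature_omitted",
                           2: "wholly_omitted"}[take])
            pts -= take
        kwargs["copying"] = CopyingResult(per_figure=tuple(states))
    return TestBattery(phase=phase, **kwargs)


class TestClassification:
    def test_all_normal_complete_battery_is_control(self):
        b = battery_from_scores(letter=0.02, bells=0.03, copying=0)
        assert classify_patient(b) == "control"

    def test_single_pathological_test_is_neglect(self):
        b = battery_from_scores(letter=0.59)
        assert classify_patient(b) == "neglect"

    def test_incomplete_normal_battery_is_unclassifiable(self):
        b = battery_from_scores(letter=0.02, bells=0.03)  # copying missing
        assert classify_patient(b) == "unclassifiable"

    def test_empty_battery_rejected(self):
        with pytest.raises(ValueError):
            classify_patient(TestBattery())


class TestControlNorms:
    def test_hand_computed_mean_and_sample_sd(self):
        batteries = [battery_from_scores(letter=0.0, bells=0.0, copying=0),
                     battery_from_scores(letter=0.02, bells=0.01, copying=1)]
        norms = fit_control_norms(batteries)
        assert norms.mean["letter"] == pytest.approx(0.01)
        assert norms.sd["letter"] == pytest.approx(0.0141, abs=1e-4)

    def test_controls_standardize_to_mean_zero_sd_one(self, rng):
        vals = rng.normal(0.01, 0.02, size=12)
        batteries = [battery_from_scores(letter=v, bells=v, copying=i % 3)
                     for i, v in enumerate(vals)]
        norms = fit_control_norms(batteries)
        z = [(v - norms.mean["letter"]) / norms.sd["letter"] for v in vals]
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)

    def test_single_control_rejected(self):
        with pytest.raises(DegenerateNormsError):
            fit_control_norms([battery_from_scores(letter=0.0, bells=0.0, copying=0)])

    def test_zero_variance_rejected(self):
        same = [battery_from_scores(letter=0.01, bells=0.01, copying=0)] * 3
        with pytest.raises(DegenerateNormsError):
            fit_control_norms(same)


class TestCompositeZ:
    NORMS = ControlNorms(mean={"letter": 0.01, "bells": 0.01, "copying": 0.2},
                         sd={"letter": 0.02, "bells": 0.02, "copying": 0.5})

    def test_mean_of_per_test_z(self):
        # per-test z-scores (1, 2, 3) -> composite 2
        norms = ControlNorms(mean={"letter": 0, "bells": 0, "copying": 0},
                             sd={"letter": 1, "bells": 0.25, "copying": 1})
        b = battery_from_scores(letter=1.0, bells=0.5, copying=3)
        assert composite_z(b, norms) == pytest.approx(2.0)

    def test_chronic_group_scale_letter_z(self):
        # letter CoC 0.59 against control norms mean 0.01 SD 0.02 -> z = 29
        assert self.NORMS.z("letter", 0.59) == pytest.approx(29.0)

    def test_missing_test_averages_available(self):
        b = battery_from_scores(letter=0.05, bells=0.03)
        expected = np.mean([self.NORMS.z("letter", 0.05), self.NORMS.z("bells", 0.03)])
        assert composite_z(b, self.NORMS) == pytest.approx(expected)
        assert not b.is_complete


class TestTargets:
    def test_z_difference_is_acute_minus_chronic(self):
        assert target_z_difference(10, 4) == 6
        assert target_z_difference(3.3, 3.3) == 0

    def test_full_resolution_gives_hundred_percent(self):
        acute = {"letter": 0.4, "bells": 0.5, "copying": 4}
        chronic = {"letter": 0.0, "bells": 0.0, "copying": 0}
        assert target_effectiveness(acute, chronic) == pytest.approx(100.0)

    def test_no_improvement_gives_zero_percent(self):
        acute = {"letter": 0.4, "bells": 0.5, "copying": 4}
        assert target_effectiveness(acute, dict(acute)) == pytest.approx(0.0)

    def test_single_test_formula_arithmetic(self):
        assert target_effectiveness({"letter": 0.4}, {"letter": 0.1}) == pytest.approx(75.0)

    def test_worsening_clipped_to_zero(self):
        assert target_effectiveness({"letter": 0.4}, {"letter": 0.9}) == 0.0

    def test_scale_invariance_with_zero_floor(self):
        a, c = {"letter": 0.4}, {"letter": 0.1}
        scaled = target_effectiveness({"letter": 4.0}, {"letter": 1.0})
        assert target_effectiveness(a, c) == pytest.approx(scaled)

    def test_all_tests_at_floor_rejected(self):
        with pytest.raises(UndefinedRecoveryError):
            target_effectiveness({"letter": 0.0}, {"letter": 0.0})


class TestControlChronicPolicy:
    def _patients(self):
        control = PatientRecord("c1", "control", 60, "F",
                                battery_from_scores(letter=0.02, bells=0.01, copying=0))
        neglect = PatientRecord("n1", "recovered", 70, "M",
                                battery_from_scores(letter=0.5, bells=0.5, copying=4))
        return [control, neglect]

    NORMS = TestCompositeZ.NORMS

    def test_zero_and_full(self):
        out = apply_control_chronic_policy(self._patients(), "zero_and_full", norms=self.NORMS)
        ctrl = out[0]
        assert ctrl.targets.chronic_z == 0.0
        assert ctrl.targets.effectiveness == 100.0
        # z difference equals the control's own acute composite
        assert ctrl.targets.z_difference == pytest.approx(composite_z(ctrl.acute, self.NORMS))

    def test_carry_forward_acute(self):
        out = apply_control_chronic_policy(self._patients(), "carry_forward_acute",
                                           norms=self.NORMS)
        ctrl = out[0]
        assert ctrl.targets.chronic_z == pytest.approx(composite_z(ctrl.acute, self.NORMS))
        assert ctrl.targets.z_difference == pytest.approx(0.0)

    def test_recovery_zero(self):
        out = apply_control_chronic_policy(self._patients(), "recovery_zero", norms=self.NORMS)
        assert out[0].targets.effectiveness == 0.0

    def test_neglect_patients_untouched(self):
        out = apply_control_chronic_policy(self._patients(), "zero_and_full", norms=self.NORMS)
        assert out[1].targets is None

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            apply_control_chronic_policy(self._patients(), "oracle")
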