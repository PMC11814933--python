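"""Behavioural scoring for spatial neglect.

Three paper-and-pencil tests quantify neglect severity: a letter
cancellation task, a bells cancellation test, and a figure-copying task.
Cancellation performance is summarised by the centre of cancellation
(CoC): the mean horizontal position of the targets the patient marked,
normalized so that 0 is the sheet centre and +1 the right (ipsilesional)
edge.  A positive CoC means the patient marked mostly right-sided
targets, i.e. neglected the left.  Copying is scored 0-8 (higher =
worse).  A patient counts as having neglect if at least one available
test is pathological; as a control only if all three tests are available
and non-pathological.

Severity is standardized per test against the acute scores of the
control patients, and the three z-scores are averaged into a composite.
Three chronicity targets are derived from the acute and chronic
composites: the chronic composite z itself, the acute-minus-chronic
difference, and the effectiveness of recovery (percentage of the
potential improvement actually achieved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "LETTER_COC_CUTOFF",
    "BELLS_COC_CUTOFF",
    "COPYING_CUTOFF",
    "COPYING_MAX_SCORE",
    "CancellationResult",
    "CopyingResult",
    "TestBattery",
    "ControlNorms",
    "TargetScores",
    "PatientRecord",
    "DegenerateNormsError",
    "UndefinedRecoveryError",
    "compute_coc",
    "score_copying",
    "copying_percent_correct",
    "is_pathological",
    "classify_patient",
    "fit_control_norms",
    "composite_z",
    "target_z_difference",
    "target_effectiveness",
    "apply_control_chronic_policy",
    "score_cohort",
]

#: CoC above which a cancellation score counts as pathological (strict >).
LETTER_COC_CUTOFF = 0.081
BELLS_COC_CUTOFF = 0.083
#: Copying score at or above which the copy counts as pathological
#: (2 points out of 8 = 25% omissions).
COPYING_CUTOFF = 2
COPYING_MAX_SCORE = 8

TESTS = ("letter", "bells", "copying")

FigureState = Literal["complete", "contralateral_feature_omitted", "wholly_omitted"]
_FIGURE_POINTS: dict[str, int] = {
    "complete": 0,
    "contralateral_feature_omitted": 1,
    "wholly_omitted": 2,
}


class DegenerateNormsError(ValueError):
    """Control norms cannot be fitted (too few controls or zero variance)."""


class UndefinedRecoveryError(ValueError):
    """Effectiveness of recovery is undefined (no test with acute severity above its floor)."""


@dataclass(frozen=True)
class CancellationResult:
    """One cancellation sheet: target positions and which were marked.

    ``target_x`` holds horizontal positions normalized to [-1, +1]
    (0 = sheet centre, +1 = right edge); ``marked`` is the parallel
    boolean list.
    """

    target_x: tuple[float, ...]
    marked: tuple[bool, ...]
    test_name: Literal["letter", "bells"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_x", tuple(float(x) for x in self.target_x))
        object.__setattr__(self, "marked", tuple(bool(m) for m in self.marked))
        if len(self.target_x) != len(self.marked):
            raise ValueError("target_x and marked must have equal length")
        if not self.target_x:
            raise ValueError("cancellation sheet has no targets")
        if any(x < -1.0 - 1e-12 or x > 1.0 + 1e-12 for x in self.target_x):
            raise ValueError("target positions must lie in [-1, +1]")
        if self.test_name not in ("letter", "bells"):
            raise ValueError(f"unknown cancellation test {self.test_name!r}")

    @property
    def n_marked(self) -> int:
        return sum(self.marked)


@dataclass(frozen=True)
class CopyingResult:
    """Copying task: four figures, each complete / feature-omitted / wholly omitted.

    One extra point is given when contralesional figures were drawn on
    the ipsilesional side of the sheet.
    """

    per_figure: tuple[FigureState, FigureState, FigureState, FigureState]
    misplaced_contralesional: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_figure", tuple(self.per_figure))
        if len(self.per_figure) != 4:
            raise ValueError("copying task has exactly 4 figures")
        for s in self.per_figure:
            if s not in _FIGURE_POINTS:
                raise ValueError(f"unknown figure state {s!r}")


@dataclass(frozen=True)
class TestBattery:
    """The three diagnostic tests at one time point; any test may be missing."""

    __test__ = False  # domain class, despite the pytest-like name

    letter: CancellationResult | None = None
    bells: CancellationResult | None = None
    copying: CopyingResult | None = None
    phase: Literal["acute", "chronic"] = "acute"

    def scores(self) -> dict[str, float]:
        """Raw score per available test (CoC for cancellation, 0-8 for copying)."""
        out: dict[str, float] = {}
        if self.letter is not None:
            out["letter"] = compute_coc(self.letter)
        if self.bells is not None:
            out["bells"] = compute_coc(self.bells)
        if self.copying is not None:
            out["copying"] = float(score_copying(self.copying))
        return out

    @property
    def is_scorable(self) -> bool:
        return any(t is not None for t in (self.letter, self.bells, self.copying))

    @property
    def is_complete(self) -> bool:
        return all(t is not None for t in (self.letter, self.bells, self.copying))


@dataclass(frozen=True)
class ControlNorms:
    """Per-test mean and sample SD of the control patients' acute scores."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, s in self.sd.items():
            if not s > 0:
                raise DegenerateNormsError(f"control SD for {t!r} must be > 0, got {s}")

    def z(self, test: str, score: float) -> float:
        return (score - self.mean[test]) / self.sd[test]


@dataclass
class TargetScores:
    """The three chronicity target variables for one patient."""

    chronic_z: float
    z_difference: float
    effectiveness: float  # percent in [0, 100]


@dataclass
class PatientRecord:
    """One patient: demographics, group label, test batteries, lesion reference."""

    patient_id: str
    group: Literal["chronic", "recovered", "control"]
    age: float
    sex: Literal["F", "M"]
    acute: TestBattery
    chronic: TestBattery | None = None
    lesion: object | None = None  # LesionVolume or a path to one
    targets: TargetScores | None = None


def compute_coc(result: CancellationResult) -> float:
    """Centre of cancellation: mean normalized position of the marked targets.

    With no target marked the patient found nothing, which on these
    sheets is read as complete left neglect: the layout's maximum
    (rightmost) position is returned so that severity stays monotone
    instead of undefined.
    """
    if result.n_marked == 0:
        return max(result.target_x)
    xs = [x for x, m in zip(result.target_x, result.marked) if m]
    return float(np.mean(xs))


def score_copying(result: CopyingResult) -> int:
    """Copying score 0-8: 1 per contralateral-feature omission, 2 per wholly
    omitted figure, +1 for contralesional figures misplaced to the right,
    capped at the maximum of 8."""
    score = sum(_FIGURE_POINTS[s] for s in result.per_figure)
    if result.misplaced_contralesional:
        score += 1
    return min(score, COPYING_MAX_SCORE)


def copying_percent_correct(score: float) -> float:
    """Reporting convenience: copying score re-expressed as % correct."""
    return 100.0 * (1.0 - score / COPYING_MAX_SCORE)


def is_pathological(test_name: str, score: float) -> bool:
    """Apply the per-test cutoff: CoC > 0.081 (letters) or > 0.083 (bells),
    copying score >= 2."""
    if test_name == "letter":
        return score > LETTER_COC_CUTOFF
    if test_name == "bells":
        return score > BELLS_COC_CUTOFF
    if test_name == "copying":
        return score >= COPYING_CUTOFF
    raise ValueError(f"unknown test name {test_name!r}")


def classify_patient(acute: TestBattery) -> Literal["neglect", "control", "unclassifiable"]:
    """Neglect if any available acute test is pathological; control only if
    all three tests are available and all non-pathological."""
    if not acute.is_scorable:
        raise ValueError("battery has no scorable test")
    scores = acute.scores()
    if any(is_pathological(t, s) for t, s in scores.items()):
        return "neglect"
    if acute.is_complete:
        return "control"
    return "unclassifiable"


def fit_control_norms(control_batteries: Iterable[TestBattery]) -> ControlNorms:
    """Per-test mean and sample SD (ddof=1) of the controls' acute scores.

    Requires at least two controls per test and nonzero variance;
    otherwise standardization is degenerate and an error is raised.
    """
    per_test: dict[str, list[float]] = {t: [] for t in TESTS}
    for battery in control_batteries:
        for t, s in battery.scores().items():
            per_test[t].append(s)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n: dict[str, int] = {}
    for t, vals in per_test.items():
        if len(vals) < 2:
            raise DegenerateNormsError(
                f"need >= 2 control scores for {t!r}, got {len(vals)}"
            )
        m = float(np.mean(vals))
        s = float(np.std(vals, ddof=1))
        if not s > 0:
            raise DegenerateNormsError(f"control scores for {t!r} have zero variance")
        mean[t], sd[t], n[t] = m, s, len(vals)
    return ControlNorms(mean=mean, sd=sd, n=n)


def composite_z(battery: TestBattery, norms: ControlNorms) -> float:
    """Mean of the available per-test z-scores (all oriented higher = worse).

    CoC and the raw copying score both increase with severity, so no test
    needs sign flipping.  Patients missing a test are averaged over the
    available tests; completeness is visible via ``battery.is_complete``.
    """
    scores = battery.scores()
    if not scores:
        raise ValueError("battery has no scorable test")
    return float(np.mean([norms.z(t, s) for t, s in scores.items()]))


def target_z_difference(acute_z: float, chronic_z: float) -> float:
    """Direct improvement: acute minus chronic composite z (positive = improved)."""
    return acute_z - chronic_z


def target_effectiveness(
    acute_scores: Mapping[str, float],
    chronic_scores: Mapping[str, float],
    floors: Mapping[str, float] | None = None,
) -> float:
    """Effectiveness of recovery in percent.

    Per test, ER = 100 * (acute - chronic) / (acute - floor): the share
    of the possible improvement (from the acute score down to the
    no-deficit floor) actually achieved, clipped to [0, 100].  Tests
    whose acute score is at or below the floor carry no recoverable
    deficit and are skipped; the remaining tests are averaged.  100
    means the deficit fully resolved, 0 means no improvement at all.
    Floors default to 0 on every test.
    """
    floors = dict(floors) if floors is not None else {}
    per_test: list[float] = []
    for t, acute in acute_scores.items():
        if t not in chronic_scores:
            continue
        floor = floors.get(t, 0.0)
        if acute <= floor:
            continue
        er = 100.0 * (acute - chronic_scores[t]) / (acute - floor)
        per_test.append(float(np.clip(er, 0.0, 100.0)))
    if not per_test:
        raise UndefinedRecoveryError(
            "no test has acute severity above its floor; recovery undefined"
        )
    return float(np.mean(per_test))


ControlChronicPolicy = Literal["zero_and_full", "carry_forward_acute", "recovery_zero"]


def apply_control_chronic_policy(
    patients: Sequence[PatientRecord],
    policy: ControlChronicPolicy = "zero_and_full",
    *,
    norms: ControlNorms | None = None,
) -> list[PatientRecord]:
    """Impute chronic targets for control patients (who were not re-tested).

    zero_and_full
        chronic z = 0 (the control average) and recovery = 100%.
    carry_forward_acute
        chronic z = that control's own acute composite z; recovery = 100%.
    recovery_zero
        like zero_and_full but recovery = 0%.

    Neglect patients are returned untouched.  ``carry_forward_acute``
    needs ``norms`` to compute the acute composite.
    """
    if policy not in ("zero_and_full", "carry_forward_acute", "recovery_zero"):
        raise ValueError(f"unknown control chronic policy {policy!r}")
    out: list[PatientRecord] = []
    for p in patients:
        if p.group != "control":
            out.append(p)
            continue
        if policy == "carry_forward_acute":
            if norms is None:
                raise ValueError("carry_forward_acute policy requires control norms")
            acute_z = composite_z(p.acute, norms)
            chronic_z = acute_z
            eff = 100.0
        else:
            acute_z = composite_z(p.acute, norms) if norms is not None else 0.0
            chronic_z = 0.0
            eff = 100.0 if policy == "zero_and_full" else 0.0
        targets = TargetScores(
            chronic_z=chronic_z,
            z_difference=target_z_difference(acute_z, chronic_z),
            effectiveness=eff,
        )
        out.append(replace(p, targets=targets))
    return out


def score_cohort(
    patients: Sequence[PatientRecord],
    *,
    control_policy: ControlChronicPolicy = "zero_and_full",
    floors: Mapping[str, float] | None = None,
):
    """Score a whole cohort into a tidy per-patient table.

    Fits control norms from the acute scores of the patients classified
    as controls, standardizes everyone, computes the three chronicity
    targets (imputing controls per ``control_policy``), and returns a
    pandas DataFrame with raw scores, z-scores, targets and the
    classification, plus the fitted :class:`ControlNorms`.
    """
    import pandas as pd

    classifications = {p.patient_id: classify_patient(p.acute) for p in patients}
    controls = [p.acute for p in patients if classifications[p.patient_id] == "control"]
    norms = fit_control_norms(controls)

    rows = []
    for p in patients:
        cls = classifications[p.patient_id]
        acute_scores = p.acute.scores()
        acute_z = composite_z(p.acute, norms)
        row: dict[str, object] = {
            "id": p.patient_id,
            "group": p.group,
            "classification": cls,
            "age": p.age,
            "sex": p.sex,
            "acute_z": acute_z,
            "acute_complete": p.acute.is_complete,
        }
        for t in TESTS:
            row[f"acute_{t}"] = acute_scores.get(t, math.nan)
        if cls != "control" and p.chronic is not None and p.chronic.is_scorable:
            chronic_scores = p.chronic.scores()
            chronic_z = composite_z(p.chronic, norms)
            eff = target_effectiveness(acute_scores, chronic_scores, floors)
            for t in TESTS:
                row[f"chronic_{t}"] = chronic_scores.get(t, math.nan)
            row["chronic_z"] = chronic_z
            row["z_difference"] = target_z_difference(acute_z, chronic_z)
            row["effectiveness"] = eff
        else:
            for t in TESTS:
                row[f"chronic_{t}"] = math.nan
            row["chronic_z"] = math.nan
            row["z_difference"] = math.nan
            row["effectiveness"] = math.nan
        rows.append(row)

    table = pd.DataFrame(rows).set_index("id")

    # impute control targets per policy
    imputed = apply_control_chronic_policy(
        [p for p in patients if classifications[p.patient_id] == "control"],
        control_policy,
        norms=norms,
    )
    for p in imputed:
        assert p.targets is not None
        table.loc[p.patient_id, "chronic_z"] = p.targets.chronic_z
        table.loc[p.patient_id, "z_difference"] = p.targets.z_difference
        table.loc[p.patient_id, "effectiveness"] = p.targets.effectiveness

    return table, norms
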