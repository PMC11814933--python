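"""Synthetic stroke cohorts with known lesion -> outcome structure.

The real study cohort (acute right-hemisphere stroke; 12 patients with
chronic neglect, 30 who recovered, 30 controls without acute neglect)
cannot be shared, so every downstream stage is exercised on synthetic
cohorts that emulate its data structure: binary lesion blobs on a
common grid whose overlap with a planted "chronic neglect ROI" drives
the chronic outcome, cancellation sheets and copying results generated
from a latent severity, and demographics with group-typical
distributions.  All distributional choices are stand-ins — the study
reports no generative model — and are documented in the methods note.

The generative chain per neglect patient:

    chronic latent = w_acute * acute_severity
                   + w_roi   * ROI-overlap fraction
                   + w_vol   * normalized lesion volume
                   + Gaussian(0, noise_sd),  clipped to [0, 1]

and the chronic test battery is then *generated* from that latent and
scored through the real behaviour module — ground-truth z-scores are
never written directly.  Controls follow the study design: acute tests
only, all non-pathological by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .behaviour import (
    CancellationResult,
    CopyingResult,
    PatientRecord,
    TestBattery,
    classify_patient,
)
from .lesion import LesionVolume, roi_overlap, write_lesion

__all__ = [
    "SphereSpec",
    "CohortConfig",
    "GroundTruth",
    "plant_roi",
    "generate_cancellation_sheet",
    "generate_copying",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Lesion volume (ml, toy grid) treated as "very large" when normalizing
#: the volume predictor into [0, 1].
VOLUME_NORM_ML = 30.0

_MAX_REJECTION_TRIES = 64


@dataclass(frozen=True)
class SphereSpec:
    """Geometric ROI description: a discrete ball |v - center|^2 <= radius^2."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Group sizes default to the study's 12 chronic / 30 recovered / 30
    control.  The grid is a desk-scale 32^3 at 2 mm voxels so that the
    ml arithmetic stays nontrivial while PCA remains cheap.
    ``effect_weights`` are the contributions of (acute severity,
    ROI-overlap fraction, normalized lesion volume) to the chronic
    latent outcome; ``noise_sd`` is the SD of the additive Gaussian
    noise on that latent.
    """

    n_chronic: int = 12
    n_recovered: int = 30
    n_control: int = 30
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    roi_spec: SphereSpec = field(default_factory=lambda: SphereSpec((22.0, 16.0, 14.0), 6.0))
    effect_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    noise_sd: float = 0.05
    n_targets: int = 60
    #: severity-independent miss probabilities emulating healthy attentional
    #: lapses, so that control scores have the small non-degenerate spread
    #: real control cohorts show
    lapse_cancellation: float = 0.02
    lapse_copying: float = 0.08
    deterministic_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chronic", "n_recovered", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(s <= 0 for s in self.grid_shape) or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("grid_shape and voxel_size_mm must be positive")

    @property
    def n_total(self) -> int:
        return self.n_chronic + self.n_recovered + self.n_control

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        return aff


@dataclass
class GroundTruth:
    """Latent generative state, kept for parameter-recovery experiments."""

    acute_severity: np.ndarray
    roi_fraction: np.ndarray
    volume_norm: np.ndarray
    latent_chronic: np.ndarray  # pre-noise
    chronic_severity: np.ndarray  # post-noise, clipped; NaN for controls
    effect_weights: tuple[float, float, float]

    @property
    def generative_blocks(self) -> list[str]:
        """Feature blocks carrying generative weight (ROI-derived blocks
        are interchangeable readouts of the ROI-overlap fraction)."""
        blocks: list[str] = []
        w_acute, w_roi, w_vol = self.effect_weights
        if w_acute != 0:
            blocks.append("acute_behaviour")
        if w_roi != 0:
            blocks += ["roi_size", "roi_pct_pcs", "roi_fs_pcs"]
        if w_vol != 0:
            blocks.append("wb_size")
        return blocks


def plant_roi(
    grid_shape: tuple[int, int, int],
    roi_spec: SphereSpec,
    affine: np.ndarray | None = None,
    space_tag: str = "synthetic",
) -> LesionVolume:
    """Rasterize the ROI spec onto the grid as a binary volume."""
    cx, cy, cz = roi_spec.center
    if not (0 <= cx < grid_shape[0] and 0 <= cy < grid_shape[1] and 0 <= cz < grid_shape[2]):
        raise ValueError(f"roi centre {roi_spec.center} outside grid {grid_shape}")
    grid = _rasterize_sphere(grid_shape, roi_spec.center, roi_spec.radius)
    if not grid.any():
        raise ValueError("roi spec rasterizes to an empty volume")
    if affine is None:
        affine = np.eye(4)
    return LesionVolume(grid=grid, affine=affine, space_tag=space_tag)


def _rasterize_sphere(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
) -> np.ndarray:
    ii, jj, kk = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    return (d2 <= radius**2 + 1e-9).astype(np.uint8)


def generate_cancellation_sheet(
    severity: float,
    n_targets: int,
    rng: np.random.Generator | int,
    test_name: str = "letter",
    deterministic: bool = False,
    lapse: float = 0.0,
) -> CancellationResult:
    """Simulate one cancellation sheet at the given latent severity.

    Targets sit at positions evenly spaced and symmetric about the sheet
    centre.  The probability of marking a target is 1 everywhere at
    severity 0 and collapses onto the right edge as severity approaches
    1, modelling the rightward attentional bias:

        p(mark | x) = (1 - lapse) * [(1-s)^2 + (1 - (1-s)^2) * sigmoid((x - (2s-1)) / tau)]

    so the "attentional cut" 2s - 1 sweeps from the left edge (s=0, all
    found) to the right edge (s=1, only the right-extreme column found),
    while the residual marking probability left of the cut, (1-s)^2,
    decays fast enough that severe patients reach the high CoC values
    severe left neglect produces on real sheets.
    ``lapse`` (default 0) is a position-independent miss probability;
    being symmetric it perturbs the CoC around its severity-driven value
    without biasing it.  ``deterministic=True`` marks exactly the
    targets with p >= 0.5, giving a reproducible noiseless
    severity -> score map.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not 0.0 <= lapse < 1.0:
        raise ValueError(f"lapse must be in [0, 1), got {lapse}")
    xs = np.linspace(-1.0, 1.0, n_targets)
    tau = 0.1
    cut = 2.0 * severity - 1.0
    residual = (1.0 - severity) ** 2
    p = (1.0 - lapse) * (residual + (1.0 - residual) / (1.0 + np.exp(-(xs - cut) / tau)))
    if deterministic:
        marked = p >= 0.5
    else:
        marked = rng.random(n_targets) < p
    return CancellationResult(
        target_x=tuple(xs), marked=tuple(bool(m) for m in marked), test_name=test_name
    )


def generate_copying(
    severity: float,
    rng: np.random.Generator | int,
    deterministic: bool = False,
    lapse: float = 0.0,
) -> CopyingResult:
    """Simulate the four-figure copying task at the given severity.

    Each figure is wholly omitted with probability s^2 and has its
    contralateral feature omitted with probability 2s(1-s) + lapse, so
    the expected score is about 2s per figure (8s over the sheet) plus
    a small severity-independent lapse contribution.  Misplacement of
    contralesional figures occurs with probability 0.2 s.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if deterministic:
        points = int(round(8 * severity))
        states: list[str] = []
        for _ in range(4):
            if points >= 2:
                states.append("wholly_omitted")
                points -= 2
            elif points == 1:
                states.append("contralateral_feature_omitted")
                points -= 1
            else:
                states.append("complete")
        return CopyingResult(per_figure=tuple(states), misplaced_contralesional=False)
    states = []
    p_whole = severity**2
    p_feature = min(2 * severity * (1 - severity) + lapse, 1.0 - p_whole)
    for _ in range(4):
        u = rng.random()
        if u < p_whole:
            states.append("wholly_omitted")
        elif u < p_whole + p_feature:
            states.append("contralateral_feature_omitted")
        else:
            states.append("complete")
    misplaced = bool(rng.random() < 0.2 * severity)
    return CopyingResult(per_figure=tuple(states), misplaced_contralesional=misplaced)


def _generate_battery(
    severity: float,
    config: CohortConfig,
    rng: np.random.Generator,
    phase: str,
) -> TestBattery:
    det = config.deterministic_scores
    lc = 0.0 if det else config.lapse_cancellation
    lp = 0.0 if det else config.lapse_copying
    return TestBattery(
        letter=generate_cancellation_sheet(severity, config.n_targets, rng, "letter", det, lc),
        bells=generate_cancellation_sheet(severity, config.n_targets, rng, "bells", det, lc),
        copying=generate_copying(severity, rng, det, lp),
        phase=phase,  # type: ignore[arg-type]
    )


# group-typical sampling ranges for the latent acute severity; controls
# stay low enough that their scores are non-pathological (enforced below)
_SEVERITY_RANGE = {
    "chronic": (0.50, 0.95),
    "recovered": (0.25, 0.95),
    "control": (0.0, 0.04),
}
_AGE_DIST = {"chronic": (69.0, 9.0), "recovered": (64.0, 12.0), "control": (56.0, 16.0)}
# median lesion volume in ml on the toy grid per group; the study-scale
# lesions (tens of ml in a ~1300 ml cerebrum) are rescaled to the same
# fraction of the toy grid volume
_LESION_MEDIAN_ML = {"chronic": 16.0, "recovered": 13.0, "control": 5.0}
_LESION_SIGMA = 0.6


def _generate_lesion(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> LesionVolume:
    """One connected, right-lateralized blob: a union of random spheres
    whose satellites are centred inside the main sphere."""
    gx, gy, gz = config.grid_shape
    voxel_ml = float(np.prod(config.voxel_size_mm)) / 1000.0
    target_ml = _LESION_MEDIAN_ML[group] * math.exp(rng.normal(0.0, _LESION_SIGMA))
    target_vox = max(target_ml / voxel_ml, 8.0)
    r_main = (3.0 * target_vox / (4.0 * math.pi)) ** (1.0 / 3.0)
    # centre in the right half of the grid (axis 0 = left-right, right = high
    # index), in the neighbourhood of deep right-hemisphere structures
    center = np.array(
        [
            rng.uniform(gx * 0.55 + r_main * 0.3, gx - 2),
            rng.uniform(gy * 0.2, gy * 0.8),
            rng.uniform(gz * 0.2, gz * 0.8),
        ]
    )
    grid = _rasterize_sphere(config.grid_shape, tuple(center), r_main)
    for _ in range(rng.integers(2, 5)):
        offset = rng.normal(0.0, r_main * 0.6, size=3)
        if np.linalg.norm(offset) > r_main:  # keep satellites attached
            offset *= r_main / np.linalg.norm(offset)
        sat_center = center + offset
        sat_r = r_main * rng.uniform(0.3, 0.7)
        grid |= _rasterize_sphere(config.grid_shape, tuple(sat_center), sat_r)
    return LesionVolume(grid=grid, affine=config.affine, space_tag="synthetic")


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[LesionVolume], GroundTruth]:
    """Generate one cohort: patient records, lesion volumes, ground truth.

    A single integer seed fans out through ``numpy.random.SeedSequence``
    into independent per-patient substreams, so the same config + seed
    always reproduces the same cohort and individual patients can be
    regenerated independently.
    """
    roi = plant_roi(config.grid_shape, config.roi_spec, config.affine)
    roi_ml = roi.volume_ml
    groups = (
        ["chronic"] * config.n_chronic
        + ["recovered"] * config.n_recovered
        + ["control"] * config.n_control
    )
    streams = np.random.SeedSequence(config.seed).spawn(len(groups))
    w = np.asarray(config.effect_weights, dtype=float)

    patients: list[PatientRecord] = []
    lesions: list[LesionVolume] = []
    gt = {k: [] for k in ("s", "roi_frac", "vol_norm", "latent", "s_chr")}

    for i, (group, stream) in enumerate(zip(groups, streams)):
        rng = np.random.default_rng(stream)
        lo, hi = _SEVERITY_RANGE[group]
        severity = float(rng.uniform(lo, hi))
        lesion = _generate_lesion(group, config, rng)
        _, overlap_ml = roi_overlap(lesion, roi)
        roi_frac = overlap_ml / roi_ml
        vol_norm = min(lesion.volume_ml / VOLUME_NORM_ML, 1.0)

        # acute battery; neglect patients must screen positive, controls
        # must screen negative on all three tests (bounded rejection)
        acute = _generate_battery(severity, config, rng, "acute")
        want = "control" if group == "control" else "neglect"
        for _ in range(_MAX_REJECTION_TRIES):
            if classify_patient(acute) == want:
                break
            if want == "control":
                severity = max(severity * 0.5, 0.0)
            else:
                severity = min(severity + 0.05, 1.0)
            acute = _generate_battery(severity, config, rng, "acute")
        else:  # pragma: no cover - the severity adjustments converge fast
            raise RuntimeError(f"could not generate a {want} battery for patient {i}")

        latent = float(w @ [severity, roi_frac, vol_norm])
        if group == "control":
            chronic_battery = None
            s_chr = math.nan
        else:
            s_chr = float(np.clip(latent + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
            chronic_battery = _generate_battery(s_chr, config, rng, "chronic")

        mean, sd = _AGE_DIST[group]
        age = float(np.clip(rng.normal(mean, sd), 25.0, 95.0))
        sex = "F" if rng.random() < 0.5 else "M"

        patients.append(
            PatientRecord(
                patient_id=f"p{i:03d}",
                group=group,  # type: ignore[arg-type]
                age=age,
                sex=sex,  # type: ignore[arg-type]
                acute=acute,
                chronic=chronic_battery,
                lesion=lesion,
            )
        )
        lesions.append(lesion)
        gt["s"].append(severity)
        gt["roi_frac"].append(roi_frac)
        gt["vol_norm"].append(vol_norm)
        gt["latent"].append(latent)
        gt["s_chr"].append(s_chr)

    ground_truth = GroundTruth(
        acute_severity=np.array(gt["s"]),
        roi_fraction=np.array(gt["roi_frac"]),
        volume_norm=np.array(gt["vol_norm"]),
        latent_chronic=np.array(gt["latent"]),
        chronic_severity=np.array(gt["s_chr"]),
        effect_weights=config.effect_weights,
    )
    return patients, lesions, ground_truth


# ---------------------------------------------------------------------------
# cohort I/O: one NIfTI per patient, per-sheet CSVs, and a cohort table
# ---------------------------------------------------------------------------


def _write_battery(battery: TestBattery, outdir: Path, pid: str, phase: str) -> None:
    import pandas as pd

    for test in ("letter", "bells"):
        result: CancellationResult | None = getattr(battery, test)
        if result is None:
            continue
        pd.DataFrame({"target_x": result.target_x, "marked": np.asarray(result.marked, int)}).to_csv(
            outdir / f"{pid}_{phase}_{test}.csv", index=False
        )
    if battery.copying is not None:
        pd.DataFrame(
            {
                "figure_state": battery.copying.per_figure,
                "misplaced_contralesional": int(battery.copying.misplaced_contralesional),
            }
        ).to_csv(outdir / f"{pid}_{phase}_copying.csv", index=False)


def _read_battery(sheet_dir: Path, pid: str, phase: str) -> TestBattery | None:
    import pandas as pd

    kwargs: dict[str, object] = {}
    for test in ("letter", "bells"):
        f = sheet_dir / f"{pid}_{phase}_{test}.csv"
        if f.exists():
            df = pd.read_csv(f)
            kwargs[test] = CancellationResult(
                target_x=tuple(df["target_x"]),
                marked=tuple(df["marked"].astype(bool)),
                test_name=test,  # type: ignore[arg-type]
            )
    f = sheet_dir / f"{pid}_{phase}_copying.csv"
    if f.exists():
        df = pd.read_csv(f)
        kwargs["copying"] = CopyingResult(
            per_figure=tuple(df["figure_state"]),
            misplaced_contralesional=bool(df["misplaced_contralesional"].iloc[0]),
        )
    if not kwargs:
        return None
    return TestBattery(phase=phase, **kwargs)  # type: ignore[arg-type]


def write_cohort(
    patients: Sequence[PatientRecord],
    lesions: Sequence[LesionVolume],
    ground_truth: GroundTruth,
    outdir: str | Path,
    roi: LesionVolume | None = None,
) -> Path:
    """Write a cohort to disk: lesion NIfTIs, sheet CSVs, cohort table,
    and the ground-truth latents as JSON."""
    import json

    import pandas as pd

    outdir = Path(outdir)
    (outdir / "lesions").mkdir(parents=True, exist_ok=True)
    (outdir / "sheets").mkdir(parents=True, exist_ok=True)

    rows = []
    for p, lesion in zip(patients, lesions):
        lesion_path = outdir / "lesions" / f"{p.patient_id}.nii.gz"
        write_lesion(lesion, lesion_path)
        _write_battery(p.acute, outdir / "sheets", p.patient_id, "acute")
        if p.chronic is not None:
            _write_battery(p.chronic, outdir / "sheets", p.patient_id, "chronic")
        row = {
            "id": p.patient_id,
            "group": p.group,
            "age": p.age,
            "sex": p.sex,
            "lesion_path": str(lesion_path.relative_to(outdir)),
        }
        for phase, battery in (("acute", p.acute), ("chronic", p.chronic)):
            scores = battery.scores() if battery is not None else {}
            for t in ("letter", "bells", "copying"):
                row[f"{phase}_{t}"] = scores.get(t, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    if roi is not None:
        write_lesion(roi, outdir / "roi.nii.gz")
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "acute_severity": ground_truth.acute_severity.tolist(),
                "roi_fraction": ground_truth.roi_fraction.tolist(),
                "volume_norm": ground_truth.volume_norm.tolist(),
                "latent_chronic": ground_truth.latent_chronic.tolist(),
                "chronic_severity": [
                    None if math.isnan(v) else v
                    for v in ground_truth.chronic_severity
                ],
                "effect_weights": list(ground_truth.effect_weights),
            }
        )
    )
    return outdir


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[list[PatientRecord], list[LesionVolume]]:
    """Load a cohort written by :func:`write_cohort`."""
    import pandas as pd

    from .lesion import read_lesion

    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    patients: list[PatientRecord] = []
    lesions: list[LesionVolume] = []
    for _, row in table.iterrows():
        pid = str(row["id"])
        acute = _read_battery(cohort_dir / "sheets", pid, "acute")
        if acute is None:
            raise ValueError(f"patient {pid} has no acute test sheets")
        chronic = _read_battery(cohort_dir / "sheets", pid, "chronic")
        lesion = read_lesion(cohort_dir / row["lesion_path"], space_tag="synthetic")
        patients.append(
            PatientRecord(
                patient_id=pid,
                group=row["group"],
                age=float(row["age"]),
                sex=row["sex"],
                acute=acute,
                chronic=chronic,
                lesion=lesion,
            )
        )
        lesions.append(lesion)
    return patients, lesions
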