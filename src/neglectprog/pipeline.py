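"""End-to-end orchestration: cohort -> scores -> features -> models.

Ties the stages together the way the study protocol chains them:
score the behaviour, classify and standardize, derive the chronicity
target, build lesion features (sizes, voxel-frequency-filtered PCA of
the whole-brain and ROI-based overlap matrices), assemble the scaled
predictor table, and hand everything to the model-selection layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .behaviour import ControlChronicPolicy, PatientRecord, score_cohort
from .engine import CVPlan
from .features import (
    DEFAULT_VARIANCE_THRESHOLDS,
    PCModel,
    FeatureMatrix,
    assemble_features,
    fit_pca,
    minmax_scale,
    select_pcs_by_variance,
    threshold_search,
)
from .lesion import LesionVolume, VoxelIndexSet, roi_overlap, vectorize, voxel_frequency_filter
from .model import PrognosisModel, PrognosisResults

__all__ = [
    "LesionFeatures",
    "TargetSpec",
    "compute_lesion_features",
    "prepare_target",
    "winning_variance_threshold",
    "build_feature_matrix",
    "CohortAnalysis",
]

TargetName = Literal["chronic_z", "z_difference", "effectiveness"]


@dataclass
class LesionFeatures:
    """Cohort-level lesion featurization shared by all predictor blocks."""

    wb_size_ml: np.ndarray
    roi_size_ml: np.ndarray
    wb_index: VoxelIndexSet
    roi_index: VoxelIndexSet
    wb_pca: PCModel
    roi_pca: PCModel
    wb_scores: np.ndarray  # patients x components
    roi_scores: np.ndarray


def compute_lesion_features(
    lesions: Sequence[LesionVolume],
    roi: LesionVolume,
    min_patients: int = 5,
) -> LesionFeatures:
    """Sizes, ROI overlaps, voxel filter and PCA for a whole cohort.

    The voxel-frequency filter (damage in >= ``min_patients`` patients)
    is applied independently to the whole-brain maps and to the
    ROI-based overlap maps, then each filtered matrix is reduced by
    centred PCA.
    """
    wb_size = np.array([v.volume_ml for v in lesions])
    overlaps = []
    roi_size = np.empty(len(lesions))
    for i, lesion in enumerate(lesions):
        overlap, ml = roi_overlap(lesion, roi)
        overlaps.append(overlap)
        roi_size[i] = ml

    wb_index = voxel_frequency_filter(lesions, min_patients, variant="whole_brain")
    roi_index = voxel_frequency_filter(overlaps, min_patients, variant="roi_overlap")
    if len(wb_index) == 0:
        raise ValueError("voxel filter removed every whole-brain voxel")
    if len(roi_index) == 0:
        raise ValueError(
            "voxel filter removed every ROI-overlap voxel; "
            "the ROI is rarely lesioned in this cohort"
        )
    wb_matrix = vectorize(lesions, wb_index)
    roi_matrix = vectorize(overlaps, roi_index)
    wb_pca = fit_pca(wb_matrix, variant="whole_brain")
    roi_pca = fit_pca(roi_matrix, variant="roi_overlap")
    return LesionFeatures(
        wb_size_ml=wb_size,
        roi_size_ml=roi_size,
        wb_index=wb_index,
        roi_index=roi_index,
        wb_pca=wb_pca,
        roi_pca=roi_pca,
        wb_scores=wb_pca.transform(wb_matrix),
        roi_scores=roi_pca.transform(roi_matrix),
    )


@dataclass
class TargetSpec:
    """One prepared target: values, neglect mask, group labels."""

    name: str
    values: np.ndarray
    eval_mask: np.ndarray
    groups: np.ndarray


def prepare_target(scores: pd.DataFrame, target: TargetName) -> TargetSpec:
    """Extract one chronicity target from the tidy score table.

    The evaluation mask marks the patients classified as neglect; their
    chronic scores must be present (controls' were imputed by policy).
    """
    if target not in ("chronic_z", "z_difference", "effectiveness"):
        raise ValueError(f"unknown target {target!r}")
    values = scores[target].to_numpy(dtype=float)
    eval_mask = (scores["classification"] == "neglect").to_numpy()
    if np.isnan(values).any():
        missing = scores.index[np.isnan(values)].tolist()
        raise ValueError(f"target {target!r} missing for patients {missing}")
    return TargetSpec(
        name=target,
        values=values,
        eval_mask=eval_mask,
        groups=scores["group"].to_numpy(),
    )


def winning_variance_threshold(
    pc_model: PCModel,
    pc_scores: np.ndarray,
    target: TargetSpec,
    plan: CVPlan,
    candidates: Sequence[float] = DEFAULT_VARIANCE_THRESHOLDS,
) -> tuple[float, dict[float, float]]:
    """Choose the %-variance threshold whose PC block predicts the target
    best (minimal cross-validated MSE; ties -> smaller threshold)."""

    def evaluate(thr: float) -> float:
        idx = select_pcs_by_variance(pc_model, thr)
        cols = [minmax_scale(pc_scores[:, j])[0] for j in idx]
        X = np.column_stack(cols)
        res = PrognosisModel(
            X, target.values, target.eval_mask, groups=target.groups, plan=plan
        ).fit()
        return res.mse

    return threshold_search(candidates, evaluate)


def build_feature_matrix(
    patients: Sequence[PatientRecord],
    lesion_features: LesionFeatures,
    target: TargetSpec,
    blocks: Sequence[str],
    *,
    filter_method: str = "pearson",
    k_filter: int = 5,
    variance_threshold: float | Mapping[str, float] | Literal["search"] = "search",
    threshold_candidates: Sequence[float] = DEFAULT_VARIANCE_THRESHOLDS,
    search_plan: CVPlan | None = None,
) -> FeatureMatrix:
    """Assemble the requested blocks for one target variable.

    FS-PC blocks filter components by association with this target over
    the neglect patients; %-PC blocks use either a fixed threshold or a
    per-target threshold search (``variance_threshold="search"``).
    """
    lf = lesion_features
    thr: float | Mapping[str, float]
    if variance_threshold == "search":
        thr_map: dict[str, float] = {}
        for block, model, scores in (
            ("wb_pct_pcs", lf.wb_pca, lf.wb_scores),
            ("roi_pct_pcs", lf.roi_pca, lf.roi_scores),
        ):
            if block in blocks:
                if search_plan is None:
                    raise ValueError("variance_threshold='search' needs a search_plan")
                thr_map[block], _ = winning_variance_threshold(
                    model, scores, target, search_plan, threshold_candidates
                )
        thr = thr_map
    else:
        thr = variance_threshold
    return assemble_features(
        patients,
        blocks,
        wb_size_ml=lf.wb_size_ml,
        roi_size_ml=lf.roi_size_ml,
        pc_scores={"whole_brain": lf.wb_scores, "roi_overlap": lf.roi_scores},
        pc_models={"whole_brain": lf.wb_pca, "roi_overlap": lf.roi_pca},
        target=target.values,
        eval_mask=target.eval_mask,
        filter_method=filter_method,
        k_filter=k_filter,
        variance_threshold=thr,
    )


class CohortAnalysis:
    """One cohort scored and featurized, ready for model fitting.

    Convenience wrapper: builds the score table (imputing control
    targets per policy), the lesion features, and per-target feature
    matrices on demand.
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        lesions: Sequence[LesionVolume],
        roi: LesionVolume,
        *,
        control_policy: ControlChronicPolicy = "zero_and_full",
        min_patients: int = 5,
    ) -> None:
        self.patients = list(patients)
        self.lesions = list(lesions)
        self.roi = roi
        self.scores, self.norms = score_cohort(patients, control_policy=control_policy)
        self.lesion_features = compute_lesion_features(lesions, roi, min_patients)

    def target(self, name: TargetName) -> TargetSpec:
        return prepare_target(self.scores, name)

    def features(
        self,
        target: TargetSpec | TargetName,
        blocks: Sequence[str],
        **kwargs,
    ) -> FeatureMatrix:
        if isinstance(target, str):
            target = self.target(target)
        return build_feature_matrix(
            self.patients, self.lesion_features, target, blocks, **kwargs
        )

    def fit(
        self,
        target: TargetSpec | TargetName,
        blocks: Sequence[str],
        plan: CVPlan,
        **feature_kwargs,
    ) -> PrognosisResults:
        if isinstance(target, str):
            target = self.target(target)
        fm = self.features(target, blocks, **feature_kwargs)
        return PrognosisModel(
            fm, target.values, target.eval_mask, groups=target.groups, plan=plan
        ).fit()
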