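"""Single-patient prediction from a trained model bundle.

The study ships its best models as an online tool into which a
clinician drops one lesion map and the acute cancellation scores.  A
:class:`ModelBundle` is the equivalent here: the winning predictor
blocks fitted on the full cohort, together with everything needed to
featurize one new patient — the voxel index sets, PC loadings, the
per-column min-max scaling, and the ROI map.  Predictions come back on
the original target scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import CVPlan, grid_search, svr_fit, svr_predict
from .features import FeatureMatrix, minmax_descale
from .lesion import LesionVolume, roi_overlap, vectorize
from .pipeline import CohortAnalysis, TargetSpec

__all__ = ["ModelBundle", "train_bundle"]


@dataclass
class ModelBundle:
    """Everything needed to predict one new patient."""

    blocks: list[str]
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]]
    provenance: dict[str, dict]
    target_name: str
    target_scaling: tuple[float, float]
    svr_model: object
    chosen_spec: dict
    lesion_features: object  # pipeline.LesionFeatures (index sets + PCA)
    roi: LesionVolume
    grid_shape: tuple[int, int, int]
    space_tag: str
    training_features: FeatureMatrix

    def save(self, path: str | Path) -> Path:
        import joblib

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        import joblib

        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle

    # -- featurization of one new patient --------------------------------

    def _scale(self, name: str, raw: float) -> float:
        lo, hi = self.scaling[name]
        if hi == lo:
            return 0.0
        return (raw - lo) / (hi - lo)

    def featurize(
        self,
        lesion: LesionVolume,
        letter_coc: float,
        bells_coc: float,
        age: float | None = None,
        sex: str | None = None,
    ) -> np.ndarray:
        """Assemble the bundle's feature row for one patient.

        Scaling uses the training cohort's recorded min/max, so a new
        patient may land slightly outside [0, 1]; CoC inputs outside
        the valid [-1, 1] range are rejected.
        """
        for name, coc in (("letter", letter_coc), ("bells", bells_coc)):
            if not -1.0 <= coc <= 1.0:
                raise ValueError(f"{name} CoC {coc} outside the valid range [-1, 1]")
        if lesion.grid.shape != self.grid_shape or lesion.space_tag != self.space_tag:
            raise ValueError(
                f"lesion grid {lesion.grid.shape} / space {lesion.space_tag!r} does not "
                f"match the bundle's {self.grid_shape} / {self.space_tag!r}"
            )
        lf = self.lesion_features
        overlap, roi_ml = roi_overlap(lesion, self.roi)
        values: dict[str, float] = {}
        pc_cache: dict[str, np.ndarray] = {}
        for name in self.feature_names:
            prov = self.provenance[name]
            kind = prov["kind"]
            if kind == "acute_behaviour":
                raw = 0.5 * (letter_coc + bells_coc)
            elif kind == "age":
                if age is None:
                    raise ValueError("bundle needs `age` for this model")
                raw = float(age)
            elif kind == "sex":
                if sex is None:
                    raise ValueError("bundle needs `sex` for this model")
                raw = 1.0 if str(sex).upper().startswith("F") else 0.0
            elif kind == "wb_size":
                raw = lesion.volume_ml
            elif kind == "roi_size":
                raw = roi_ml
            elif kind == "pc_block":
                variant = prov["variant"]
                if variant not in pc_cache:
                    if variant == "whole_brain":
                        row = vectorize([lesion], lf.wb_index)
                        pc_cache[variant] = lf.wb_pca.transform(row)[0]
                    else:
                        row = vectorize([overlap], lf.roi_index)
                        pc_cache[variant] = lf.roi_pca.transform(row)[0]
                raw = float(pc_cache[variant][prov["component"]])
            else:  # pragma: no cover - provenance kinds are closed
                raise ValueError(f"unknown feature kind {kind!r}")
            values[name] = self._scale(name, raw)
        return np.array([values[n] for n in self.feature_names])

    def predict(
        self,
        lesion: LesionVolume,
        letter_coc: float,
        bells_coc: float,
        age: float | None = None,
        sex: str | None = None,
    ) -> dict:
        """Predict the target for one patient; returns value + provenance."""
        row = self.featurize(lesion, letter_coc, bells_coc, age=age, sex=sex)
        scaled = float(svr_predict(self.svr_model, row[None, :])[0])
        value = float(minmax_descale(np.array([scaled]), self.target_scaling)[0])
        return {
            "target": self.target_name,
            "prediction": value,
            "prediction_scaled": scaled,
            "features": dict(zip(self.feature_names, row)),
            "blocks": self.blocks,
            "hyperparameters": self.chosen_spec,
        }

    def fitted_predictions(self) -> np.ndarray:
        """The full-cohort model's predictions for its own training
        patients, on the original target scale."""
        X = self.training_features.block_array(self.blocks)
        scaled = svr_predict(self.svr_model, X)
        return minmax_descale(scaled, self.target_scaling)


def train_bundle(
    analysis: CohortAnalysis,
    target: TargetSpec,
    blocks: Sequence[str],
    plan: CVPlan,
    feature_matrix: FeatureMatrix | None = None,
) -> ModelBundle:
    """Train a deployable model on the full cohort.

    Hyperparameters are chosen by the same inner-CV grid search used in
    the nested protocol, run once on the complete sample, then a single
    epsilon-SVR is refitted on all patients.  (Its apparent fit is an
    in-sample quantity; generalization error is what the nested CV
    reports.)
    """
    from .features import minmax_scale

    blocks = list(blocks)
    fm = feature_matrix if feature_matrix is not None else analysis.features(target, blocks)
    X = fm.block_array(blocks)
    y_scaled, target_scaling, degenerate = minmax_scale(target.values)
    if degenerate:
        raise ValueError("constant target: nothing to train")
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    spec = grid_search(X, y_scaled, target.eval_mask, plan, rng, strata=target.groups)
    model = svr_fit(X, y_scaled, spec)
    feature_names = [c for b in blocks for c in fm.blocks[b]]
    template = analysis.lesions[0]
    return ModelBundle(
        blocks=blocks,
        feature_names=feature_names,
        scaling={n: fm.scaling[n] for n in feature_names},
        provenance={n: fm.provenance[n] for n in feature_names},
        target_name=target.name,
        target_scaling=target_scaling,
        svr_model=model,
        chosen_spec={"C": spec.C, "gamma": spec.gamma, "epsilon": spec.epsilon},
        lesion_features=analysis.lesion_features,
        roi=analysis.roi,
        grid_shape=template.grid.shape,
        space_tag=template.space_tag,
        training_features=fm,
    )
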