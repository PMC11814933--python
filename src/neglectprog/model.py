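"""Model/Results interface over the repeated nested-CV epsilon-SVR.

:class:`PrognosisModel` is built from a feature matrix, a target vector
and an evaluation mask; ``fit()`` runs the repeated nested CV and
returns a :class:`PrognosisResults` carrying the averaged out-of-sample
predictions, the cross-validated metrics (MSE mean ± SD of the squared
errors, R², Pearson r), the winning hyperparameters per fold and
repetition, and a ``summary()`` table.

The target is min-max scaled to [0, 1] once on the full cohort (the
study protocol; a leakage caveat discussed in the methods note), so the
reported MSE lives on the same 0-1 scale as the study's.  Predictions
are available on both scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CVPlan, CVResult, Metrics, repeat_and_average
from .features import FeatureMatrix, minmax_descale, minmax_scale

__all__ = ["PrognosisModel", "PrognosisResults"]


class PrognosisModel:
    """Epsilon-SVR prognosis model under repeated nested cross-validation.

    Parameters
    ----------
    features
        Patients x predictors, already scaled to [0, 1]: a
        :class:`~neglectprog.features.FeatureMatrix` (optionally
        restricted via ``blocks``) or a plain array.
    target
        Per-patient target on its original scale; min-max scaled
        internally.
    eval_mask
        Boolean per patient; True marks the neglect patients over which
        every error (inner selection and outer metrics) is computed.
        Training always uses all patients.
    groups
        Optional per-patient stratum labels (chronic / recovered /
        control) for stratified fold assignment.
    plan
        Fold / repetition / grid layout; defaults to the full protocol
        (5 outer, 4 inner, 10 repetitions, 441-point grid).
    """

    def __init__(
        self,
        features: FeatureMatrix | np.ndarray,
        target: np.ndarray,
        eval_mask: np.ndarray,
        groups: Sequence | None = None,
        plan: CVPlan | None = None,
        blocks: Sequence[str] | None = None,
    ) -> None:
        if isinstance(features, FeatureMatrix):
            self.feature_matrix: FeatureMatrix | None = features
            self.blocks = list(blocks) if blocks is not None else list(features.blocks)
            X = features.block_array(self.blocks)
            self.feature_names = [c for b in self.blocks for c in features.blocks[b]]
        else:
            self.feature_matrix = None
            X = np.asarray(features, float)
            if X.ndim == 1:
                X = X[:, None]
            self.blocks = list(blocks) if blocks is not None else ["x"]
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        if np.isnan(X).any():
            raise ValueError("features contain missing values")
        self.exog = X
        target = np.asarray(target, float)
        if len(target) != len(X):
            raise ValueError("features and target lengths differ")
        if np.isnan(target).any():
            raise ValueError("target contains missing values")
        self.endog_raw = target
        self.endog, self.target_scaling, degenerate = minmax_scale(target)
        if degenerate:
            raise ValueError("constant target: nothing to predict")
        self.eval_mask = np.asarray(eval_mask, bool)
        if self.eval_mask.shape != (len(target),):
            raise ValueError("eval_mask must be boolean per patient")
        if self.eval_mask.sum() < 2:
            raise ValueError("need at least 2 evaluation patients")
        self.groups = None if groups is None else np.asarray(groups)
        self.plan = plan if plan is not None else CVPlan()

    def fit(self, seed: int | None = None) -> "PrognosisResults":
        """Run the repeated nested CV and return the results object."""
        plan = self.plan if seed is None else self.plan.with_(seed=seed)
        cv = repeat_and_average(
            self.exog, self.endog, self.eval_mask, plan, strata=self.groups
        )
        return PrognosisResults(model=self, plan=plan, cv=cv)


@dataclass
class PrognosisResults:
    """Results of one repeated nested-CV run."""

    model: PrognosisModel
    plan: CVPlan
    cv: CVResult

    @property
    def metrics(self) -> Metrics:
        return self.cv.metrics

    @property
    def mse(self) -> float:
        """Mean squared error over evaluation patients (0-1 target scale)."""
        return self.cv.metrics.mse_mean

    @property
    def mse_sd(self) -> float:
        """SD of the per-patient squared errors."""
        return self.cv.metrics.mse_sd

    @property
    def rsquared(self) -> float:
        """Cross-validated R²; negative when predictions are worse than
        predicting the evaluation mean."""
        return self.cv.metrics.r_squared

    @property
    def pearson_r(self) -> float:
        return self.cv.metrics.pearson_r

    @property
    def predictions(self) -> np.ndarray:
        """Averaged out-of-sample predictions on the scaled [0, 1] target."""
        return self.cv.predictions

    @property
    def predictions_original_scale(self) -> np.ndarray:
        return minmax_descale(self.cv.predictions, self.model.target_scaling)

    def prediction_frame(self) -> pd.DataFrame:
        """Per-patient table: actual, averaged prediction, evaluation flag."""
        index = (
            self.model.feature_matrix.values.index
            if self.model.feature_matrix is not None
            else pd.RangeIndex(len(self.cv.actual))
        )
        return pd.DataFrame(
            {
                "actual_scaled": self.cv.actual,
                "predicted_scaled": self.cv.predictions,
                "actual": self.model.endog_raw,
                "predicted": self.predictions_original_scale,
                "evaluated": self.cv.eval_mask,
            },
            index=index,
        )

    def summary(self) -> str:
        m = self.cv.metrics
        n = len(self.cv.actual)
        lines = [
            "Neglect prognosis: repeated nested-CV epsilon-SVR",
            "=" * 58,
            f"Predictor blocks:    {', '.join(self.model.blocks)}",
            f"Features:            {len(self.model.feature_names)}",
            f"Patients (train):    {n}",
            f"Patients (eval):     {int(self.cv.eval_mask.sum())}",
            f"Outer / inner folds: {self.plan.outer_folds} / {self.plan.inner_folds}",
            f"Repetitions:         {self.plan.n_repetitions}",
            f"Grid points:         {len(self.plan.grid)}",
            f"Seed:                {self.plan.seed}",
            "-" * 58,
            f"MSE (mean +- SD of squared errors): {m.mse_mean:.3f} +- {m.mse_sd:.3f}",
            f"Cross-validated R^2:                {m.r_squared:.2f}",
            f"Pearson r:                          {m.pearson_r:.2f}",
            "=" * 58,
        ]
        return "\n".join(lines)
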