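"""Model families, forward selection, permutation importance, group tests.

Three model families are compared per target variable, always by the
cross-validated MSE over neglect patients: (i) every predictor block on
its own, (ii) forward sequential selection starting from the best
single block and adding whichever block most reduces the MSE for as
long as any reduction is possible, (iii) full models containing all
scalar predictors plus at most one lesion-location (PC) block, since
the four location variants cover overlapping information.

Predictor importance is assessed by permutation: the tested block's
values are shuffled across patients (target and remaining blocks
fixed), the repeated nested CV is re-run, and the p-value is the
add-one estimator (1 + #{null MSE <= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .engine import CVPlan, Metrics, repeat_and_average
from .features import LOCATION_BLOCKS, FeatureMatrix
from .model import PrognosisModel, PrognosisResults

__all__ = [
    "SelectionTrace",
    "ModelComparison",
    "evaluate_single_predictors",
    "forward_selection",
    "evaluate_full_models",
    "permutation_test",
    "two_sample_t_from_summary",
]


@dataclass
class SelectionTrace:
    """Forward-selection path: blocks in chosen order with the MSE after
    each accepted iteration, plus every candidate's MSE per iteration."""

    selected: list[str]
    mse_path: list[float]
    candidate_mse: list[dict[str, float]]
    stopping_reason: str
    results: dict[tuple[str, ...], PrognosisResults] = field(default_factory=dict)

    @property
    def final_mse(self) -> float:
        return self.mse_path[-1]

    @property
    def final_result(self) -> PrognosisResults:
        return self.results[tuple(self.selected)]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "mse_path": self.mse_path,
            "candidate_mse": self.candidate_mse,
            "stopping_reason": self.stopping_reason,
        }


@dataclass
class ModelComparison:
    """Per-model CV results keyed by predictor-block set, with the winner."""

    family: Literal["single", "forward", "full"]
    results: dict[tuple[str, ...], PrognosisResults]

    @property
    def winner(self) -> tuple[str, ...]:
        return min(sorted(self.results), key=lambda k: self.results[k].mse)

    @property
    def winner_result(self) -> PrognosisResults:
        return self.results[self.winner]

    def table(self):
        import pandas as pd

        rows = []
        for key in sorted(self.results, key=lambda k: self.results[k].mse):
            m: Metrics = self.results[key].metrics
            rows.append(
                {
                    "model": " + ".join(key),
                    "mse_mean": m.mse_mean,
                    "mse_sd": m.mse_sd,
                    "r_squared": m.r_squared,
                    "pearson_r": m.pearson_r,
                }
            )
        return pd.DataFrame(rows)


def _fit(
    fm: FeatureMatrix,
    blocks: Sequence[str],
    target: np.ndarray,
    eval_mask: np.ndarray,
    plan: CVPlan,
    groups: Sequence | None,
) -> PrognosisResults:
    return PrognosisModel(
        fm, target, eval_mask, groups=groups, plan=plan, blocks=list(blocks)
    ).fit()


def evaluate_single_predictors(
    fm: FeatureMatrix,
    blocks: Sequence[str],
    target: np.ndarray,
    eval_mask: np.ndarray,
    plan: CVPlan,
    groups: Sequence | None = None,
) -> ModelComparison:
    """Fit every predictor block individually; the winner has minimal MSE."""
    if not blocks:
        raise ValueError("need at least one block")
    results = {(b,): _fit(fm, [b], target, eval_mask, plan, groups) for b in blocks}
    return ModelComparison(family="single", results=results)


def forward_selection(
    fm: FeatureMatrix,
    blocks: Sequence[str],
    target: np.ndarray,
    eval_mask: np.ndarray,
    plan: CVPlan,
    groups: Sequence | None = None,
    single: ModelComparison | None = None,
) -> SelectionTrace:
    """Forward sequential selection over predictor blocks.

    Starts from the single block with the smallest MSE, then repeatedly
    adds the block yielding the largest MSE reduction; stops as soon as
    no addition strictly reduces the MSE.  PC blocks enter as atomic
    candidates (their five components together).  Location blocks are
    mutually exclusive: once one is selected the other variants leave
    the candidate pool.
    """
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("forward selection needs at least 2 candidate blocks")
    if single is None:
        single = evaluate_single_predictors(fm, blocks, target, eval_mask, plan, groups)
    results = dict(single.results)
    first = single.winner[0]
    selected = [first]
    mse_path = [single.results[(first,)].mse]
    candidate_mse: list[dict[str, float]] = [
        {b: single.results[(b,)].mse for b in blocks}
    ]
    stopping = "no further MSE reduction"
    while True:
        remaining = [b for b in blocks if b not in selected]
        if any(b in LOCATION_BLOCKS for b in selected):
            remaining = [b for b in remaining if b not in LOCATION_BLOCKS]
        if not remaining:
            stopping = "all candidate blocks selected"
            break
        scores: dict[str, float] = {}
        for b in remaining:
            key = tuple(selected + [b])
            if key not in results:
                results[key] = _fit(fm, key, target, eval_mask, plan, groups)
            scores[b] = results[key].mse
        candidate_mse.append(scores)
        best = min(sorted(scores), key=lambda b: scores[b])
        if scores[best] < mse_path[-1]:
            selected.append(best)
            mse_path.append(scores[best])
        else:
            break
    return SelectionTrace(
        selected=selected,
        mse_path=mse_path,
        candidate_mse=candidate_mse,
        stopping_reason=stopping,
        results={k: v for k, v in results.items() if set(k) <= set(selected) or len(k) == 1},
    )


def evaluate_full_models(
    fm: FeatureMatrix,
    target: np.ndarray,
    eval_mask: np.ndarray,
    plan: CVPlan,
    groups: Sequence | None = None,
    scalar_blocks: Sequence[str] | None = None,
    location_blocks: Sequence[str] | None = None,
) -> ModelComparison:
    """Full models: all scalar predictors plus one lesion-location variant
    per model (and one model with no location block)."""
    scalars = [
        b for b in (scalar_blocks if scalar_blocks is not None else fm.blocks)
        if b not in LOCATION_BLOCKS
    ]
    locations = [
        b for b in (location_blocks if location_blocks is not None else fm.blocks)
        if b in LOCATION_BLOCKS
    ]
    variants: list[tuple[str, ...]] = [tuple(scalars)]
    variants += [tuple(scalars + [loc]) for loc in locations]
    results = {
        key: _fit(fm, key, target, eval_mask, plan, groups) for key in variants
    }
    return ModelComparison(family="full", results=results)


def permutation_test(
    fm: FeatureMatrix,
    model_blocks: Sequence[str],
    tested_block: str,
    target: np.ndarray,
    eval_mask: np.ndarray,
    plan: CVPlan,
    n_perm: int = 5000,
    seed: int = 0,
    observed_mse: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation importance of one block within a model.

    The tested block's rows are shuffled across patients while the
    target and the other blocks stay fixed; the repeated nested CV is
    re-run per permutation and the null MSEs are compared with the
    observed one.  Returns (p_value, null_mse_distribution) with
    p = (1 + #{null <= observed}) / (1 + n_perm) — smaller null errors
    mean the intact block was not needed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model_blocks = list(model_blocks)
    if tested_block not in model_blocks:
        raise ValueError(f"tested block {tested_block!r} not in model {model_blocks}")
    X = fm.block_array(model_blocks)
    cols = []
    for b in model_blocks:
        cols.extend((b, c) for c in fm.blocks[b])
    tested_cols = np.array([i for i, (b, _) in enumerate(cols) if b == tested_block])

    if observed_mse is None:
        observed_mse = PrognosisModel(
            fm, target, eval_mask, plan=plan, blocks=model_blocks
        ).fit().mse

    from .features import minmax_scale

    y_scaled, _, _ = minmax_scale(np.asarray(target, float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(y_scaled))
        Xp = X.copy()
        Xp[:, tested_cols] = X[np.ix_(perm, tested_cols)]
        cv = repeat_and_average(Xp, y_scaled, eval_mask, plan)
        null[i] = cv.metrics.mse_mean
    p = (1 + int((null <= observed_mse).sum())) / (1 + n_perm)
    return p, null


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: Literal["pooled", "welch"] = "pooled",
) -> float:
    """Two-sample t statistic from printed group summaries.

    ``pooled`` is the classic equal-variance t; ``welch`` the
    unequal-variance version.  The sign follows mean1 - mean2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se = math.sqrt(sd1**2 / n1 + sd2**2 / n2)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return (mean1 - mean2) / se
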