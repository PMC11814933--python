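"""Predictor construction: behaviour, demographics, sizes, PC blocks.

Candidate predictors mirror the study design: mean acute CoC of the two
cancellation tasks ("acute behaviour"), age, sex, whole-brain (WB)
lesion size, ROI lesion size (overlap with the chronic neglect ROI),
and four lesion-location blocks of principal-component scores — PCA of
the WB lesion matrix or of the ROI-based overlap matrix, with
components kept either by cumulative explained variance ("%-PCs",
contiguous) or as the five components most associated with the target
under a feature-selection filter ("FS-PCs", non-contiguous).  Every
column is min-max scaled to [0, 1] with the scaling parameters
recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import PatientRecord, compute_coc

__all__ = [
    "PCModel",
    "FeatureMatrix",
    "SCALAR_BLOCKS",
    "PC_BLOCKS",
    "LOCATION_BLOCKS",
    "acute_behaviour_feature",
    "fit_pca",
    "select_pcs_by_variance",
    "select_pcs_by_filter",
    "threshold_search",
    "minmax_scale",
    "minmax_descale",
    "assemble_features",
]

#: Blocks contributing one column each.
SCALAR_BLOCKS = ("acute_behaviour", "age", "sex", "wb_size", "roi_size")
#: Lesion-location blocks (mutually overlapping information; models
#: include at most one of them).
PC_BLOCKS = ("wb_pct_pcs", "roi_pct_pcs", "wb_fs_pcs", "roi_fs_pcs")
LOCATION_BLOCKS = PC_BLOCKS

#: Default candidate grid for the cumulative-explained-variance threshold.
DEFAULT_VARIANCE_THRESHOLDS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class PCModel:
    """Centred PCA of a patients x voxels lesion matrix."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_voxels), orthonormal rows
    explained_variance_ratio: np.ndarray  # descending
    variant: Literal["whole_brain", "roi_overlap"] = "whole_brain"

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.components + self.mean


def acute_behaviour_feature(patients: Sequence[PatientRecord]) -> np.ndarray:
    """Per-patient mean of the letter and bells acute CoC.

    Missing cancellation tests surface as NaN rather than silently
    dropping the patient.
    """
    out = np.full(len(patients), np.nan)
    for i, p in enumerate(patients):
        if p.acute.letter is not None and p.acute.bells is not None:
            out[i] = 0.5 * (compute_coc(p.acute.letter) + compute_coc(p.acute.bells))
    return out


def fit_pca(
    matrix: np.ndarray,
    variant: Literal["whole_brain", "roi_overlap"] = "whole_brain",
) -> PCModel:
    """Centred PCA keeping all min(n-1, p) components with nonzero variance."""
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"need a 2D matrix with >=2 patients, got shape {X.shape}")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix: PCA undefined (zero variance)")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    pca.fit(X)
    # drop numerically-zero trailing components of rank-deficient matrices
    keep = pca.explained_variance_ > max(pca.explained_variance_[0], 1.0) * 1e-12
    return PCModel(
        mean=pca.mean_,
        components=pca.components_[keep],
        explained_variance_ratio=pca.explained_variance_ratio_[keep],
        variant=variant,
    )


def select_pcs_by_variance(model: PCModel, threshold: float) -> np.ndarray:
    """Smallest prefix of components whose cumulative explained-variance
    ratio reaches ``threshold`` (contiguous selection)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(model.explained_variance_ratio)
    if cum[-1] < threshold - 1e-12:
        warnings.warn(
            f"threshold {threshold} exceeds total explained variance {cum[-1]:.4f}; "
            "keeping all components",
            stacklevel=2,
        )
        return np.arange(model.n_components)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return np.arange(k)


def _filter_pearson(scores: np.ndarray, target: np.ndarray) -> np.ndarray:
    sc = scores - scores.mean(axis=0)
    tc = target - target.mean()
    denom = np.sqrt((sc**2).sum(axis=0) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (sc * tc[:, None]).sum(axis=0) / denom, 0.0)
    return np.abs(r)


def _filter_spearman(scores: np.ndarray, target: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(scores, axis=0)
    return _filter_pearson(ranks, stats.rankdata(target))


def _filter_f_score(scores: np.ndarray, target: np.ndarray) -> np.ndarray:
    # univariate linear-fit F statistic; monotone in r^2, so ranking by F
    # differs from |r| only through its own scale
    r = _filter_pearson(scores, target)
    n = scores.shape[0]
    with np.errstate(divide="ignore"):
        return np.where(r < 1.0, r**2 / (1 - r**2) * (n - 2), np.inf)


FILTER_METHODS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "pearson": _filter_pearson,
    "spearman": _filter_spearman,
    "f_score": _filter_f_score,
}


def select_pcs_by_filter(
    scores: np.ndarray,
    target: np.ndarray,
    method: str = "pearson",
    k: int = 5,
    eval_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the k components most strongly associated with the target.

    Association is computed over ``eval_mask`` patients only (the
    neglect subsample), matching the neglect-only model-selection
    criterion.  Ties break toward the lower component index; selection
    may be non-contiguous.
    """
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}; choose from {sorted(FILTER_METHODS)}")
    scores = np.asarray(scores, float)
    target = np.asarray(target, float)
    if eval_mask is not None:
        scores = scores[np.asarray(eval_mask, bool)]
        target = target[np.asarray(eval_mask, bool)]
    n_comp = scores.shape[1]
    if n_comp < k:
        warnings.warn(
            f"only {n_comp} components available for k={k}; keeping all", stacklevel=2
        )
        return np.arange(n_comp)
    assoc = FILTER_METHODS[method](scores, target)
    # stable argsort on (-assoc, index) -> deterministic tie-break
    order = np.lexsort((np.arange(n_comp), -assoc))
    return np.sort(order[:k])


def threshold_search(
    candidate_thresholds: Sequence[float],
    evaluate: Callable[[float], float],
) -> tuple[float, dict[float, float]]:
    """Pick the %-variance threshold whose PC block predicts best.

    ``evaluate`` maps a threshold to the cross-validated MSE of the
    corresponding %-PC block; the threshold with minimal MSE wins, ties
    break toward the smaller threshold.  All candidate scores are
    returned for logging.
    """
    if not candidate_thresholds:
        raise ValueError("empty candidate threshold list")
    results = {float(t): float(evaluate(float(t))) for t in candidate_thresholds}
    winner = min(sorted(results), key=lambda t: results[t])
    return winner, results


def minmax_scale(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Scale to [0, 1] as (x - min) / (max - min).

    Returns (scaled, (min, max), degenerate).  A constant vector maps to
    all zeros with the degeneracy flag set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty vector")
    lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    if hi == lo:
        return np.zeros_like(v), (lo, hi), True
    return (v - lo) / (hi - lo), (lo, hi), False


def minmax_descale(scaled: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    lo, hi = params
    return np.asarray(scaled, float) * (hi - lo) + lo


@dataclass
class FeatureMatrix:
    """Patients x named predictors, each scaled to [0, 1], with provenance.

    ``blocks`` maps block name -> column names, so that selection can
    treat a PC block as one atomic candidate; ``scaling`` records the
    per-column min/max; ``provenance`` records where each column came
    from (behavioural, demographic, size, or pc_block with variant,
    selection rule and component indices).
    """

    values: pd.DataFrame
    blocks: dict[str, list[str]]
    scaling: dict[str, tuple[float, float]]
    provenance: dict[str, dict] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)

    @property
    def n_patients(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def block_array(self, block_names: Sequence[str]) -> np.ndarray:
        cols: list[str] = []
        for b in block_names:
            cols.extend(self.blocks[b])
        return self.values[cols].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def manifest(self) -> dict:
        return {
            "blocks": self.blocks,
            "scaling": {c: list(p) for c, p in self.scaling.items()},
            "provenance": self.provenance,
            "degenerate": sorted(self.degenerate),
        }


def _add_column(
    fm_values: dict[str, np.ndarray],
    fm: "FeatureMatrixBuilder",
    name: str,
    raw: np.ndarray,
    provenance: dict,
) -> None:
    scaled, params, degenerate = minmax_scale(raw)
    fm_values[name] = scaled
    fm.scaling[name] = params
    fm.provenance[name] = provenance
    if degenerate:
        fm.degenerate.add(name)


@dataclass
class FeatureMatrixBuilder:
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)


def assemble_features(
    patients: Sequence[PatientRecord],
    blocks: Sequence[str],
    *,
    wb_size_ml: np.ndarray | None = None,
    roi_size_ml: np.ndarray | None = None,
    pc_scores: Mapping[str, np.ndarray] | None = None,
    pc_models: Mapping[str, PCModel] | None = None,
    target: np.ndarray | None = None,
    eval_mask: np.ndarray | None = None,
    filter_method: str = "pearson",
    k_filter: int = 5,
    variance_threshold: float | Mapping[str, float] = 0.95,
    index: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the requested feature blocks into a scaled FeatureMatrix.

    Scalar blocks: acute_behaviour, age, sex (F=1, M=0), wb_size,
    roi_size.  PC blocks need ``pc_scores`` keyed by "whole_brain" /
    "roi_overlap" (full score matrices); FS blocks additionally need
    the target and eval mask to run the association filter, %-blocks
    use ``variance_threshold`` (a scalar, or per-block mapping) and the
    corresponding ``pc_models`` for the explained-variance ratios.
    """
    known = set(SCALAR_BLOCKS) | set(PC_BLOCKS)
    unknown = [b for b in blocks if b not in known]
    if unknown:
        raise ValueError(f"unknown feature block(s) {unknown}; known: {sorted(known)}")

    builder = FeatureMatrixBuilder()
    values: dict[str, np.ndarray] = {}
    block_cols: dict[str, list[str]] = {}

    variant_of = {"wb_pct_pcs": "whole_brain", "wb_fs_pcs": "whole_brain",
                  "roi_pct_pcs": "roi_overlap", "roi_fs_pcs": "roi_overlap"}

    for block in blocks:
        if block == "acute_behaviour":
            raw = acute_behaviour_feature(patients)
            _add_column(values, builder, block, raw, {"kind": "acute_behaviour"})
            block_cols[block] = [block]
        elif block == "age":
            raw = np.array([p.age for p in patients], float)
            _add_column(values, builder, block, raw, {"kind": "age"})
            block_cols[block] = [block]
        elif block == "sex":
            raw = np.array([1.0 if p.sex == "F" else 0.0 for p in patients])
            _add_column(values, builder, block, raw, {"kind": "sex", "coding": "F=1, M=0"})
            block_cols[block] = [block]
        elif block == "wb_size":
            if wb_size_ml is None:
                raise ValueError("wb_size block requested but wb_size_ml not provided")
            _add_column(values, builder, block, np.asarray(wb_size_ml, float),
                        {"kind": "wb_size", "units": "ml"})
            block_cols[block] = [block]
        elif block == "roi_size":
            if roi_size_ml is None:
                raise ValueError("roi_size block requested but roi_size_ml not provided")
            _add_column(values, builder, block, np.asarray(roi_size_ml, float),
                        {"kind": "roi_size", "units": "ml"})
            block_cols[block] = [block]
        else:  # PC block
            variant = variant_of[block]
            if pc_scores is None or variant not in pc_scores:
                raise ValueError(f"{block} requested but pc_scores[{variant!r}] not provided")
            scores = np.asarray(pc_scores[variant], float)
            if block.endswith("fs_pcs"):
                if target is None:
                    raise ValueError(f"{block} needs a target for the association filter")
                idx = select_pcs_by_filter(
                    scores, target, method=filter_method, k=k_filter, eval_mask=eval_mask
                )
                rule = {"selection_rule": "filter", "method": filter_method, "k": k_filter}
            else:
                if pc_models is None or variant not in pc_models:
                    raise ValueError(f"{block} needs pc_models[{variant!r}] for %-variance selection")
                thr = (
                    variance_threshold[block]
                    if isinstance(variance_threshold, Mapping)
                    else float(variance_threshold)
                )
                idx = select_pcs_by_variance(pc_models[variant], thr)
                rule = {"selection_rule": "variance", "threshold": thr}
            cols = []
            for j in idx:
                col = f"{block}_{j}"
                _add_column(
                    values, builder, col, scores[:, j],
                    {"kind": "pc_block", "block": block, "variant": variant,
                     "component": int(j), **rule},
                )
                cols.append(col)
            block_cols[block] = cols

    frame = pd.DataFrame(values, index=list(index) if index is not None
                         else [p.patient_id for p in patients])
    return FeatureMatrix(
        values=frame,
        blocks=block_cols,
        scaling=builder.scaling,
        provenance=builder.provenance,
        degenerate=builder.degenerate,
    )
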