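"""Model-to-brain neural predictivity and transfer readouts.

Model feature layers are scored against target recordings with the same
noise-corrected regression metric used for inter-animal consistency,
with the (deterministic) model features standing in for the source
animal: the mapping is fit separately to each half of the target's
trials, and the corrected per-unit ratios are concatenated across target
animals before taking the median. The best layer for an area is the one
maximising that median. The module also provides the stimulus
preprocessing contract (resize conventions for models trained at
different resolutions) and a generic linear transfer readout
(PCA -> linear classifier / ridge, regularisation chosen by inner
cross-validation) for downstream task evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit, ShuffleSplit
from sklearn.svm import LinearSVC

from ._stats import columnwise_pearson
from .consistency import (ConsistencyResult, SplitHalfPlan, StimulusSplitPlan,
                          _corrected_engine, aggregate_units)
from .mapping import MappingSpec
from .recordings import PopulationRecording

__all__ = [
    "ModelFeatureSet",
    "PredictivityResult",
    "model_neural_predictivity",
    "preprocess_stimulus_images",
    "linear_transfer_evaluation",
    "REGULARIZATION_GRID",
]

# Penalty grid for the linear readouts (classifier C; ridge alpha = 1/C).
REGULARIZATION_GRID: tuple[float, ...] = tuple(
    float(c) for c in (
        1e-8, 5e-8, 1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4,
        1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1, 1, 5, 1e2, 5e2,
        1e3, 5e3, 1e4, 5e4, 1e5, 5e5, 1e6, 5e6, 1e7, 5e7, 1e8, 5e8,
    )
)


@dataclass
class ModelFeatureSet:
    """Per-layer, trial-free feature matrices aligned to a stimulus set."""

    layers: dict[str, np.ndarray]
    stimulus_ids: list[str] = field(default_factory=list)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("feature set needs at least one layer")
        n_stimuli = {np.asarray(m).shape[0] for m in self.layers.values()}
        if len(n_stimuli) != 1:
            raise ValueError("all layers must share the stimulus axis")
        n = n_stimuli.pop()
        if not self.stimulus_ids:
            self.stimulus_ids = [f"stim_{i:04d}" for i in range(n)]
        if len(self.stimulus_ids) != n:
            raise ValueError("stimulus_ids length must match feature rows")
        for name, m in self.layers.items():
            arr = np.asarray(m, dtype=float)
            if arr.ndim != 2 or not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} must be a finite 2-D matrix")
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)


@dataclass
class PredictivityResult:
    """Per-layer aggregated predictivity and the best layer."""

    per_layer: dict[str, list[ConsistencyResult]]
    medians: dict[str, float]
    sems: dict[str, float]
    best_layer: str


def model_neural_predictivity(
    features: ModelFeatureSet,
    targets: Sequence[PopulationRecording],
    spec: MappingSpec | None = None,
    half_plan: SplitHalfPlan | None = None,
    split_plan: StimulusSplitPlan | None = None,
    sqrt_scope: str = "product",
) -> PredictivityResult:
    """Noise-corrected predictivity of each feature layer, plus best layer.

    For each layer and target animal, the mapping is fit from the layer's
    features to each trial-half of the target (train stimuli) and the
    corrected ratio evaluated on held-out stimuli; the model's mapping
    reliability term reflects only fit instability since the features
    carry no trial noise. Per-unit averages are concatenated across
    target animals; the best layer maximises the median.
    """
    spec = spec or MappingSpec()
    half_plan = half_plan or SplitHalfPlan()
    split_plan = split_plan or StimulusSplitPlan()
    if not targets:
        raise ValueError("need at least one target recording")
    for rec in targets:
        if rec.stimulus_ids != features.stimulus_ids:
            raise ValueError(
                f"stimulus ids of {rec.animal_id} do not match the features")

    per_layer: dict[str, list[ConsistencyResult]] = {}
    medians: dict[str, float] = {}
    sems: dict[str, float] = {}
    for name, mat in features.layers.items():
        results = []
        for target in targets:
            def source_halves(b: int, mat=mat):
                return mat, mat  # deterministic features: both "halves" equal
            meta = {"mode": "model", "layer": name,
                    "target": target.animal_id, "mapping": spec.kind,
                    "sqrt_scope": sqrt_scope}
            results.append(_corrected_engine(
                source_halves, target, spec, half_plan, split_plan,
                sqrt_scope, meta))
        per_layer[name] = results
        med, sem, _ = aggregate_units(results)
        medians[name] = med
        sems[name] = sem
    best = max(medians, key=medians.get)
    return PredictivityResult(per_layer=per_layer, medians=medians,
                              sems=sems, best_layer=best)


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out_shape = shape + img.shape[2:]
    return _sk_resize(img, out_shape, order=1, anti_aliasing=True,
                      preserve_range=True)


def _shortest_edge_resize(img: np.ndarray, edge: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h <= w:
        # non-short edge truncates (a 918 x 1174 input at edge 64 -> 64 x 81)
        new = (edge, int(w * edge / h))
    else:
        new = (int(h * edge / w), edge)
    return _resize(img, new)


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than {size}x{size} crop")
    top, left = (h - size) // 2, (w - size) // 2
    return img[top:top + size, left:left + size]


def preprocess_stimulus_images(
    images: np.ndarray,
    source_regime: str,
    target_resolution: int = 64,
) -> np.ndarray | list[np.ndarray]:
    """Apply a model's validation-time resize chain to stimulus images.

    ``imagenet_trained``: shortest edge to 256, center crop 224 x 224,
    resize to ``target_resolution`` square. ``cifar_trained``: shortest
    edge to ``target_resolution``, aspect preserved (so the long edge need
    not be square). Accepts one image (H, W[, C]) or a batch with a
    leading axis; bilinear interpolation with anti-aliasing throughout,
    deterministic and idempotent at the target geometry.
    """
    if source_regime not in ("imagenet_trained", "cifar_trained"):
        raise ValueError("source_regime must be 'imagenet_trained' or "
                         "'cifar_trained'")
    arr = np.asarray(images, dtype=float)
    single = arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] in (1, 3, 4))
    batch = [arr] if single else list(arr)

    out = []
    for img in batch:
        if source_regime == "imagenet_trained":
            img = _shortest_edge_resize(img, 256)
            img = _center_crop(img, 224)
            img = _resize(img, (target_resolution, target_resolution))
        else:
            img = _shortest_edge_resize(img, target_resolution)
        out.append(img)
    if single:
        return out[0]
    shapes = {o.shape for o in out}
    return np.stack(out) if len(shapes) == 1 else out


def _outer_splits(y: np.ndarray, task_kind: str, n_splits: int,
                  test_fraction: float, seed: int):
    if task_kind == "classification":
        splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                          test_size=test_fraction,
                                          random_state=seed)
        return splitter.split(np.zeros_like(y), y)
    splitter = ShuffleSplit(n_splits=n_splits, test_size=test_fraction,
                            random_state=seed)
    return splitter.split(np.zeros((len(y), 1)))


def linear_transfer_evaluation(
    features_per_layer: dict[str, np.ndarray],
    targets: np.ndarray,
    task_kind: str,
    n_outer_splits: int = 10,
    inner_folds: int = 5,
    pca_dim: int = 1000,
    test_fraction: float = 0.25,
    penalty_grid: Sequence[float] = REGULARIZATION_GRID,
    seed: int = 0,
) -> tuple[dict[str, float], str]:
    """Linear readout performance of each feature layer on a task.

    Features above ``pca_dim`` dimensions are reduced by PCA fit on the
    training portion of each outer split only. Classification fits a
    linear max-margin classifier with penalty C chosen by ``inner_folds``-
    fold cross-validation on the training split; regression fits ridge
    with alpha = 1/C over the same grid and scores the Pearson correlation
    (averaged over output dimensions). Scores are averaged over
    ``n_outer_splits`` class-balanced train/test splits; returns
    ``(per-layer scores, best layer)``.
    """
    if task_kind not in ("classification", "regression"):
        raise ValueError("task_kind must be 'classification' or 'regression'")
    y = np.asarray(targets)
    if task_kind == "regression" and y.ndim == 1:
        y = y[:, None]
    n_samples = len(y)
    if n_samples < inner_folds:
        raise ValueError("fewer samples than inner folds")
    if task_kind == "classification" and np.unique(y).size < 2:
        raise ValueError("classification needs at least two classes")

    scores: dict[str, float] = {}
    for name, mat in features_per_layer.items():
        x = np.asarray(mat, dtype=float)
        if x.shape[0] != n_samples:
            raise ValueError(f"layer {name!r} rows do not match targets")
        split_scores = []
        for k, (tr, te) in enumerate(
                _outer_splits(y.ravel() if task_kind == "classification" else y,
                              task_kind, n_outer_splits, test_fraction, seed)):
            x_tr, x_te = x[tr], x[te]
            if x.shape[1] > pca_dim:
                pca = PCA(n_components=min(pca_dim, len(tr) - 1),
                          random_state=seed)
                x_tr = pca.fit_transform(x_tr)
                x_te = pca.transform(x_te)
            if task_kind == "classification":
                grid = {"C": list(penalty_grid)}
                search = GridSearchCV(
                    LinearSVC(max_iter=5000), grid, cv=inner_folds)
                search.fit(x_tr, y[tr].ravel())
                split_scores.append(search.score(x_te, y[te].ravel()))
            else:
                grid = {"alpha": [1.0 / c for c in penalty_grid]}
                search = GridSearchCV(Ridge(), grid, cv=inner_folds)
                search.fit(x_tr, y[tr])
                pred = np.atleast_2d(search.predict(x_te))
                pred = pred.reshape(len(te), -1)
                r = columnwise_pearson(pred, y[te].reshape(len(te), -1))
                split_scores.append(float(np.nanmean(r)))
        scores[name] = float(np.mean(split_scores))
    best = max(scores, key=scores.get)
    return scores, best
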