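"""Source-to-target population mapping transforms.

Four mapping classes align one population's trial-averaged responses to
another's: ``identity`` (unit-matched pass-through), ``one_to_one`` (each
target unit paired with its single best-correlated source unit plus a
univariate rescaling), ``ridge`` (L2-penalised multivariate regression,
alpha = 1 in the scikit-learn convention), and ``pls`` (partial least
squares with 25 components). These are the transform classes whose
strictness spans "no pooling at all" to "flexible but still linear"; all
consistency and predictivity computations are parameterised by one of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge

from ._stats import cross_pearson

logger = logging.getLogger(__name__)

MAP_KINDS = ("identity", "one_to_one", "ridge", "pls")


@dataclass(frozen=True)
class MappingSpec:
    """Declarative description of a mapping transform.

    ``ridge_penalty`` is the L2 regularisation strength (default 1);
    ``pls_components`` the requested PLS component count (default 25;
    capped at ``min(requested, n_train_stimuli - 1, n_source_units)`` and
    at the numerical rank of the training matrix so small problems stay
    well-posed). ``one_to_one_abs`` switches the assignment from the signed
    maximum Pearson correlation (default, "top correlated") to the maximum
    absolute correlation.
    """

    kind: str = "pls"
    ridge_penalty: float = 1.0
    pls_components: int = 25
    one_to_one_abs: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}")
        if self.ridge_penalty <= 0:
            raise ValueError("ridge_penalty must be > 0")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")


@dataclass
class FittedMap:
    """A trained mapping plus everything needed to reapply it."""

    spec: MappingSpec
    n_source_units: int
    n_target_units: int
    params: dict[str, Any] = field(default_factory=dict)
    train_stimulus_ids: list[str] | None = None

    def predict(self, source_test: np.ndarray) -> np.ndarray:
        return predict_map(self, source_test)


def _validate_xy(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("source and target must be 2-D (stimuli x units)")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"stimulus count mismatch: source {x.shape[0]} vs target {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 stimuli to fit a mapping")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in mapping inputs")
    return x, y


def one_to_one_assignment(
    source_train: np.ndarray,
    target_train: np.ndarray,
    absolute: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-correlated source unit per target unit.

    Returns ``(assignment, valid)``: for each target unit the index of the
    source unit with maximal (signed, or absolute when ``absolute``) Pearson
    correlation on the training stimuli; ties resolve to the lowest source
    index. A constant target unit has no defined correlation: its entry is
    -1 with ``valid`` False.
    """
    x, y = _validate_xy(source_train, target_train)
    corr = cross_pearson(x, y)  # (n_src, n_tgt)
    if absolute:
        corr = np.abs(corr)
    score = np.where(np.isnan(corr), -np.inf, corr)
    target_valid = ~np.all(np.isnan(corr), axis=0)
    assignment = np.argmax(score, axis=0)  # first occurrence wins ties
    assignment = np.where(target_valid, assignment, -1)
    return assignment, target_valid


def fit_map(
    source_train: np.ndarray,
    target_train: np.ndarray,
    spec: MappingSpec,
    train_stimulus_ids: list[str] | None = None,
) -> FittedMap:
    """Fit the mapping described by ``spec`` on training stimuli."""
    x, y = _validate_xy(source_train, target_train)
    fm = FittedMap(spec=spec, n_source_units=x.shape[1],
                   n_target_units=y.shape[1],
                   train_stimulus_ids=train_stimulus_ids)

    if spec.kind == "identity":
        if x.shape[1] != y.shape[1]:
            raise ValueError("identity mapping requires equal unit counts")
        return fm

    if spec.kind == "one_to_one":
        assignment, valid = one_to_one_assignment(
            x, y, absolute=spec.one_to_one_abs)
        slope = np.zeros(y.shape[1])
        intercept = np.full(y.shape[1], np.nan)
        for j in range(y.shape[1]):
            if not valid[j]:
                continue
            xv = x[:, assignment[j]]
            xvc = xv - xv.mean()
            denom = float(xvc @ xvc)
            slope[j] = float(xvc @ (y[:, j] - y[:, j].mean())) / denom if denom > 0 else 0.0
            intercept[j] = y[:, j].mean() - slope[j] * xv.mean()
        fm.params = {"assignment": assignment, "valid": valid,
                     "slope": slope, "intercept": intercept}
        return fm

    # Multivariate fits: drop zero-variance source units first.
    keep = x.std(axis=0) > 0
    if not np.any(keep):
        raise ValueError("all source units are constant on the training set")
    xk = x[:, keep]

    if spec.kind == "ridge":
        model = Ridge(alpha=spec.ridge_penalty, fit_intercept=True)
        model.fit(xk, y)
    else:  # pls
        cap = min(spec.pls_components, x.shape[0] - 1, xk.shape[1])
        rank = int(np.linalg.matrix_rank(xk - xk.mean(axis=0)))
        n_comp = max(1, min(cap, rank))
        if n_comp < spec.pls_components:
            logger.debug("PLS components capped: requested %d, using %d",
                         spec.pls_components, n_comp)
        model = PLSRegression(n_components=n_comp, scale=False)
        model.fit(xk, y)
        fm.params["n_components"] = n_comp
    fm.params.update({"model": model, "source_keep": keep})
    return fm


def predict_map(fitted: FittedMap, source_test: np.ndarray) -> np.ndarray:
    """Apply a fitted mapping to new source responses (deterministic)."""
    x = np.asarray(source_test, dtype=float)
    if x.ndim != 2 or x.shape[1] != fitted.n_source_units:
        raise ValueError(
            f"source_test must have {fitted.n_source_units} columns "
            f"(got shape {x.shape})")
    spec = fitted.spec
    if spec.kind == "identity":
        return x.copy()
    if spec.kind == "one_to_one":
        assignment = fitted.params["assignment"]
        valid = fitted.params["valid"]
        pred = np.full((x.shape[0], len(assignment)), np.nan)
        cols = x[:, np.where(valid, assignment, 0)]
        pred = cols * fitted.params["slope"] + fitted.params["intercept"]
        pred[:, ~valid] = np.nan
        return pred
    xk = x[:, fitted.params["source_keep"]]
    pred = fitted.params["model"].predict(xk)
    return np.asarray(pred)
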