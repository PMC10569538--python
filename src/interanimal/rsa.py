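"""Representational similarity analysis with noise correction.

An RDM (representational dissimilarity matrix) summarises a population's
stimulus geometry as a stimuli x stimuli matrix of pairwise response
dissimilarities; two systems are compared by correlating the strict upper
triangles of their RDMs (the RSA score). Because RSA already marginalises
over units, populations of different sizes compare directly under the
identity mapping, and the same split-half / Spearman-Brown machinery used
for unit-level consistency yields a noise-corrected RSA: the cross-system
RSA divided by the geometric mean of the two systems' RDM reliabilities
(for deterministic model features the source reliability is exactly 1).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._stats import pearson
from .consistency import (ConsistencyResult, SplitHalfPlan,
                          _animal_stream_seed, _half_average, spearman_brown)
from .recordings import PopulationRecording

__all__ = ["compute_rdm", "rsa_score", "noise_corrected_rsa"]


def compute_rdm(responses: np.ndarray, metric: str = "correlation") -> np.ndarray:
    """Stimuli x stimuli dissimilarity matrix of a (stimuli, units) array.

    Default dissimilarity is 1 - Pearson correlation between the two
    stimuli's response vectors across units; ``metric="euclidean"`` is
    available as an alternative. Symmetric with a zero diagonal. A
    constant (zero-variance) stimulus vector has no defined correlation
    distance: its entries are NaN and excluded pairwise downstream.
    """
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2:
        raise ValueError("responses must be 2-D (stimuli x units)")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 units")
    if metric == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if metric != "correlation":
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ xc.T) / np.outer(norms, norms)
    rdm = 1.0 - corr
    rdm[~np.isfinite(rdm)] = np.nan
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rsa_score(rdm_x: np.ndarray, rdm_y: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two RDMs.

    The diagonal is excluded. Entries undefined in either RDM are dropped
    pairwise; a constant (or empty) remaining triangle raises.
    """
    rdm_x = np.asarray(rdm_x, dtype=float)
    rdm_y = np.asarray(rdm_y, dtype=float)
    if rdm_x.shape != rdm_y.shape:
        raise ValueError("RDMs must have equal shapes")
    n = rdm_x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 stimuli")
    iu = np.triu_indices(n, k=1)
    tx, ty = rdm_x[iu], rdm_y[iu]
    ok = np.isfinite(tx) & np.isfinite(ty)
    tx, ty = tx[ok], ty[ok]
    if tx.size < 3:
        raise ValueError("too few defined RDM entries")
    r = pearson(tx, ty)
    if not np.isfinite(r):
        raise ValueError("RSA undefined: constant RDM triangle")
    return r


def noise_corrected_rsa(
    x_source,
    target: PopulationRecording,
    half_plan: SplitHalfPlan | None = None,
    mode: str = "animal_pair",
    metric: str = "correlation",
) -> ConsistencyResult:
    """Noise-corrected RSA between a source and a target animal.

    ``animal_pair`` mode (source is a :class:`PopulationRecording`)::

        RSA(s1A, s2B) / sqrt( SB(RSA(s1A, s2A)) * SB(RSA(s1B, s2B)) )

    ``model`` mode (source is a deterministic stimuli x features matrix,
    whose mapping reliability is exactly 1)::

        RSA(r, s2B) / sqrt( SB(RSA(s1B, s2B)) )

    averaged over bootstrapped trial halvings. Bootstraps with a
    nonpositive reliability term are excluded and counted. The result holds
    a single value (one per target *animal*, since RSA pools over units).
    """
    half_plan = half_plan or SplitHalfPlan()
    if mode not in ("animal_pair", "model"):
        raise ValueError("mode must be 'animal_pair' or 'model'")
    if mode == "animal_pair" and not isinstance(x_source, PopulationRecording):
        raise TypeError("animal_pair mode needs a PopulationRecording source")

    if mode == "model":
        feats = np.asarray(x_source, dtype=float)
        if feats.shape[0] != target.n_stimuli:
            raise ValueError("feature rows must match target stimuli")
        rdm_model = compute_rdm(feats, metric=metric)

    total, count, excluded = 0.0, 0, 0
    for b in range(half_plan.n_bootstraps):
        rng_t = np.random.default_rng(np.random.SeedSequence(
            _animal_stream_seed(half_plan.seed, b, target.animal_id)))
        s1b, s2b = _half_average(target.responses, rng_t)
        tgt_raw = rsa_score(compute_rdm(s1b, metric=metric),
                            compute_rdm(s2b, metric=metric))
        if tgt_raw <= 0:
            excluded += 1
            continue
        tgt_rel = spearman_brown(tgt_raw)
        if mode == "animal_pair":
            rng_s = np.random.default_rng(np.random.SeedSequence(
                _animal_stream_seed(half_plan.seed, b, x_source.animal_id)))
            s1a, s2a = _half_average(x_source.responses, rng_s)
            src_raw = rsa_score(compute_rdm(s1a, metric=metric),
                                compute_rdm(s2a, metric=metric))
            if src_raw <= 0:
                excluded += 1
                continue
            src_rel = spearman_brown(src_raw)
            num = rsa_score(compute_rdm(s1a, metric=metric),
                            compute_rdm(s2b, metric=metric))
        else:
            src_rel = 1.0
            num = rsa_score(rdm_model, compute_rdm(s2b, metric=metric))
        total += num / np.sqrt(src_rel * tgt_rel)
        count += 1

    if count == 0:
        raise ValueError("every bootstrap excluded: target RDM unreliable")
    value = total / count
    kept = np.array([count > 0.5 * half_plan.n_bootstraps])
    return ConsistencyResult(
        per_unit_values=np.array([value if kept[0] else np.nan]),
        n_excluded=np.array([excluded]),
        n_evaluations=half_plan.n_bootstraps,
        kept_mask=kept,
        metadata={"mode": f"rsa_{mode}", "target": target.animal_id,
                  "metric": metric, "half_plan": half_plan})
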