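"""Noise-corrected inter-animal consistency.

The central question this module answers: how well can one animal's
population activity predict another's, once both animals' trial noise is
accounted for? The estimator compares a mapping's predictions against a
held-out half of the target's trials (numerator) and normalises by the
geometric mean of the mapping's own split-half reliability and the
target's internal consistency, each Spearman-Brown corrected to its
full-trial equivalent (denominator):

    Corr(M(s1A; s1B), s2B) / sqrt( SB(Corr(M(s1A;s1B), M(s2A;s2B)))
                                   * SB(Corr(s1B, s2B)) )

averaged over bootstrapped trial halvings and stimulus train/test splits,
yielding one value per target unit. A perfect mapping of the reliable
signal scores 1 regardless of the noise level, which is what makes this
quantity usable as a ceiling for model-to-brain predictivity.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._stats import columnwise_pearson
from .mapping import MappingSpec, fit_map
from .recordings import PopulationRecording

logger = logging.getLogger(__name__)

__all__ = [
    "SplitHalfPlan",
    "StimulusSplitPlan",
    "ConsistencyResult",
    "split_trials",
    "spearman_brown",
    "internal_consistency",
    "noise_corrected_pairwise_consistency",
    "pooled_source_consistency",
    "aggregate_units",
    "fit_loglinear_extrapolation",
]


@dataclass(frozen=True)
class SplitHalfPlan:
    """How many bootstrapped trial halvings to average over."""

    n_bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


@dataclass(frozen=True)
class StimulusSplitPlan:
    """Random train/test stimulus splits (default 50%, ten splits)."""

    train_fraction: float = 0.5
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass
class ConsistencyResult:
    """Per-target-unit corrected values plus diagnostics.

    ``per_unit_values`` carries one averaged value per target unit (mean of
    the corrected ratio over all bootstrap x split evaluations in which the
    unit's denominator was valid); units excluded in more than half of the
    evaluations are dropped (``kept_mask`` False, value NaN). ``median`` and
    ``sem`` summarise the kept units.
    """

    per_unit_values: np.ndarray
    n_excluded: np.ndarray
    n_evaluations: int
    kept_mask: np.ndarray
    numerator_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    denominator_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    @property
    def kept_values(self) -> np.ndarray:
        return self.per_unit_values[self.kept_mask]

    @property
    def median(self) -> float:
        vals = self.kept_values
        if vals.size == 0:
            raise ValueError("all units excluded; no median defined")
        return float(np.median(vals))

    @property
    def sem(self) -> float:
        vals = self.kept_values
        if vals.size == 0:
            raise ValueError("all units excluded; no s.e.m. defined")
        if vals.size == 1:
            return 0.0
        return float(np.std(vals, ddof=1) / np.sqrt(vals.size))


def spearman_brown(r):
    """Full-length reliability from a split-half correlation: 2r / (1 + r)."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= -1.0):
        raise ValueError("Spearman-Brown is undefined for r <= -1")
    out = 2.0 * arr / (1.0 + arr)
    return float(out) if np.isscalar(r) else out


def _half_average(responses: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint half-split of the trial axis, each half averaged."""
    n_trials = responses.shape[1]
    perm = rng.permutation(n_trials)
    half = n_trials // 2
    if n_trials % 2:
        logger.debug("odd trial count %d: dropping one random trial", n_trials)
    s1 = responses[:, perm[:half]].mean(axis=1)
    s2 = responses[:, perm[half:2 * half]].mean(axis=1)
    return s1, s2


def split_trials(recording: PopulationRecording, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split a recording's trials into random disjoint halves and average.

    Returns two ``(n_stimuli, n_units)`` arrays. Odd trial counts drop one
    randomly chosen trial.
    """
    if recording.n_trials < 2:
        raise ValueError("need at least 2 trials to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _half_average(recording.responses, rng)


def _animal_stream_seed(base_seed: int, bootstrap: int, animal_id: str) -> list[int]:
    # Stable per-animal entropy so pooled and pairwise computations draw
    # identical trial halvings for the same animal and bootstrap index.
    return [base_seed, bootstrap, zlib.crc32(animal_id.encode())]


def _stimulus_split(n_stimuli: int, plan: StimulusSplitPlan, split_index: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(
        np.random.SeedSequence([plan.seed, split_index]))
    perm = rng.permutation(n_stimuli)
    n_train = int(round(plan.train_fraction * n_stimuli))
    n_train = min(max(n_train, 2), n_stimuli - 2)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def internal_consistency(
    recording: PopulationRecording,
    plan: SplitHalfPlan | None = None,
    corrected: bool = True,
) -> np.ndarray:
    """Per-unit split-half consistency, averaged over bootstrapped halvings.

    For each bootstrap the trials are split into random disjoint halves,
    each averaged, and the Pearson correlation across stimuli is taken per
    unit; with ``corrected`` the Spearman-Brown transform is applied per
    bootstrap before averaging. Bootstraps in which a unit is constant are
    excluded for that unit (logged); a unit invalid in every bootstrap
    yields NaN.
    """
    plan = plan or SplitHalfPlan()
    if recording.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if recording.n_stimuli < 3:
        raise ValueError("need at least 3 stimuli")
    resp = recording.responses
    if resp.ndim == 4:
        raise ValueError("time-binned recording: select a window first "
                         "(see unit selection) or average over bins")
    acc = np.zeros(recording.n_units)
    cnt = np.zeros(recording.n_units, dtype=int)
    for b in range(plan.n_bootstraps):
        rng = np.random.default_rng(np.random.SeedSequence(
            _animal_stream_seed(plan.seed, b, recording.animal_id)))
        s1, s2 = _half_average(resp, rng)
        r = columnwise_pearson(s1, s2)
        if corrected:
            with np.errstate(invalid="ignore"):
                r = np.where(r > -1.0, 2.0 * r / (1.0 + r), np.nan)
        ok = np.isfinite(r)
        if not ok.all():
            logger.debug("bootstrap %d: %d constant units excluded",
                         b, int((~ok).sum()))
        acc[ok] += r[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    out[cnt == 0] = np.nan
    return out


def _corrected_engine(
    source_halves: Callable[[int], tuple[np.ndarray, np.ndarray]],
    target: PopulationRecording,
    spec: MappingSpec,
    half_plan: SplitHalfPlan,
    split_plan: StimulusSplitPlan,
    sqrt_scope: str,
    metadata: dict,
) -> ConsistencyResult:
    """Shared evaluation loop for animal-pair and model-to-brain scoring.

    ``source_halves(b)`` returns the two source half-average matrices for
    bootstrap ``b`` (identical deterministic features twice, in model mode).
    Each of the ``n_bootstraps`` evaluations pairs a fresh trial halving
    with one of the ``n_splits`` stimulus splits, cycling through splits.
    """
    if sqrt_scope not in ("product", "mapping_only"):
        raise ValueError("sqrt_scope must be 'product' or 'mapping_only'")
    n_units = target.n_units
    n_eval = half_plan.n_bootstraps
    acc = np.zeros(n_units)
    cnt = np.zeros(n_units, dtype=int)
    num_trace = np.full(n_eval, np.nan)
    den_trace = np.full(n_eval, np.nan)

    for b in range(n_eval):
        split_idx = b % split_plan.n_splits
        train, test = _stimulus_split(target.n_stimuli, split_plan, split_idx)
        rng_t = np.random.default_rng(np.random.SeedSequence(
            _animal_stream_seed(half_plan.seed, b, target.animal_id)))
        s1b, s2b = _half_average(target.responses, rng_t)
        x1, x2 = source_halves(b)

        m1 = fit_map(x1[train], s1b[train], spec)
        m2 = fit_map(x2[train], s2b[train], spec)
        p1 = m1.predict(x1[test])
        p2 = m2.predict(x2[test])

        num = columnwise_pearson(p1, s2b[test])
        with np.errstate(invalid="ignore"):
            map_rel = spearman_brown(
                np.clip(columnwise_pearson(p1, p2), -1.0 + 1e-12, 1.0))
            tgt_rel = spearman_brown(
                np.clip(columnwise_pearson(s1b[test], s2b[test]),
                        -1.0 + 1e-12, 1.0))
            if sqrt_scope == "product":
                denom = np.sqrt(map_rel * tgt_rel)
            else:
                denom = np.sqrt(map_rel) * tgt_rel
        valid = (np.isfinite(num) & np.isfinite(denom)
                 & (map_rel > 0) & (tgt_rel > 0))
        ratio = np.where(valid, num / denom, np.nan)
        acc[valid] += ratio[valid]
        cnt[valid] += 1
        if valid.any():
            num_trace[b] = float(np.nanmedian(num[valid]))
            den_trace[b] = float(np.nanmedian(denom[valid]))

    with np.errstate(invalid="ignore"):
        per_unit = acc / cnt
    per_unit[cnt == 0] = np.nan
    n_excluded = n_eval - cnt
    kept = cnt > 0.5 * n_eval
    per_unit = np.where(kept, per_unit, np.nan)
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("%d/%d target units dropped (>50%% invalid evaluations)",
                    n_dropped, n_units)
    return ConsistencyResult(
        per_unit_values=per_unit, n_excluded=n_excluded,
        n_evaluations=n_eval, kept_mask=kept,
        numerator_trace=num_trace, denominator_trace=den_trace,
        metadata=metadata)


def _check_same_stimuli(a: PopulationRecording, b: PopulationRecording) -> None:
    if a.stimulus_ids != b.stimulus_ids:
        raise ValueError("recordings must share an identical stimulus set")


def noise_corrected_pairwise_consistency(
    source: PopulationRecording,
    target: PopulationRecording,
    spec: MappingSpec | None = None,
    half_plan: SplitHalfPlan | None = None,
    split_plan: StimulusSplitPlan | None = None,
    sqrt_scope: str = "product",
) -> ConsistencyResult:
    """Noise-corrected consistency from one source animal to one target.

    Per bootstrap x split: both animals' trials are halved and averaged;
    the mapping is fit half-1-to-half-1 and half-2-to-half-2 on training
    stimuli; the corrected ratio is evaluated on held-out stimuli (see the
    module docstring) and averaged per target unit. Evaluations where a
    denominator term is nonpositive or undefined are excluded and counted;
    units invalid in more than half of the evaluations are dropped.
    """
    spec = spec or MappingSpec()
    half_plan = half_plan or SplitHalfPlan()
    split_plan = split_plan or StimulusSplitPlan()
    _check_same_stimuli(source, target)
    if source.n_trials < 2 or target.n_trials < 2:
        raise ValueError("both recordings need at least 2 trials")

    def source_halves(b: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(np.random.SeedSequence(
            _animal_stream_seed(half_plan.seed, b, source.animal_id)))
        return _half_average(source.responses, rng)

    meta = {"mode": "pairwise", "source": source.animal_id,
            "target": target.animal_id, "mapping": spec.kind,
            "sqrt_scope": sqrt_scope,
            "half_plan": half_plan, "split_plan": split_plan}
    return _corrected_engine(source_halves, target, spec, half_plan,
                             split_plan, sqrt_scope, meta)


def pooled_source_consistency(
    cohort: Sequence[PopulationRecording],
    spec: MappingSpec | None = None,
    half_plan: SplitHalfPlan | None = None,
    split_plan: StimulusSplitPlan | None = None,
    sqrt_scope: str = "product",
) -> list[ConsistencyResult]:
    """Hold out each animal in turn against the pooled remaining units.

    The source for each held-out target is the unit-concatenation of all
    other animals (a pseudo-population); the computation is otherwise
    identical to the pairwise case. With two animals this reduces exactly
    to the pairwise result.
    """
    if len(cohort) < 2:
        raise ValueError("pooled-source consistency needs >= 2 animals")
    spec = spec or MappingSpec()
    half_plan = half_plan or SplitHalfPlan()
    split_plan = split_plan or StimulusSplitPlan()
    for rec in cohort[1:]:
        _check_same_stimuli(cohort[0], rec)

    results = []
    for t_idx, target in enumerate(cohort):
        sources = [r for i, r in enumerate(cohort) if i != t_idx]

        def source_halves(b: int, sources=sources) -> tuple[np.ndarray, np.ndarray]:
            h1, h2 = [], []
            for rec in sources:
                rng = np.random.default_rng(np.random.SeedSequence(
                    _animal_stream_seed(half_plan.seed, b, rec.animal_id)))
                a, c = _half_average(rec.responses, rng)
                h1.append(a)
                h2.append(c)
            return np.hstack(h1), np.hstack(h2)

        meta = {"mode": "pooled", "target": target.animal_id,
                "sources": [r.animal_id for r in sources],
                "mapping": spec.kind, "sqrt_scope": sqrt_scope,
                "half_plan": half_plan, "split_plan": split_plan}
        results.append(_corrected_engine(source_halves, target, spec,
                                         half_plan, split_plan, sqrt_scope,
                                         meta))
    return results


def aggregate_units(results: Sequence[ConsistencyResult]
                    ) -> tuple[float, float, np.ndarray]:
    """Concatenate per-unit values across target animals; median and s.e.m.

    The s.e.m. is the standard deviation of the per-unit values divided by
    the square root of the number of kept units. Excluded units are not
    silently averaged in; if everything is excluded, an error is raised.
    """
    if not results:
        raise ValueError("no results to aggregate")
    values = np.concatenate([r.kept_values for r in results])
    if values.size == 0:
        raise ValueError("all units excluded across all results")
    median = float(np.median(values))
    sem = 0.0 if values.size == 1 else float(
        np.std(values, ddof=1) / np.sqrt(values.size))
    return median, sem, values


class LogLinearFit:
    """f(n) = a * log10(n) + b, least squares; reported predictions cap at 1."""

    def __init__(self, a: float, b: float):
        self.a = float(a)
        self.b = float(b)

    def predict(self, n, clip: bool = True):
        n = np.asarray(n, dtype=float)
        if np.any(n <= 0):
            raise ValueError("sample sizes must be positive")
        raw = self.a * np.log10(n) + self.b
        if clip and np.any(raw > 1.0):
            logger.info("log-linear prediction clipped at 1.0")
            raw = np.minimum(raw, 1.0)
        return float(raw) if raw.ndim == 0 else raw

    def __iter__(self):  # allows a, b, predict = fit_loglinear_extrapolation(...)
        yield self.a
        yield self.b
        yield self.predict


def fit_loglinear_extrapolation(sample_sizes: Sequence[float],
                                consistencies: Sequence[float]) -> LogLinearFit:
    """Fit the unit-subsampling consistency curve f(n) = a log10(n) + b."""
    n = np.asarray(sample_sizes, dtype=float)
    y = np.asarray(consistencies, dtype=float)
    if n.size < 2 or np.unique(n).size < 2:
        raise ValueError("need at least 2 distinct sample points")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    a, b = np.polyfit(np.log10(n), y, deg=1)
    return LogLinearFit(a, b)
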