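"""Dataset conditioning: reliability filters, time windows, specimen cuts.

Three procedures condition raw recordings before any consistency analysis:

* a unit filter keeping units whose Spearman-Brown corrected split-half
  consistency reaches 0.3 (averaged over 100 bootstrapped halvings) and
  whose peak responses are not significantly modulated by a behavioural
  covariate such as running speed (p > 0.05);
* a temporal-window selector for time-binned (electrophysiology-style)
  recordings, averaging responses over the largest contiguous run of
  10-ms bins in which the population-median split-half consistency
  reaches 0.3;
* a specimen filter keeping, per area, only specimens with at least the
  75th-percentile unit count.

The behavioural-modulation test is a stand-in: the selection criterion
names no specific test, so a two-sided permutation test on the Spearman
correlation between the covariate and the unit's preferred-stimulus
responses is used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .consistency import SplitHalfPlan, internal_consistency
from .recordings import PopulationRecording

__all__ = [
    "SelectionReport",
    "calcium_unit_filter",
    "neuropixels_window_select",
    "specimen_percentile_filter",
]


@dataclass
class SelectionReport:
    """Per-unit filter outcome with both criteria reported separately."""

    reliability: np.ndarray
    kept_mask: np.ndarray
    reliability_pass: np.ndarray
    behavior_p_values: np.ndarray | None = None
    behavior_pass: np.ndarray | None = None
    window: tuple[int, int] | None = None
    per_bin_median_reliability: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def dropped_mask(self) -> np.ndarray:
        return ~self.kept_mask

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


def _preferred_stimulus(responses: np.ndarray) -> np.ndarray:
    """Stimulus with maximal trial-mean response per unit (ties: lowest index)."""
    mean = responses.mean(axis=1)  # (stimuli, units)
    return np.argmax(mean, axis=0)


def _permutation_p_values(
    responses: np.ndarray,
    covariate: np.ndarray,
    preferred: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Two-sided permutation p-value of the covariate/response Spearman rho.

    For each unit the covariate values at its preferred stimulus's
    presentations are permuted; rho is a Pearson correlation of ranks, so
    the permutation null is built by shuffling the covariate ranks.
    """
    n_stimuli, n_trials, n_units = responses.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.empty(n_units)
    # Pre-draw one permutation block per stimulus actually used.
    perms_cache: dict[int, np.ndarray] = {}
    for u in range(n_units):
        s = int(preferred[u])
        y = rankdata(responses[s, :, u])
        x = rankdata(covariate[s])
        if s not in perms_cache:
            perms_cache[s] = np.stack(
                [rng.permutation(x) for _ in range(n_permutations)])
        perms = perms_cache[s]
        yc = y - y.mean()
        sy = np.sqrt((yc**2).sum())

        def rho(xm: np.ndarray) -> np.ndarray:
            xc = xm - xm.mean(axis=-1, keepdims=True)
            sx = np.sqrt((xc**2).sum(axis=-1))
            with np.errstate(invalid="ignore", divide="ignore"):
                return (xc @ yc) / (sx * sy)

        obs = float(rho(x[None, :])[0])
        if not np.isfinite(obs):
            p[u] = 1.0  # constant responses: no modulation evidence
            continue
        null = rho(perms)
        null = null[np.isfinite(null)]
        p[u] = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (len(null) + 1.0)
    return p


def calcium_unit_filter(
    recording: PopulationRecording,
    behavior_covariate: np.ndarray | None = None,
    reliability_threshold: float = 0.3,
    p_threshold: float = 0.05,
    half_plan: SplitHalfPlan | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SelectionReport:
    """Keep units that are reliable and not behaviourally modulated.

    A unit passes when its Spearman-Brown corrected split-half consistency
    (averaged over the plan's bootstraps) is at least
    ``reliability_threshold`` AND, when a per-presentation
    ``behavior_covariate`` of shape ``(n_stimuli, n_trials)`` is given,
    the permutation p-value of its preferred-stimulus modulation exceeds
    ``p_threshold``.
    """
    half_plan = half_plan or SplitHalfPlan(n_bootstraps=100)
    reliability = internal_consistency(recording, half_plan, corrected=True)
    with np.errstate(invalid="ignore"):
        rel_pass = reliability >= reliability_threshold
    rel_pass &= np.isfinite(reliability)

    p_values = None
    behavior_pass = None
    if behavior_covariate is not None:
        cov = np.asarray(behavior_covariate, dtype=float)
        if cov.shape != (recording.n_stimuli, recording.n_trials):
            raise ValueError(
                "behavior_covariate must have shape (n_stimuli, n_trials)")
        preferred = _preferred_stimulus(recording.responses)
        p_values = _permutation_p_values(
            recording.responses, cov, preferred, n_permutations, seed)
        behavior_pass = p_values > p_threshold

    kept = rel_pass if behavior_pass is None else (rel_pass & behavior_pass)
    return SelectionReport(
        reliability=reliability, kept_mask=kept, reliability_pass=rel_pass,
        behavior_p_values=p_values, behavior_pass=behavior_pass,
        metadata={"reliability_threshold": reliability_threshold,
                  "p_threshold": p_threshold,
                  "n_bootstraps": half_plan.n_bootstraps})


def _per_bin_median_reliability(
    recording: PopulationRecording,
    half_plan: SplitHalfPlan,
    n_bins: int,
) -> np.ndarray:
    medians = np.empty(n_bins)
    for b in range(n_bins):
        bin_rec = PopulationRecording(
            responses=recording.responses[..., b],
            animal_id=recording.animal_id, area=recording.area,
            stimulus_ids=list(recording.stimulus_ids))
        rel = internal_consistency(bin_rec, half_plan, corrected=True)
        medians[b] = float(np.nanmedian(rel))
    return medians


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) of the longest run of True; earliest wins ties."""
    best = None
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    return best


def neuropixels_window_select(
    recording: PopulationRecording,
    max_ms: int = 250,
    reliability_threshold: float = 0.3,
    half_plan: SplitHalfPlan | None = None,
) -> tuple[tuple[int, int] | None, PopulationRecording | None, SelectionReport]:
    """Average a time-binned recording over its most reliable window.

    Considers bins up to ``max_ms``; the window is the largest contiguous
    run of bins whose population-median Spearman-Brown corrected
    split-half consistency reaches the threshold (ties: earliest run).
    Returns ``(window, averaged recording, report)``; when no bin
    qualifies the window and recording are None.
    """
    if recording.n_bins is None:
        raise ValueError("recording has no time-bin axis")
    half_plan = half_plan or SplitHalfPlan(n_bootstraps=100)
    n_consider = min(recording.n_bins, max_ms // recording.time_bin_ms)
    if n_consider < 1:
        raise ValueError("no bins inside the considered time range")
    medians = _per_bin_median_reliability(recording, half_plan, n_consider)
    window = _longest_true_run(medians >= reliability_threshold)

    averaged = None
    if window is not None:
        start, stop = window
        averaged = PopulationRecording(
            responses=recording.responses[..., start:stop].mean(axis=-1),
            animal_id=recording.animal_id, area=recording.area,
            stimulus_ids=list(recording.stimulus_ids))
    reliability = (internal_consistency(averaged, half_plan)
                   if averaged is not None
                   else np.full(recording.n_units, np.nan))
    report = SelectionReport(
        reliability=reliability,
        kept_mask=np.full(recording.n_units, window is not None),
        reliability_pass=np.full(recording.n_units, window is not None),
        window=window, per_bin_median_reliability=medians,
        metadata={"reliability_threshold": reliability_threshold,
                  "max_ms": max_ms, "bin_ms": recording.time_bin_ms})
    return window, averaged, report


def specimen_percentile_filter(
    unit_counts: dict[str, dict[str, int]],
    percentile: float = 75.0,
) -> dict[str, list[str]]:
    """Keep specimens with at least the area's percentile unit count.

    ``unit_counts`` maps area -> {specimen_id: n_units}. The threshold is
    the linear-interpolation percentile of that area's counts and the
    comparison is inclusive (>=), so a single specimen is always kept.
    """
    kept: dict[str, list[str]] = {}
    for area, counts in unit_counts.items():
        if not counts:
            raise ValueError(f"area {area!r} has no specimens")
        values = np.array(list(counts.values()), dtype=float)
        threshold = float(np.percentile(values, percentile))
        kept[area] = [s for s, n in counts.items() if n >= threshold]
    return kept
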