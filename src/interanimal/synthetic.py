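"""Synthetic multi-animal cohorts with analytically known signal/noise.

The generator emulates the shape of a natural-scenes recording session:
multiple animals per area, 118 stimuli presented 50 times each, per-unit
reliabilities that can straddle the 0.3 selection threshold, and an
optional 10-ms time-bin axis. Each animal observes a shared low-rank
latent signal through its own mixing matrix; trials add i.i.d. Gaussian
noise per unit. Because signal and noise variances are known, the expected
split-half reliability of every unit has a closed form
(:func:`analytic_split_half_consistency`), which anchors the recovery
tests for every estimator downstream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .recordings import GroundTruth, PopulationRecording, apply_nonlinearity

__all__ = [
    "generate_cohort",
    "analytic_split_half_consistency",
    "generate_timebinned_recording",
    "generate_model_features",
]


def _per_unit_noise_sd(noise_sd, n_units: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve a scalar / (low, high) range / per-unit vector into a vector."""
    if np.isscalar(noise_sd):
        sd = np.full(n_units, float(noise_sd))
    elif isinstance(noise_sd, tuple) and len(noise_sd) == 2:
        lo, hi = float(noise_sd[0]), float(noise_sd[1])
        if lo < 0 or hi < lo:
            raise ValueError("noise_sd range must satisfy 0 <= low <= high")
        sd = rng.uniform(lo, hi, size=n_units)
    else:
        sd = np.asarray(noise_sd, dtype=float)
        if sd.shape != (n_units,):
            raise ValueError("per-unit noise_sd must have length n_units")
    if np.any(sd < 0):
        raise ValueError("noise_sd must be nonnegative")
    return sd


def generate_cohort(
    n_animals: int = 2,
    n_units: int = 100,
    n_stimuli: int = 118,
    n_trials: int = 50,
    n_latent: int = 20,
    noise_sd=1.0,
    nonlinearity_tag: str = "none",
    seed: int = 0,
    area: str = "VISp",
    shared_signal: bool = True,
) -> tuple[list[PopulationRecording], GroundTruth]:
    """Simulate a multi-animal cohort with a shared latent signal.

    Each animal ``p`` has true responses ``t_p = g(latent @ W_p)`` where
    ``latent`` is ``(n_stimuli, n_latent)`` standard normal, ``W_p`` has
    i.i.d. ``N(0, 1/n_latent)`` entries (so units have unit signal variance
    in expectation), and ``g`` is the optional pointwise nonlinearity.
    Observed trials are ``t_p + eps`` with ``eps ~ N(0, noise_sd_u^2)``.

    ``noise_sd`` may be a scalar, a ``(low, high)`` tuple (per-unit uniform
    draw — a heteroscedastic population), or a length-``n_units`` vector.
    With ``shared_signal=False`` every animal gets an independent latent,
    which is the null condition for inter-animal consistency.

    One master ``seed`` drives everything; per-animal substreams are spawned
    deterministically, so output is bit-reproducible.
    """
    for name, v in [("n_animals", n_animals), ("n_units", n_units),
                    ("n_stimuli", n_stimuli), ("n_latent", n_latent)]:
        if int(v) < 1:
            raise ValueError(f"{name} must be >= 1")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")

    master = np.random.SeedSequence(seed)
    latent_ss, *animal_ss = master.spawn(1 + n_animals)
    latent_rng = np.random.default_rng(latent_ss)
    latent = latent_rng.standard_normal((n_stimuli, n_latent))

    recordings: list[PopulationRecording] = []
    mixings, trues, sds = [], [], []
    for p, ss in enumerate(animal_ss):
        rng = np.random.default_rng(ss)
        if not shared_signal:
            latent_p = rng.standard_normal((n_stimuli, n_latent))
        else:
            latent_p = latent
        mixing = rng.normal(scale=1.0 / np.sqrt(n_latent),
                            size=(n_latent, n_units))
        true = apply_nonlinearity(latent_p @ mixing, nonlinearity_tag)
        sd = _per_unit_noise_sd(noise_sd, n_units, rng)
        noise = rng.standard_normal((n_stimuli, n_trials, n_units)) * sd
        responses = true[:, None, :] + noise
        recordings.append(PopulationRecording(
            responses=responses, animal_id=f"animal_{p:02d}", area=area))
        mixings.append(mixing)
        trues.append(true)
        sds.append(sd)

    gt = GroundTruth(latent=latent, mixing_per_animal=mixings,
                     true_responses=trues, noise_sd=sds,
                     nonlinearity_tag=nonlinearity_tag)
    return recordings, gt


def analytic_split_half_consistency(
    signal_var: float, noise_var: float, n_trials: int
) -> float:
    """Expected split-half correlation under the Gaussian trial-noise model.

    Splitting ``n_trials`` into two disjoint halves of ``n_trials // 2``
    trials each and averaging, the correlation across stimuli between the
    two half-averages is ``v / (v + w / (n_trials // 2))`` with signal
    variance ``v`` and trial-noise variance ``w``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if signal_var <= 0:
        raise ValueError("signal_var must be positive")
    if noise_var < 0:
        raise ValueError("noise_var must be nonnegative")
    n_half = n_trials // 2
    return float(signal_var / (signal_var + noise_var / n_half))


def noise_var_for_consistency(target: float, n_trials: int,
                              signal_var: float = 1.0) -> float:
    """Invert :func:`analytic_split_half_consistency` for the noise variance."""
    if not 0 < target <= 1:
        raise ValueError("target consistency must be in (0, 1]")
    n_half = n_trials // 2
    return float(signal_var * (1.0 - target) / target * n_half)


def generate_timebinned_recording(
    reliability_profile: Sequence[float],
    n_bins: int,
    n_units: int = 30,
    n_stimuli: int = 118,
    n_trials: int = 50,
    bin_ms: int = 10,
    max_ms: int = 250,
    seed: int = 0,
    animal_id: str = "animal_00",
    area: str = "VISp",
) -> PopulationRecording:
    """Recording with a time-bin axis whose per-bin reliability is planted.

    ``reliability_profile`` gives the target expected split-half consistency
    of each bin (population-wide). Bins with a nonpositive target carry pure
    noise. Used to test temporal-window selection.
    """
    profile = np.asarray(reliability_profile, dtype=float)
    if profile.shape != (n_bins,):
        raise ValueError("reliability_profile length must equal n_bins")
    if n_bins * bin_ms > max_ms:
        raise ValueError(f"n_bins * bin_ms exceeds {max_ms} ms window")

    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master)
    signal = rng.standard_normal((n_stimuli, 1, n_units, 1))
    responses = np.empty((n_stimuli, n_trials, n_units, n_bins))
    for b, target in enumerate(profile):
        if target <= 0:
            responses[..., b] = rng.standard_normal(
                (n_stimuli, n_trials, n_units))
            continue
        w = noise_var_for_consistency(min(target, 1.0 - 1e-12), n_trials)
        noise = rng.standard_normal((n_stimuli, n_trials, n_units)) * np.sqrt(w)
        responses[..., b] = signal[..., 0] + noise
    return PopulationRecording(responses=responses, animal_id=animal_id,
                               area=area, time_bin_ms=bin_ms)


def generate_model_features(
    ground_truth: GroundTruth,
    layer_specs: Sequence[tuple[int, float]],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-layer feature matrices derived from the simulator latent.

    Each ``(n_features, corruption)`` spec produces a ``stimuli x features``
    matrix: at corruption 0 an invertible (full column rank) linear transform
    of the latent; at corruption 1 pure noise; in between a variance-
    preserving interpolation ``sqrt(1-c^2) * signal + c * noise``.
    """
    latent = ground_truth.latent
    n_stimuli, n_latent = latent.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    layers: dict[str, np.ndarray] = {}
    for i, (n_features, corruption) in enumerate(layer_specs):
        if not 0.0 <= corruption <= 1.0:
            raise ValueError("corruption level must be in [0, 1]")
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        transform = rng.standard_normal((n_latent, n_features))
        signal = latent @ transform / np.sqrt(n_latent)
        noise = rng.standard_normal((n_stimuli, n_features))
        c = float(corruption)
        layers[f"layer_{i}"] = np.sqrt(max(1.0 - c**2, 0.0)) * signal + c * noise
    return layers
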