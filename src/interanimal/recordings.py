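"""Core data containers for trial-structured population recordings.

A :class:`PopulationRecording` holds one animal's responses as a
``stimuli x trials x units`` array (optionally ``x time_bins`` when the
recording keeps a within-presentation time axis), together with the animal
and area identifiers needed to organise multi-animal analyses.
:class:`GroundTruth` is produced only by the synthetic cohort generator and
carries the noiseless responses and noise scales that make every estimator
in the package testable against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NONLINEARITY_TAGS = ("none", "rectify", "squash")


@dataclass
class PopulationRecording:
    """One animal's stimulus-evoked responses.

    Parameters
    ----------
    responses:
        ``(n_stimuli, n_trials, n_units)`` array, or
        ``(n_stimuli, n_trials, n_units, n_bins)`` when ``time_bin_ms`` is set.
    animal_id, area:
        Metadata identifying the specimen and visual area.
    time_bin_ms:
        Width of the time bins along the trailing axis, if present.
    stimulus_ids:
        Unique identifier per stimulus, aligned with axis 0.
    """

    responses: np.ndarray
    animal_id: str
    area: str = "VISp"
    time_bin_ms: int | None = None
    stimulus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        expected_ndim = 4 if self.time_bin_ms is not None else 3
        if self.responses.ndim != expected_ndim:
            raise ValueError(
                f"responses must be {expected_ndim}-D "
                f"(got shape {self.responses.shape})"
            )
        if self.time_bin_ms is not None and self.time_bin_ms <= 0:
            raise ValueError("time_bin_ms must be positive")
        if not self.stimulus_ids:
            self.stimulus_ids = [f"stim_{i:04d}" for i in range(self.n_stimuli)]
        if len(self.stimulus_ids) != self.n_stimuli:
            raise ValueError("stimulus_ids length must equal n_stimuli")
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus_ids must be unique")
        if self.n_stimuli < 2:
            raise ValueError("need at least 2 stimuli")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite values")

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    @property
    def n_units(self) -> int:
        return self.responses.shape[2]

    @property
    def n_bins(self) -> int | None:
        return self.responses.shape[3] if self.responses.ndim == 4 else None

    def trial_average(self) -> np.ndarray:
        """Mean over the trial axis."""
        return self.responses.mean(axis=1)

    def subset_units(self, unit_idx: np.ndarray) -> "PopulationRecording":
        return PopulationRecording(
            responses=self.responses[:, :, np.asarray(unit_idx)],
            animal_id=self.animal_id,
            area=self.area,
            time_bin_ms=self.time_bin_ms,
            stimulus_ids=list(self.stimulus_ids),
        )


@dataclass
class GroundTruth:
    """Simulator oracle: noiseless responses and the noise model behind them.

    ``true_responses[p]`` is ``latent @ mixing_per_animal[p]`` passed through
    the optional pointwise nonlinearity; each observed trial is that matrix
    plus i.i.d. Gaussian noise with per-unit standard deviation
    ``noise_sd[p]``.
    """

    latent: np.ndarray
    mixing_per_animal: list[np.ndarray]
    true_responses: list[np.ndarray]
    noise_sd: list[np.ndarray]
    nonlinearity_tag: str = "none"

    def __post_init__(self) -> None:
        if self.nonlinearity_tag not in NONLINEARITY_TAGS:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity_tag!r}")
        for sd in self.noise_sd:
            if np.any(np.asarray(sd) < 0):
                raise ValueError("noise_sd must be nonnegative")

    @property
    def n_animals(self) -> int:
        return len(self.true_responses)


def apply_nonlinearity(x: np.ndarray, tag: str) -> np.ndarray:
    if tag == "none":
        return x
    if tag == "rectify":
        return np.maximum(x, 0.0)
    if tag == "squash":
        return np.tanh(x)
    raise ValueError(f"unknown nonlinearity {tag!r}")
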