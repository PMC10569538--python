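"""HDF5 persistence for recordings, ground truth, features and results.

Container layout (schema version 1): one HDF5 group per animal holding a
``responses`` dataset (stimuli x trials x units, plus a trailing time-bin
axis when present), a ``stimulus_ids`` dataset and ``animal_id`` / ``area``
/ optional ``time_bin_ms`` attributes; an optional ``ground_truth`` group
mirrors the simulator oracle; root attributes carry ``schema_version`` and
``master_seed``. All stimulus indexing is 0-based. Numeric payloads round-
trip bitwise. Result tables go to CSV (per-unit) and JSON (summaries).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .consistency import ConsistencyResult
from .predictivity import ModelFeatureSet
from .recordings import GroundTruth, PopulationRecording

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "write_recordings",
    "read_recordings",
    "write_features",
    "read_features",
    "result_to_frame",
    "write_result",
]


class SchemaError(ValueError):
    """A container is missing a required dataset/attribute or has an
    unrecognised schema version."""


def write_recordings(
    path,
    recordings: list[PopulationRecording],
    ground_truth: GroundTruth | None = None,
    master_seed: int | None = None,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if master_seed is not None:
            f.attrs["master_seed"] = int(master_seed)
        for rec in recordings:
            g = f.create_group(rec.animal_id)
            g.create_dataset("responses", data=rec.responses)
            g.create_dataset(
                "stimulus_ids",
                data=np.array([s.encode() for s in rec.stimulus_ids]))
            g.attrs["animal_id"] = rec.animal_id
            g.attrs["area"] = rec.area
            if rec.time_bin_ms is not None:
                g.attrs["time_bin_ms"] = int(rec.time_bin_ms)
        if ground_truth is not None:
            gt = f.create_group("ground_truth")
            gt.attrs["nonlinearity_tag"] = ground_truth.nonlinearity_tag
            gt.create_dataset("latent", data=ground_truth.latent)
            for p in range(ground_truth.n_animals):
                sub = gt.create_group(f"animal_{p:02d}")
                sub.create_dataset("mixing",
                                   data=ground_truth.mixing_per_animal[p])
                sub.create_dataset("true_responses",
                                   data=ground_truth.true_responses[p])
                sub.create_dataset("noise_sd", data=ground_truth.noise_sd[p])


def _require(group, key: str, path_desc: str):
    if key not in group:
        raise SchemaError(f"missing {path_desc}/{key}")
    return group[key]


def read_recordings(path) -> tuple[list[PopulationRecording], GroundTruth | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    recordings: list[PopulationRecording] = []
    ground_truth = None
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SchemaError("missing root attribute schema_version")
        if int(version) != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version!r}")
        for name in sorted(f):
            if name == "ground_truth":
                continue
            g = f[name]
            responses = np.asarray(_require(g, "responses", name))
            ids = [s.decode() for s in _require(g, "stimulus_ids", name)[()]]
            if "animal_id" not in g.attrs:
                raise SchemaError(f"missing attribute {name}/animal_id")
            recordings.append(PopulationRecording(
                responses=responses,
                animal_id=str(g.attrs["animal_id"]),
                area=str(g.attrs.get("area", "VISp")),
                time_bin_ms=(int(g.attrs["time_bin_ms"])
                             if "time_bin_ms" in g.attrs else None),
                stimulus_ids=ids))
        if "ground_truth" in f:
            gt = f["ground_truth"]
            latent = np.asarray(_require(gt, "latent", "ground_truth"))
            animals = sorted(k for k in gt if k != "latent")
            ground_truth = GroundTruth(
                latent=latent,
                mixing_per_animal=[np.asarray(gt[a]["mixing"]) for a in animals],
                true_responses=[np.asarray(gt[a]["true_responses"])
                                for a in animals],
                noise_sd=[np.asarray(gt[a]["noise_sd"]) for a in animals],
                nonlinearity_tag=str(gt.attrs.get("nonlinearity_tag", "none")))
    return recordings, ground_truth


def write_features(path, features: ModelFeatureSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = features.provenance
        f.create_dataset(
            "stimulus_ids",
            data=np.array([s.encode() for s in features.stimulus_ids]))
        g = f.create_group("layers")
        for name, mat in features.layers.items():
            g.create_dataset(name, data=mat)


def read_features(path) -> ModelFeatureSet:
    with h5py.File(path, "r") as f:
        if "layers" not in f:
            raise SchemaError("missing group layers")
        ids = [s.decode() for s in _require(f, "stimulus_ids", "/")[()]]
        layers = {name: np.asarray(f["layers"][name]) for name in f["layers"]}
        provenance = str(f.attrs.get("provenance", "unknown"))
    return ModelFeatureSet(layers=layers, stimulus_ids=ids,
                           provenance=provenance)


def result_to_frame(result: ConsistencyResult, label: str = "") -> pd.DataFrame:
    """Per-unit results table (one row per target unit)."""
    n = len(result.per_unit_values)
    return pd.DataFrame({
        "label": [label] * n,
        "unit": np.arange(n),
        "value": result.per_unit_values,
        "kept": result.kept_mask,
        "n_excluded": result.n_excluded,
        "n_evaluations": [result.n_evaluations] * n,
    })


def write_result(csv_path, json_path, results: list[ConsistencyResult],
                 labels: list[str], summary_extra: dict | None = None) -> None:
    """Write the per-unit CSV and the summary JSON for a set of results."""
    frames = [result_to_frame(r, lab) for r, lab in zip(results, labels)]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    values = np.concatenate([r.kept_values for r in results])
    summary = {
        "median": float(np.median(values)) if values.size else None,
        "sem": (float(np.std(values, ddof=1) / np.sqrt(values.size))
                if values.size > 1 else 0.0),
        "n_units_kept": int(values.size),
        "n_units_total": int(sum(len(r.per_unit_values) for r in results)),
        "n_excluded_unit_evaluations": int(
            sum(int(r.n_excluded.sum()) for r in results)),
        "per_target": {
            lab: {"median": r.median, "sem": r.sem,
                  "n_kept": int(r.kept_mask.sum())}
            for r, lab in zip(results, labels) if r.kept_mask.any()
        },
    }
    if summary_extra:
        summary.update(summary_extra)
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
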