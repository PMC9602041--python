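"""Readers and writers: YAML experiment configs, spike rasters, membrane records.

Rasters are delimited text (``t_ms,neuron_id``, 0-based indices).  Membrane
records are a binary array container (``.npz`` holding the ms x neuron matrix
in mV) with a JSON sidecar describing shape, resolution, population split and
the damage mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .infoquant import OrdinalConfig
from .network import (
    DamageMask,
    DriveConfig,
    NetworkConfig,
    NeuronParams,
    SimulationResult,
    SpikeRaster,
    SynapseTable,
)
from .pipeline import ExperimentConfig, Seeds
from .plasticity import PlasticityParams

__all__ = [
    "config_from_yaml",
    "config_to_yaml",
    "write_raster_csv",
    "read_raster_csv",
    "write_membrane_record",
    "read_membrane_record",
    "write_weight_snapshot",
]


def _build_network(d: dict) -> NetworkConfig:
    d = dict(d)
    for key in ("exc_params", "inh_params"):
        if key in d:
            d[key] = NeuronParams(**d[key])
    if "delay_range_exc" in d:
        d["delay_range_exc"] = tuple(d["delay_range_exc"])
    return NetworkConfig(**d)


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    sub_builders = {
        "network": _build_network,
        "plasticity": lambda x: PlasticityParams(**x),
        "drive": lambda x: DriveConfig(**x),
        "ordinal": lambda x: OrdinalConfig(**x),
        "seeds": lambda x: Seeds(**x),
    }
    for key, build in sub_builders.items():
        if key in d:
            d[key] = build(d[key])
    for key in ("modes", "damage_levels", "bands", "sources"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    """Load a nested key/value experiment configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_yaml(cfg: ExperimentConfig, path: str | Path) -> None:
    data = asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    raster.to_dataframe().to_csv(path, index=False)


def read_raster_csv(path: str | Path, duration: int | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy(dtype=np.int64)
    n = df["neuron_id"].to_numpy(dtype=np.int64)
    if duration is None:
        duration = int(t.max()) + 1 if t.size else 0
    return SpikeRaster(times=t, neurons=n, duration=duration)


def write_membrane_record(result: SimulationResult, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.npz`` (v matrix, mV) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    npz_path = stem.with_suffix(".npz")
    meta_path = stem.with_suffix(".json")
    np.savez_compressed(npz_path, v_mv=result.v_mv)
    n_total = result.v_mv.shape[1]
    meta = {
        "shape": list(result.v_mv.shape),
        "dt_ms": 1.0,
        "units": "mV",
        "n_total": n_total,
        "damaged": result.damage.indices.tolist(),
        "n_spikes": int(len(result.raster)),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return npz_path, meta_path


def read_membrane_record(stem: str | Path) -> tuple[np.ndarray, dict]:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as data:
        v = data["v_mv"]
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return v, meta


def write_weight_snapshot(synapses: SynapseTable, path: str | Path) -> None:
    """Delimited-text (pre, post, w) snapshot of the connectome weights."""
    pd.DataFrame({"pre": synapses.pre, "post": synapses.post, "w": synapses.w}).to_csv(
        path, index=False, float_format="%.17g"
    )
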