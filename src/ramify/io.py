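"""File formats: volumes (multi-page TIFF, HDF5), seed lists (CSV), run
configurations (flat YAML), and run manifests (JSON)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .cones import ConeParameters
from .engine import Seed, SimulationConfig
from .environment import EnvironmentStack

__all__ = [
    "write_volume_tiff", "read_volume_tiff",
    "write_seeds_csv", "read_seeds_csv",
    "save_stack_hdf5", "load_stack_hdf5",
    "save_density_csv",
    "config_from_mapping", "load_config_yaml", "config_to_dict",
    "write_manifest",
]


def save_density_csv(density, path) -> None:
    """Dump an angular density (direction, solid angle, density) for
    debugging and visualization."""
    pd.DataFrame({
        "dx": density.directions[:, 0], "dy": density.directions[:, 1],
        "dz": density.directions[:, 2], "weight": density.weights,
        "density": density.density,
    }).to_csv(path, index=False)


def write_volume_tiff(volume: np.ndarray, path) -> None:
    """Write a 3D volume (indexed [x, y, z]) as a multi-page TIFF, one page
    per z-slice."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    tifffile.imwrite(str(path), np.ascontiguousarray(vol.transpose(2, 0, 1)))


def read_volume_tiff(path) -> np.ndarray:
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    return np.ascontiguousarray(pages.transpose(1, 2, 0)).astype(float)


def write_occupancy_tiff(stack: EnvironmentStack, path) -> None:
    tifffile.imwrite(str(path), np.ascontiguousarray(
        stack.occupancy.astype(np.int32).transpose(2, 0, 1)))


def _angles_from_direction(d: np.ndarray) -> tuple[float, float]:
    theta = float(np.arccos(np.clip(d[2], -1.0, 1.0)))
    phi = float(np.arctan2(d[1], d[0]))
    return phi, theta


def _direction_from_angles(phi: float, theta: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def write_seeds_csv(seeds: list[Seed], path) -> None:
    rows = []
    for s in seeds:
        phi, theta = _angles_from_direction(s.direction)
        rows.append({"x": s.position[0], "y": s.position[1],
                     "z": s.position[2], "phi": phi, "theta": theta,
                     "cell": -1 if s.cell is None else s.cell})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_seeds_csv(path) -> list[Seed]:
    df = pd.read_csv(path)
    seeds = []
    for _, row in df.iterrows():
        cell = int(row.get("cell", -1))
        seeds.append(Seed(
            position=np.array([row["x"], row["y"], row["z"]]),
            direction=_direction_from_angles(row["phi"], row["theta"]),
            cell=None if cell < 0 else cell))
    return seeds


def save_stack_hdf5(stack: EnvironmentStack, path) -> None:
    """Write channels, derived fields and occupancy as HDF5 groups."""
    with h5py.File(path, "w") as fh:
        ch = fh.create_group("channels")
        for name, vol in stack.channels.items():
            ch.create_dataset(name, data=vol)
        gr = fh.create_group("gradients")
        for name in stack.channels:
            gr.create_dataset(name, data=stack.gradient(name))
        tn = fh.create_group("tensors")
        for name in stack.structural:
            tn.create_dataset(name, data=stack.structure_tensor(name))
        fh.create_dataset("occupancy", data=stack.occupancy)
        fh.attrs["structural"] = list(stack.structural)
        fh.attrs["sigma_grad"] = stack.sigma_grad
        fh.attrs["sigma_window"] = stack.sigma_window


def load_stack_hdf5(path) -> EnvironmentStack:
    with h5py.File(path, "r") as fh:
        channels = {name: ds[...] for name, ds in fh["channels"].items()}
        stack = EnvironmentStack(
            channels, structural=tuple(fh.attrs.get("structural", ())),
            sigma_grad=float(fh.attrs.get("sigma_grad", 1.0)),
            sigma_window=float(fh.attrs.get("sigma_window", 2.0)))
        stack.occupancy = fh["occupancy"][...].astype(np.int32)
    return stack


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONE_FIELDS = {f.name for f in dataclasses.fields(ConeParameters)}
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"cone"}


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat key-value mapping;
    cone-level and engine-level keys may be mixed freely. Unknown keys raise
    a ``ValueError`` naming the offending key."""
    cone_kwargs, config_kwargs = {}, {}
    for key, value in mapping.items():
        if key in _CONE_FIELDS:
            cone_kwargs[key] = value
        elif key in _CONFIG_FIELDS:
            config_kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    if "drift_vector" in config_kwargs:
        config_kwargs["drift_vector"] = tuple(config_kwargs["drift_vector"])
    return SimulationConfig(cone=ConeParameters(**cone_kwargs), **config_kwargs)


def load_config_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValueError("configuration file must hold a flat mapping")
    return config_from_mapping(mapping)


def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    cone = out.pop("cone")
    out.update(cone)
    out["drift_vector"] = list(out["drift_vector"])
    return out


def write_manifest(path, config: SimulationConfig, outputs: list,
                   event_counts: dict | None = None,
                   extra: dict | None = None) -> dict:
    """Write the run manifest: config snapshot + hash, seed, package version,
    per-update event counts, output inventory. Sufficient (together with the
    inputs it names) to reproduce the run bit-exactly."""
    from . import __version__

    snapshot = config_to_dict(config)
    blob = json.dumps(snapshot, sort_keys=True).encode()
    manifest = {
        "artifact_version": __version__,
        "master_seed": config.master_seed,
        "config": snapshot,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "event_counts": dict(event_counts or {}),
        "outputs": [str(o) for o in outputs],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
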