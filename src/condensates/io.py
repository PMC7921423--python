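"""File formats: simulation configs, snapshot tables, track tables, TIFFs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .lattice import ASK3, OBSTACLE, LatticeConfig, LatticeState

__all__ = [
    "load_lattice_config",
    "save_lattice_config",
    "snapshots_to_frame",
    "export_snapshots",
    "read_track_table",
    "write_track_table",
    "read_image",
    "write_image",
    "write_run_manifest",
]

_KIND_NAMES = {ASK3: "ask3", OBSTACLE: "obstacle"}


def load_lattice_config(path: str | Path) -> LatticeConfig:
    """Read a LatticeConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(LatticeConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return LatticeConfig(**data)


def save_lattice_config(config: LatticeConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def snapshots_to_frame(snapshots: list[LatticeState]) -> pd.DataFrame:
    """Long-format trajectory table: step, molecule, kind, x, y.

    Coordinates are 0-based with x the column and y the row.
    """
    rows = []
    for snap in snapshots:
        for i, (x, y, kind) in enumerate(zip(snap.xs, snap.ys, snap.kinds)):
            rows.append((snap.step, i, _KIND_NAMES[kind], x, y))
    return pd.DataFrame(rows, columns=["step", "molecule", "kind", "x", "y"])


def export_snapshots(snapshots: list[LatticeState], path: str | Path) -> None:
    snapshots_to_frame(snapshots).to_csv(path, index=False)


def read_track_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    **read_csv_kwargs,
) -> pd.DataFrame:
    """Read a delimiter-separated track table.

    ``column_map`` renames exporter-specific headers onto the canonical
    ``track_id, frame, time_s, x, y, intensity`` (e.g. TrackMate's
    ``TRACK_ID, FRAME, POSITION_T, POSITION_X, POSITION_Y, MEAN_INTENSITY``).
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def write_track_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def write_run_manifest(path: str | Path, **entries) -> None:
    """Machine-readable record of a run (seed, config, versions, ...)."""
    import condensates

    payload = {
        "condensates_version": getattr(condensates, "__version__", "unknown"),
        "numpy_version": np.__version__,
        **entries,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
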