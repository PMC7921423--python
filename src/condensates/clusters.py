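"""Cluster detection and count/size statistics for lattice snapshots.

A *cluster* is a 4-connected component of squares occupied by ASK3 units
with at least ``min_size`` members (default 6), the in-silico proxy for a
condensate visible under confocal microscopy; smaller groups are treated as
sub-resolution and contribute to neither count nor mean size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lattice import LatticeState

__all__ = [
    "DEFAULT_MIN_CLUSTER_SIZE",
    "ClusterSummary",
    "label_components",
    "summarize",
    "summarize_state",
    "replicate_stats",
]

DEFAULT_MIN_CLUSTER_SIZE = 6

#: iteration steps per unit of simulation time t
STEPS_PER_TIME_UNIT = 100_000


@dataclass(frozen=True)
class ClusterSummary:
    """Per-snapshot cluster statistics under the >= min_size rule."""

    step: int
    n_clusters: int
    mean_size: float  # 0.0 (flagged by n_clusters == 0) when none qualify
    sizes: tuple[int, ...] = field(default=())
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE

    @property
    def time_t(self) -> float:
        """Simulation time in units of 1e5 steps."""
        return self.step / STEPS_PER_TIME_UNIT


def label_components(state: LatticeState) -> np.ndarray:
    """Label 4-connected components of ASK3-occupied squares.

    Returns an (height, width) int array; 0 is background, labels start at
    1. Obstacles never join a component.
    """
    labels, _ = ndimage.label(state.ask3_mask())
    return labels


def summarize(
    labels: np.ndarray, min_size: int = DEFAULT_MIN_CLUSTER_SIZE, step: int = 0
) -> ClusterSummary:
    """Count and mean size of components with >= min_size units."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    counts = np.bincount(labels.ravel())[1:]  # drop background
    sizes = counts[counts >= min_size]
    mean_size = float(sizes.mean()) if sizes.size else 0.0
    return ClusterSummary(
        step=step,
        n_clusters=int(sizes.size),
        mean_size=mean_size,
        sizes=tuple(int(s) for s in sorted(sizes, reverse=True)),
        min_size=min_size,
    )


def summarize_state(
    state: LatticeState, min_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> ClusterSummary:
    """Label and summarise a snapshot in one call (usable as a recorder)."""
    return summarize(label_components(state), min_size=min_size, step=state.step)


def replicate_stats(values) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n)) across replicates.

    A single replicate yields SEM 0 with a warning; empty input is an error.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("replicate_stats needs at least one replicate")
    if arr.size == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
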