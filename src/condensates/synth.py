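"""Synthetic-data generators with known ground truth.

Every pipeline in this package is exercised on data these generators
produce: FRAP track tables with a prescribed bleach depth, mobile fraction,
recovery time constant and acquisition quench; spot images with planted
condensates; and hand-specified lattice states for cluster statistics.
All generators are seed-deterministic and return their ground truth
alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frap import FrapParams
from .lattice import ASK3, OBSTACLE, LatticeState

__all__ = [
    "FrapGroundTruth",
    "SpotImageGroundTruth",
    "make_frap_tracks",
    "make_spot_image",
    "make_lattice_fixture",
]


@dataclass(frozen=True)
class FrapGroundTruth:
    """Parameters of the simulated FRAP acquisition.

    The expected relative intensity of a bleached condensate at time t
    after the bleach is ``(1 - d) + m * d * (1 - exp(-dt / tau))`` — bleach
    depth ``d``, mobile fraction ``m``, single-exponential recovery with
    time constant ``tau`` — all multiplied by the global acquisition quench
    ``exp(-quench_rate * t)``. Defaults mirror the assay: five Before
    frames, 100 After frames at ~2.1 s, a bleach rectangle holding more
    than ten condensates, and an ~80% intensity drop on bleaching.
    """

    n_bleached: int = 12
    n_nonbleached: int = 20
    bleach_depth: float = 0.8
    mobile_fraction: float = 0.5
    tau_s: float = 20.0
    quench_rate: float = 0.002  # 1/s
    noise_sd: float = 0.02  # relative-intensity units
    frame_interval_s: float = 2.1
    n_before_frames: int = 5
    n_after_frames: int = 100
    bleach_rect: tuple[float, float, float, float] = (20.0, 60.0, 20.0, 60.0)
    image_size: tuple[float, float] = (128.0, 128.0)
    jitter_sd: float = 0.3  # px, per-frame Brownian positional jitter
    base_intensity: tuple[float, float] = (500.0, 2000.0)  # per-track range

    def __post_init__(self) -> None:
        if not 0.0 < self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must lie in (0, 1)")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.n_bleached < 1 or self.n_nonbleached < 1:
            raise ValueError("need at least one track per group")

    def expected_frap_rate(self, dt_after_bleach: np.ndarray) -> np.ndarray:
        """Closed-form FRAP rate [%] the pipeline should recover
        (noise-free): 100 * m * (1 - exp(-dt / tau))."""
        dt = np.asarray(dt_after_bleach, dtype=float)
        return 100.0 * self.mobile_fraction * (1.0 - np.exp(-dt / self.tau_s))


def make_frap_tracks(
    truth: FrapGroundTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, FrapParams]:
    """Simulate a tracked FRAP acquisition for one cell.

    Bleached tracks start inside the bleach rectangle, non-bleached tracks
    outside; both jitter around their centre. Intensities follow the
    ground-truth closed form with the bleach applied at the first After
    frame's timestamp, a global quench factor, and additive Gaussian noise
    on the relative scale (scaled by each track's base intensity, so noise
    shrinks with the quench exactly like the signal).

    Returns the long-format track table and a matching
    :class:`~condensates.frap.FrapParams`.
    """
    nb, na = truth.n_before_frames, truth.n_after_frames
    n_frames = nb + na
    frames = np.arange(n_frames)
    times = frames * truth.frame_interval_s
    t_bleach = times[nb]  # bleach lands at the first After frame
    x0, x1, y0, y1 = truth.bleach_rect
    w, h = truth.image_size

    # expected relative trace per group
    dt = np.clip(times - t_bleach, 0.0, None)
    d, m = truth.bleach_depth, truth.mobile_fraction
    rel_bleached = np.where(
        frames < nb, 1.0, (1.0 - d) + m * d * (1.0 - np.exp(-dt / truth.tau_s))
    )
    rel_nonbleached = np.ones(n_frames)
    quench = np.exp(-truth.quench_rate * times)

    pad = 3.0  # keep centres away from the rectangle edge despite jitter
    rows = []
    tid = 0
    for group, n_tracks, rel in (
        ("b", truth.n_bleached, rel_bleached),
        ("n", truth.n_nonbleached, rel_nonbleached),
    ):
        for _ in range(n_tracks):
            if group == "b":
                cx = rng.uniform(x0 + pad, x1 - pad)
                cy = rng.uniform(y0 + pad, y1 - pad)
            else:
                while True:  # rejection-sample a centre outside the rectangle
                    cx, cy = rng.uniform(pad, w - pad), rng.uniform(pad, h - pad)
                    if not (x0 - pad <= cx <= x1 + pad and y0 - pad <= cy <= y1 + pad):
                        break
            base = rng.uniform(*truth.base_intensity)
            xs = cx + np.cumsum(rng.normal(0.0, truth.jitter_sd, n_frames))
            ys = cy + np.cumsum(rng.normal(0.0, truth.jitter_sd, n_frames))
            noise = rng.normal(0.0, truth.noise_sd, n_frames)
            intensity = base * quench * (rel + noise)
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "frame": frames,
                        "time_s": times,
                        "x": xs,
                        "y": ys,
                        "intensity": np.clip(intensity, 0.0, None),
                    }
                )
            )
            tid += 1
    table = pd.concat(rows, ignore_index=True)
    params = FrapParams(
        bleach_rect=truth.bleach_rect, n_before_frames=truth.n_before_frames
    )
    return table, params


@dataclass(frozen=True)
class SpotImageGroundTruth:
    """Layout of a synthetic single-channel fluorescence field.

    Gaussian spots of width ``spot_sigma`` and peak ``amplitude`` sit on a
    flat ``background`` with additive Gaussian noise. Spots keep
    ``min_separation`` between centres and ``margin`` from the image edge
    so they are individually resolvable at the stated amplitude.
    """

    shape: tuple[int, int] = (128, 128)
    n_spots: int = 7
    spot_sigma: float = 2.0
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    min_separation: float = 14.0
    margin: float = 10.0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


def make_spot_image(
    truth: SpotImageGroundTruth, rng: np.random.Generator, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a spot field, its cell mask, and the ground-truth record.

    ``mask`` defaults to the full frame; spot centres are drawn inside the
    mask with the separation/margin constraints. Returns
    ``(image float64, mask bool, record)`` where ``record`` carries the
    planted centres and count for test assertions.
    """
    h, w = truth.shape
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask")

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < truth.n_spots:
        cy = rng.uniform(truth.margin, h - truth.margin)
        cx = rng.uniform(truth.margin, w - truth.margin)
        attempts += 1
        if attempts > 1000 * max(truth.n_spots, 1):
            warnings.warn(
                "could not place all spots with the requested separation",
                stacklevel=2,
            )
            break
        if not mask[int(round(cy)), int(round(cx))]:
            continue
        if any(
            (cy - py) ** 2 + (cx - px) ** 2 < truth.min_separation**2
            for py, px in centers
        ):
            continue
        centers.append((cy, cx))

    yy, xx = np.mgrid[0:h, 0:w]
    image = np.full(truth.shape, truth.background, dtype=float)
    for cy, cx in centers:
        image += truth.amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * truth.spot_sigma**2)
        )
    image += rng.normal(0.0, truth.noise_sd, truth.shape)

    record = {
        **asdict(truth),
        # actually-placed layout (may fall short of the requested n_spots)
        "n_spots": len(centers),
        "centers": [(float(cy), float(cx)) for cy, cx in centers],
    }
    return image, mask, record


def make_lattice_fixture(
    width: int,
    height: int,
    ask3: list[tuple[int, int]] = (),
    obstacles: list[tuple[int, int]] = (),
) -> LatticeState:
    """Deterministic lattice state from explicit (x, y) placements.

    Overlapping placements raise; intended for hand-built cluster and
    move-classification fixtures.
    """
    placements = list(ask3) + list(obstacles)
    if len(set(placements)) != len(placements):
        raise ValueError("overlapping placements")
    xs = [x for x, _ in placements]
    ys = [y for _, y in placements]
    kinds = [ASK3] * len(list(ask3)) + [OBSTACLE] * len(list(obstacles))
    return LatticeState(width, height, xs, ys, kinds)
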