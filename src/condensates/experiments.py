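"""Drivers for the two in-silico experiments and the no-obstacle control.

* shrink sweep — simulate fixed molecule numbers on progressively smaller
  grids (mimicking cell shrinkage under hyperosmotic stress) and report
  final-step cluster count and mean size per grid, mean +- SEM across
  replicates;
* expansion reversal — equilibrate on a small grid, expand the grid with
  molecules in place, and follow the cluster statistics as the
  shrinkage-induced clusters dissolve;
* no-obstacle control — the shrink sweep with ``n_obstacles = 0``.

Full-scale presets (500 ASK3 units / 1500 obstacles, grids 50-120, 5e6
steps, 18 replicates; expansion 55->120 over 35e6 steps, 12 replicates)
are provided but long-running; desk-scale presets keep the same molecule
numbers and grid ratios at reduced step counts and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clusters import (
    DEFAULT_MIN_CLUSTER_SIZE,
    ClusterSummary,
    replicate_stats,
    summarize_state,
)
from .lattice import KmcRandom, LatticeConfig, RateModel, expand_grid, initialize, run

__all__ = [
    "ExperimentProtocol",
    "full_shrink_protocol",
    "desk_shrink_protocol",
    "full_expansion_protocol",
    "desk_expansion_protocol",
    "run_shrink_sweep",
    "run_expansion",
    "run_no_obstacle_control",
]


@dataclass(frozen=True)
class ExperimentProtocol:
    """A full experiment specification.

    Replicate ``r`` on the ``g``-th grid draws its random stream from
    ``(seed, g, r)``, so every replicate is independently reproducible.
    """

    kind: str  # shrink_sweep | expansion | custom
    grid_sizes: tuple[tuple[int, int], ...]
    n_steps_phase1: int
    n_steps_phase2: int = 0  # expansion only
    n_replicates: int = 3
    record_every: int = 100_000
    base: LatticeConfig = field(default_factory=LatticeConfig)
    seed: int = 0
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_steps_phase1 < 0 or self.n_steps_phase2 < 0:
            raise ValueError("step counts must be >= 0")
        if not self.grid_sizes:
            raise ValueError("at least one grid size required")

    def replicate_seed(self, grid_index: int, replicate: int) -> int:
        ss = np.random.SeedSequence([self.seed, grid_index, replicate])
        return int(ss.generate_state(1)[0] % (2**31))

    def config_for(self, width: int, height: int) -> LatticeConfig:
        return replace(self.base, width=width, height=height)


def full_shrink_protocol(seed: int = 0, **overrides) -> ExperimentProtocol:
    """The full-scale sweep: grids 50-120, 5e6 steps, 18 replicates."""
    kw = dict(
        kind="shrink_sweep",
        grid_sizes=tuple((g, g) for g in (50, 55, 60, 70, 85, 100, 120)),
        n_steps_phase1=5_000_000,
        n_replicates=18,
        seed=seed,
    )
    kw.update(overrides)
    return ExperimentProtocol(**kw)


def desk_shrink_protocol(seed: int = 0, **overrides) -> ExperimentProtocol:
    """Reduced sweep for interactive use: fewer replicates, and grids
    extended down to 45 (the near-jammed limit of 2000 molecules) so the
    crowding-induced downturn of cluster size is resolved with few runs."""
    kw = dict(
        kind="shrink_sweep",
        grid_sizes=((45, 45), (48, 48), (55, 55), (70, 70), (90, 90), (120, 120)),
        n_steps_phase1=5_000_000,
        n_replicates=6,
        seed=seed,
    )
    kw.update(overrides)
    return ExperimentProtocol(**kw)


def full_expansion_protocol(seed: int = 0, **overrides) -> ExperimentProtocol:
    """Full-scale reversal: 5e6 steps at 55x55, then 35e6 at 120x120,
    recorded every 1e5 steps (one time unit t), 12 replicates."""
    kw = dict(
        kind="expansion",
        grid_sizes=((55, 55), (120, 120)),
        n_steps_phase1=5_000_000,
        n_steps_phase2=35_000_000,
        n_replicates=12,
        record_every=100_000,
        seed=seed,
    )
    kw.update(overrides)
    return ExperimentProtocol(**kw)


def desk_expansion_protocol(seed: int = 0, **overrides) -> ExperimentProtocol:
    """Reduced reversal: same grids and phase-1 length, phase 2 shortened
    to 2e7 steps (dissolution is well underway by then), 6 replicates,
    recorded every 1e6 steps."""
    kw = dict(
        kind="expansion",
        grid_sizes=((55, 55), (120, 120)),
        n_steps_phase1=5_000_000,
        n_steps_phase2=20_000_000,
        n_replicates=6,
        record_every=1_000_000,
        seed=seed,
    )
    kw.update(overrides)
    return ExperimentProtocol(**kw)


def _final_summary(
    protocol: ExperimentProtocol, width: int, height: int, replicate: int, grid_index: int
) -> ClusterSummary:
    config = protocol.config_for(width, height)
    rng = KmcRandom(protocol.replicate_seed(grid_index, replicate))
    state = initialize(config, rng)
    run(
        state,
        RateModel.from_config(config),
        protocol.n_steps_phase1,
        rng,
        record_every=max(protocol.n_steps_phase1, 1),
        recorder=lambda s: None,
    )
    return summarize_state(state, min_size=protocol.min_cluster_size)


def run_shrink_sweep(
    protocol: ExperimentProtocol,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sweep; returns (per-replicate table, per-grid summary).

    The summary holds mean +- SEM of final-step cluster count and mean
    cluster size per grid. Replicates where no cluster qualifies enter the
    size average as 0 (the statistic microscopy would report for a field
    with no visible condensate).
    """
    rows = []
    for gi, (w, h) in enumerate(protocol.grid_sizes):
        for rep in range(protocol.n_replicates):
            s = _final_summary(protocol, w, h, rep, gi)
            rows.append(
                {
                    "width": w,
                    "height": h,
                    "replicate": rep,
                    "step": s.step,
                    "n_clusters": s.n_clusters,
                    "mean_size": s.mean_size,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary_rows = []
    for (w, h), grp in per_rep.groupby(["width", "height"], sort=True):
        mc, sc = replicate_stats(grp["n_clusters"])
        ms, ss = replicate_stats(grp["mean_size"])
        summary_rows.append(
            {
                "width": w,
                "height": h,
                "mean_count": mc,
                "sem_count": sc,
                "mean_size": ms,
                "sem_size": ss,
                "n_replicates": len(grp),
            }
        )
    return per_rep, pd.DataFrame(summary_rows)


def run_expansion(protocol: ExperimentProtocol) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equilibrate on the small grid, expand, follow phase 2.

    Returns (per-replicate time series, per-time summary). The series
    starts at the expansion instant (phase-2 step 0) and is sampled every
    ``record_every`` steps; ``time_t`` is phase-2 steps per 1e5.
    """
    if len(protocol.grid_sizes) != 2:
        raise ValueError("expansion protocol needs exactly two grid sizes")
    (w1, h1), (w2, h2) = protocol.grid_sizes
    if w2 < w1 or h2 < h1:
        raise ValueError("phase-2 grid must be at least as large as phase 1")

    rows = []
    for rep in range(protocol.n_replicates):
        config = protocol.config_for(w1, h1)
        rng = KmcRandom(protocol.replicate_seed(0, rep))
        state = initialize(config, rng)
        model = RateModel.from_config(config)
        run(
            state,
            model,
            protocol.n_steps_phase1,
            rng,
            record_every=max(protocol.n_steps_phase1, 1),
            recorder=lambda s: None,
        )
        state = expand_grid(state, w2, h2)
        expansion_step = state.step
        series = run(
            state,
            model,
            protocol.n_steps_phase2,
            rng,
            record_every=protocol.record_every,
            recorder=lambda s: summarize_state(s, protocol.min_cluster_size),
        )
        for summ in series:
            phase2_step = summ.step - expansion_step
            rows.append(
                {
                    "replicate": rep,
                    "phase2_step": phase2_step,
                    "time_t": phase2_step / 1e5,
                    "n_clusters": summ.n_clusters,
                    "mean_size": summ.mean_size,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary_rows = []
    for t, grp in per_rep.groupby("phase2_step", sort=True):
        mc, sc = replicate_stats(grp["n_clusters"])
        ms, ss = replicate_stats(grp["mean_size"])
        summary_rows.append(
            {
                "phase2_step": t,
                "time_t": t / 1e5,
                "mean_count": mc,
                "sem_count": sc,
                "mean_size": ms,
                "sem_size": ss,
            }
        )
    return per_rep, pd.DataFrame(summary_rows)


def run_no_obstacle_control(
    protocol: ExperimentProtocol,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The shrink sweep without macromolecular crowding."""
    protocol = replace(protocol, base=replace(protocol.base, n_obstacles=0))
    return run_shrink_sweep(protocol)
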