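"""FRAP-rate quantification for fast-moving condensates from
particle-tracking tables.

Condensates move too quickly for a classic single-spot FRAP readout, so the
assay bleaches a rectangle containing many condensates and quantifies
recovery from tracked spots (one row per track-point). The pipeline:

1.  discard tracks not observed in both the pre-bleach ("Before") and
    post-bleach ("After") phases, or present in fewer than
    ``min_track_frames`` frames;
2.  split retained tracks into bleached / non-bleached by whether their
    mean pre-bleach position falls inside the bleach rectangle;
3.  normalise each track to its own pre-bleach mean, F_i(t)/F_i,Before;
4.  drop bleached tracks that did not actually lose >= 15% intensity
    (detector false positives inside the rectangle);
5.  correct acquisition photobleaching (quench) by dividing each bleached
    trace by the per-time mean of the non-bleached group, giving G_i(t);
6.  average bleached traces into one virtual condensate G(t), anchor the
    scale at G_Min (the minimum of the first three post-bleach time points)
    and report FRAP rate(t) = (G(t) - G_Min)/(1 - G_Min) * 100 [%];
7.  when pooling cells, trim extreme outliers outside Q1 - 5*IQR /
    Q3 + 5*IQR.

Tables use the long format of common spot trackers (e.g. TrackMate
exports): columns ``track_id, frame, time_s, x, y, intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outliers import trim_extreme_values

__all__ = [
    "TRACK_COLUMNS",
    "FrapParams",
    "FrapResult",
    "filter_tracks",
    "classify_bleached",
    "relative_change",
    "drop_false_positives",
    "quench_correct",
    "frap_rate",
    "trim_outlier_cells",
    "run_frap_pipeline",
]

TRACK_COLUMNS = ("track_id", "frame", "time_s", "x", "y", "intensity")


@dataclass(frozen=True)
class FrapParams:
    """Acquisition geometry and filter settings for one cell.

    ``bleach_rect`` is (x_min, x_max, y_min, y_max) in pixels, closed on
    all bounds. The first ``n_before_frames`` frames are the pre-bleach
    phase; the bleach falls between them and the remaining (After) frames.
    """

    bleach_rect: tuple[float, float, float, float]
    n_before_frames: int = 5
    min_track_frames: int = 25
    false_positive_drop: float = 0.15  # required fractional intensity loss
    fp_window: int = 3  # After frames averaged for the false-positive test
    gmin_window: int = 3  # After time points searched for G_Min

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.bleach_rect
        if x1 < x0 or y1 < y0:
            raise ValueError(f"degenerate bleach rectangle {self.bleach_rect}")
        if self.n_before_frames < 1:
            raise ValueError("n_before_frames must be >= 1")
        if not 0.0 < self.false_positive_drop < 1.0:
            raise ValueError("false_positive_drop must lie in (0, 1)")


@dataclass
class FrapResult:
    """Per-cell output of the pipeline plus filter bookkeeping."""

    curve: pd.DataFrame  # columns: time_s, G, frap_rate (After time points)
    g_min: float
    groups: pd.DataFrame  # columns: track_id, group (bleached/nonbleached)
    g_tracks: pd.DataFrame  # long: track_id, time_s, G_i
    exclusions: pd.DataFrame  # columns: track_id, reason
    dropped_times: tuple[float, ...] = field(default=())

    @property
    def final_frap_rate(self) -> float:
        return float(self.curve["frap_rate"].iloc[-1])


def _require_table(table: pd.DataFrame) -> None:
    missing = set(TRACK_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"track table lacks columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty track table")


def filter_tracks(
    table: pd.DataFrame, params: FrapParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep tracks spanning Before to After with enough frames.

    Returns the retained rows and an exclusion log with one row per dropped
    track (reasons: ``no_before``, ``no_after``, ``short``).
    """
    _require_table(table)
    nb = params.n_before_frames
    reasons = []
    keep_ids = []
    for tid, grp in table.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy()
        if not (frames < nb).any():
            reasons.append((tid, "no_before"))
        elif not (frames >= nb).any():
            reasons.append((tid, "no_after"))
        elif len(frames) < params.min_track_frames:
            reasons.append((tid, "short"))
        else:
            keep_ids.append(tid)
    log = pd.DataFrame(reasons, columns=["track_id", "reason"])
    return table[table["track_id"].isin(keep_ids)].copy(), log


def classify_bleached(track: pd.DataFrame, params: FrapParams) -> str:
    """Bleached iff the mean Before-phase (x, y) lies inside the rectangle
    (closed bounds)."""
    before = track[track["frame"] < params.n_before_frames]
    if len(before) == 0:
        raise ValueError("track has no Before frames")
    mx, my = before["x"].mean(), before["y"].mean()
    x0, x1, y0, y1 = params.bleach_rect
    inside = (x0 <= mx <= x1) and (y0 <= my <= y1)
    return "bleached" if inside else "nonbleached"


def relative_change(track: pd.DataFrame, params: FrapParams) -> pd.DataFrame:
    """Divide each intensity by the track's Before-phase mean F_i,Before."""
    before = track[track["frame"] < params.n_before_frames]
    f_before = before["intensity"].mean()
    if not len(before) or not f_before > 0:
        raise ValueError(f"non-positive Before mean ({f_before})")
    out = track.copy()
    out["rel"] = out["intensity"] / f_before
    return out


def drop_false_positives(
    rel_bleached: pd.DataFrame, params: FrapParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove bleached tracks whose intensity did not drop by at least the
    required fraction (default 15%) between Before and After.

    The drop is judged on the mean relative intensity over each track's
    first ``fp_window`` After frames, mirroring the G_Min search window.
    """
    nb = params.n_before_frames
    keep_ids, reasons = [], []
    for tid, grp in rel_bleached.groupby("track_id", sort=True):
        after = grp[grp["frame"] >= nb].nsmallest(params.fp_window, "frame")
        if after["rel"].mean() <= 1.0 - params.false_positive_drop:
            keep_ids.append(tid)
        else:
            reasons.append((tid, "false_positive"))
    log = pd.DataFrame(reasons, columns=["track_id", "reason"])
    return rel_bleached[rel_bleached["track_id"].isin(keep_ids)].copy(), log


def quench_correct(
    rel_bleached: pd.DataFrame, rel_nonbleached: pd.DataFrame
) -> tuple[pd.DataFrame, tuple[float, ...]]:
    """Divide each bleached trace by the non-bleached group mean per time.

    G_i(t) = (F_i(t)/F_i,Before) / mean_j(F_j(t)/F_j,Before), removing any
    per-time global factor (acquisition quench) exactly. Time points with
    no non-bleached coverage are dropped and reported.
    """
    if len(rel_nonbleached) == 0:
        raise ValueError("no non-bleached tracks to correct against")
    ref = rel_nonbleached.groupby("time_s")["rel"].mean()
    out = rel_bleached.copy()
    out["G"] = out["rel"] / out["time_s"].map(ref)
    dropped = tuple(sorted(set(out.loc[out["G"].isna(), "time_s"])))
    out = out.dropna(subset=["G"])
    return out, dropped


def frap_rate(
    g_tracks: pd.DataFrame, params: FrapParams
) -> tuple[pd.DataFrame, float]:
    """Average bleached G_i(t) into G(t) and rescale to FRAP rate [%].

    G_Min is the minimum of G(t) over the first ``gmin_window`` After time
    points; FRAP rate(t) = (G(t) - G_Min) / (1 - G_Min) * 100, so the curve
    is 0 at the G_Min time point and approaches 100 x mobile fraction.
    """
    after = g_tracks[g_tracks["frame"] >= params.n_before_frames]
    if len(after) == 0:
        raise ValueError("no After samples among bleached tracks")
    g = after.groupby("time_s")["G"].mean().sort_index()
    g_min = float(g.iloc[: params.gmin_window].min())
    if g_min >= 1.0:
        raise ValueError(
            f"G_Min = {g_min:.3f} >= 1: no detectable bleach, recovery undefined"
        )
    curve = pd.DataFrame(
        {
            "time_s": g.index.to_numpy(),
            "G": g.to_numpy(),
            "frap_rate": (g.to_numpy() - g_min) / (1.0 - g_min) * 100.0,
        }
    )
    return curve, g_min


def trim_outlier_cells(final_rates) -> np.ndarray:
    """Retention mask over per-cell summary FRAP rates (Q1/Q3 +- 5*IQR)."""
    return trim_extreme_values(final_rates)


def run_frap_pipeline(table: pd.DataFrame, params: FrapParams) -> FrapResult:
    """Full per-cell pipeline from a raw track table to the FRAP-rate curve."""
    retained, log = filter_tracks(table, params)
    if len(retained) == 0:
        raise ValueError("no tracks survive the Before/After and length filters")

    groups = []
    rel_parts = {"bleached": [], "nonbleached": []}
    for tid, grp in retained.groupby("track_id", sort=True):
        label = classify_bleached(grp, params)
        groups.append((tid, label))
        rel_parts[label].append(relative_change(grp, params))
    group_df = pd.DataFrame(groups, columns=["track_id", "group"])

    if not rel_parts["bleached"]:
        raise ValueError("no bleached tracks inside the bleach rectangle")
    rel_b = pd.concat(rel_parts["bleached"], ignore_index=True)
    if not rel_parts["nonbleached"]:
        raise ValueError("no non-bleached tracks for quench correction")
    rel_nb = pd.concat(rel_parts["nonbleached"], ignore_index=True)

    rel_b, fp_log = drop_false_positives(rel_b, params)
    if len(rel_b) == 0:
        raise ValueError("all bleached tracks flagged as false positives")
    g_tracks, dropped_times = quench_correct(rel_b, rel_nb)
    curve, g_min = frap_rate(g_tracks, params)

    return FrapResult(
        curve=curve,
        g_min=g_min,
        groups=group_df,
        g_tracks=g_tracks[["track_id", "frame", "time_s", "G"]],
        exclusions=pd.concat([log, fp_log], ignore_index=True),
        dropped_times=dropped_times,
    )
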