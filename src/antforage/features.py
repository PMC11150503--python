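"""Track-derived observables: binary node occupancy, activity, encounters,
transition points and per-phase per-capita occupancy.

Occupancy is the binary indicator I_i(t): node i holds at least one ant at
frame t.  The three foraging phases are bounded by TP1 (first food item
discovered) and TP2 (last food item collected): exploration [0, TP1),
exploitation [TP1, TP2), relaxation [TP2, end].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import HexArena

__all__ = [
    "OccupancyMatrix",
    "ActivitySeries",
    "PhaseBounds",
    "binarize_tracks",
    "activity_series",
    "interaction_series",
    "transition_points",
    "per_capita_occupancy",
]


@dataclass
class OccupancyMatrix:
    """frames x N binary matrix of node occupancies I_i(t)."""

    values: np.ndarray          # uint8, shape (T, N)
    frame_rate_hz: float
    node_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("occupancy must be a 2-D frames x nodes matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("occupancy entries must be binary")
        if len(self.node_ids) != self.values.shape[1]:
            raise ValueError("node_ids length must equal the number of columns")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def window(self, start_s: float, end_s: float) -> "OccupancyMatrix":
        f0 = int(np.floor(start_s * self.frame_rate_hz))
        f1 = int(np.ceil(end_s * self.frame_rate_hz))
        return OccupancyMatrix(self.values[max(f0, 0):f1], self.frame_rate_hz,
                               self.node_ids)

    # sparse long-form CSV: one row per occupied (frame, node) cell, with a
    # sidecar JSON carrying the dense shape
    def to_csv(self, path, sidecar_path=None) -> None:
        t, j = np.nonzero(self.values)
        pd.DataFrame({"frame": t, "node_id": np.asarray(self.node_ids)[j]}
                     ).to_csv(path, index=False)
        sidecar = {"n_frames": int(self.n_frames),
                   "frame_rate_hz": self.frame_rate_hz,
                   "node_ids": [int(n) for n in self.node_ids]}
        with open(sidecar_path or str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "OccupancyMatrix":
        with open(sidecar_path or str(path) + ".json") as fh:
            sidecar = json.load(fh)
        df = pd.read_csv(path)
        if not {"frame", "node_id"} <= set(df.columns):
            raise ValueError("occupancy CSV must have columns frame,node_id")
        node_ids = sidecar["node_ids"]
        col = {n: k for k, n in enumerate(node_ids)}
        values = np.zeros((sidecar["n_frames"], len(node_ids)), dtype=np.uint8)
        if len(df):
            values[df["frame"].to_numpy(),
                   df["node_id"].map(col).to_numpy()] = 1
        return cls(values, sidecar["frame_rate_hz"], node_ids)


@dataclass
class ActivitySeries:
    """Per-frame ant count, per-frame new encounters, cumulative encounters."""

    counts: np.ndarray
    encounters: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        if (self.counts < 0).any() or (self.encounters < 0).any():
            raise ValueError("activity counts must be non-negative")
        if (np.diff(self.cumulative) < 0).any():
            raise ValueError("cumulative encounters must be non-decreasing")


@dataclass(frozen=True)
class PhaseBounds:
    """TP1/TP2 in seconds (None when absent) and the trial duration."""

    TP1_s: float | None
    TP2_s: float | None
    duration_s: float

    def __post_init__(self) -> None:
        if self.TP1_s is not None and self.TP2_s is not None:
            if not 0 <= self.TP1_s <= self.TP2_s <= self.duration_s:
                raise ValueError("require 0 <= TP1 <= TP2 <= duration")

    def phase_of(self, time_s: float) -> str:
        if self.TP1_s is None or time_s < self.TP1_s:
            return "exploration"
        if self.TP2_s is None or time_s < self.TP2_s:
            return "exploitation"
        return "relaxation"


def _check_tracks(tracks: pd.DataFrame) -> None:
    if len(tracks) and tracks.duplicated(["frame", "ant_id"]).any():
        raise ValueError("an ant appears more than once in a single frame")


def binarize_tracks(
    tracks: pd.DataFrame,
    arena: HexArena,
    snap_radius_mm: float = 25.0,
    n_frames: int | None = None,
    frame_rate_hz: float = 2.0,
) -> OccupancyMatrix:
    """Snap detections to their nearest node (within ``snap_radius_mm``,
    otherwise dropped) and mark those nodes occupied."""
    if snap_radius_mm <= 0:
        raise ValueError("snap_radius_mm must be positive")
    _check_tracks(tracks)
    node_ids = list(arena.active_nodes)
    col = {n: k for k, n in enumerate(node_ids)}
    T = n_frames if n_frames is not None else (
        int(tracks["frame"].max()) + 1 if len(tracks) else 0)
    values = np.zeros((T, len(node_ids)), dtype=np.uint8)
    if len(tracks):
        xy = tracks[["x_mm", "y_mm"]].to_numpy(float)
        from scipy.spatial import cKDTree

        tree = cKDTree(arena.node_xy)
        dist, nearest = tree.query(xy)
        keep = dist <= snap_radius_mm
        frames = tracks["frame"].to_numpy()[keep].astype(np.intp)
        cols = np.array([col[n] for n in np.asarray(node_ids)[nearest[keep]]],
                        dtype=np.intp)
        if (frames >= T).any() or (frames < 0).any():
            raise ValueError("track frames outside [0, n_frames)")
        if len(frames):
            values[frames, cols] = 1
    return OccupancyMatrix(values, frame_rate_hz, node_ids)


def activity_series(tracks: pd.DataFrame, n_frames: int | None = None) -> ActivitySeries:
    """Number of distinct ants present in the arena at each frame."""
    _check_tracks(tracks)
    T = n_frames if n_frames is not None else (
        int(tracks["frame"].max()) + 1 if len(tracks) else 0)
    counts = np.zeros(T, dtype=np.int64)
    if len(tracks):
        per_frame = tracks.groupby("frame")["ant_id"].nunique()
        counts[per_frame.index.to_numpy()] = per_frame.to_numpy()
    zero = np.zeros(T, dtype=np.int64)
    return ActivitySeries(counts, zero, zero.copy())


def interaction_series(
    tracks: pd.DataFrame, body_length_mm: float = 10.0, n_frames: int | None = None
) -> ActivitySeries:
    """Ant-ant encounters: each unordered pair closer than a body length in a
    frame counts as one encounter; cumulative sum over frames."""
    if body_length_mm <= 0:
        raise ValueError("body_length_mm must be positive")
    _check_tracks(tracks)
    T = n_frames if n_frames is not None else (
        int(tracks["frame"].max()) + 1 if len(tracks) else 0)
    counts = np.zeros(T, dtype=np.int64)
    enc = np.zeros(T, dtype=np.int64)
    from scipy.spatial import cKDTree

    for frame, grp in tracks.groupby("frame"):
        counts[frame] = grp["ant_id"].nunique()
        if len(grp) > 1:
            pts = grp[["x_mm", "y_mm"]].to_numpy(float)
            pairs = cKDTree(pts).query_pairs(body_length_mm, output_type="ndarray")
            # strict inequality: pairs exactly at a body length do not count
            if len(pairs):
                d = np.hypot(*(pts[pairs[:, 0]] - pts[pairs[:, 1]]).T)
                enc[frame] = int((d < body_length_mm).sum())
    return ActivitySeries(counts, enc, np.cumsum(enc))


def transition_points(events: pd.DataFrame, duration_s: float) -> PhaseBounds:
    """TP1 = time of the first ``food_found``; TP2 = time of the last
    ``food_collected``; both absent for no-food trials."""
    if len(events) and (np.diff(events["time_s"].to_numpy()) < 0).any():
        raise ValueError("event log must be time-ordered")
    found = events.loc[events["kind"] == "food_found", "time_s"]
    coll = events.loc[events["kind"] == "food_collected", "time_s"]
    if len(coll) and (not len(found) or coll.min() < found.min()):
        raise ValueError("food_collected precedes any food_found: inconsistent log")
    tp1 = float(found.min()) if len(found) else None
    tp2 = float(coll.max()) if len(coll) else None
    if tp1 is not None and tp2 is None:
        tp2 = duration_s  # found but never delivered: exploitation runs out the trial
    return PhaseBounds(tp1, tp2, duration_s)


def per_capita_occupancy(
    occupancy: OccupancyMatrix,
    activity: ActivitySeries,
    phases: PhaseBounds,
) -> dict[str, float | None]:
    """Mean over each phase of (#occupied nodes / #ants present); frames with
    zero ants are excluded, and a phase with no populated frame gets None."""
    if occupancy.n_frames != len(activity.counts):
        raise ValueError("occupancy and activity frame axes differ")
    occ = occupancy.values.sum(axis=1).astype(float)
    ants = activity.counts.astype(float)
    t = np.arange(occupancy.n_frames) / occupancy.frame_rate_hz
    out: dict[str, float | None] = {}
    for phase in ("exploration", "exploitation", "relaxation"):
        in_phase = np.array([phases.phase_of(ti) == phase for ti in t])
        ok = in_phase & (ants > 0)
        out[phase] = float(np.mean(occ[ok] / ants[ok])) if ok.any() else None
    return out
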