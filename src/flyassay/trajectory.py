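"""Trajectory-derived behavioural metrics.

Implements the tracked-fly metrics with their exact binning, threshold and
exclusion rules: the activity index (fraction of 0.5 s bins with >= 1 mm of
movement), per-epoch foraging metrics in the microfluidic SNAC arena (alcove
entries, latency to feed, path efficiency, distance travelled), and the
200 mm / 10% per-epoch exclusion rule.

Coordinates are continuous millimetres in an origin-at-corner arena frame.
All time windows are half-open [start, end); a step from sample i to i+1 is
attributed to the window containing t_i, which makes windowed distances
additive over adjacent windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .errors import GeometryError, InsufficientDataError, MalformedTrajectoryError

__all__ = [
    "Trajectory",
    "SnacSession",
    "SnacMetrics",
    "EpochRecord",
    "ExclusionDecision",
    "activity_index",
    "distance_travelled",
    "exclusion_filter",
    "snac_metrics",
    "epoch_metrics_table",
]


@dataclass
class Trajectory:
    """Time-stamped 2-D positions of one fly in the arena frame (mm, s)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise MalformedTrajectoryError("t, x, y must have equal length")
        if self.t.size < 1:
            raise MalformedTrajectoryError("trajectory needs at least one sample")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise MalformedTrajectoryError("trajectory contains non-finite values")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise MalformedTrajectoryError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "x_mm": self.x, "y_mm": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arena_id: str = "") -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["x_mm"].to_numpy(), df["y_mm"].to_numpy(), arena_id)


@dataclass
class SnacSession:
    """A SNAC foraging session: trajectory, epoch schedule, alcove geometry.

    ``epochs`` holds (start, food_on, food_off) triples in seconds; food is
    presented from food_on until the first confirmed alcove entry or the
    100 s timeout, whichever is earlier.  ``direct_distance`` is the
    straight-line distance from the fly's position at food onset to the
    alcove, one value per epoch.
    """

    trajectory: Trajectory
    epochs: list[tuple[float, float, float]]
    alcove: Polygon
    arena: Polygon | None = None
    direct_distance: list[float] = field(default_factory=list)
    fly_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.alcove, Polygon):
            self.alcove = Polygon(self.alcove)
        if self.alcove.area <= 0:
            raise GeometryError("alcove polygon is degenerate")
        if self.arena is not None:
            if not isinstance(self.arena, Polygon):
                self.arena = Polygon(self.arena)
            if not self.arena.buffer(1e-9).contains(self.alcove):
                raise GeometryError("alcove polygon lies outside the arena")
        prev_off = -np.inf
        for start, on, off in self.epochs:
            if not (start <= on <= off):
                raise GeometryError("epoch times must satisfy start <= food_on <= food_off")
            if start < prev_off:
                raise GeometryError("epochs must be ordered and non-overlapping")
            prev_off = off
        if not self.direct_distance:
            self.direct_distance = [
                self._distance_to_alcove(on) for (_, on, _) in self.epochs
            ]

    def _distance_to_alcove(self, at_time: float) -> float:
        i = int(np.searchsorted(self.trajectory.t, at_time, side="left"))
        i = min(max(i, 0), len(self.trajectory) - 1)
        return float(self.alcove.distance(Point(self.trajectory.x[i], self.trajectory.y[i])))

    # JSON round-trip: arena/alcove polygons, epoch schedule, trajectory file reference
    def to_json(self, path: str | Path, trajectory_file: str) -> None:
        doc = {
            "fly_id": self.fly_id,
            "arena": list(map(list, self.arena.exterior.coords)) if self.arena else None,
            "alcove": list(map(list, self.alcove.exterior.coords)),
            "epochs": [
                {"start": s, "food_on": on, "food_off": off} for s, on, off in self.epochs
            ],
            "direct_distance_mm": self.direct_distance,
            "trajectory_file": trajectory_file,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SnacSession":
        doc = json.loads(Path(path).read_text())
        traj = Trajectory.from_csv(Path(path).parent / doc["trajectory_file"])
        return cls(
            trajectory=traj,
            epochs=[(e["start"], e["food_on"], e["food_off"]) for e in doc["epochs"]],
            alcove=Polygon(doc["alcove"]),
            arena=Polygon(doc["arena"]) if doc.get("arena") else None,
            direct_distance=list(doc.get("direct_distance_mm") or []),
            fly_id=doc.get("fly_id", ""),
        )


def activity_index(
    traj: Trajectory,
    bin_s: float = 0.5,
    move_threshold_mm: float = 1.0,
    mode: str = "path",
) -> float:
    """Fraction of complete time bins in which the fly moved at least 1 mm.

    Bins are aligned to the trajectory start and a trailing partial bin is
    discarded.  ``mode="path"`` (default) scores the summed within-bin path
    length; ``mode="net"`` scores net displacement across the bin.
    """
    if bin_s <= 0 or move_threshold_mm < 0:
        raise ValueError("bin_s must be positive and move_threshold_mm non-negative")
    if mode not in ("path", "net"):
        raise ValueError(f"unknown mobility mode {mode!r}")
    rel = traj.t - traj.t[0]
    n_bins = int(np.floor(rel[-1] / bin_s))
    if n_bins < 1:
        raise InsufficientDataError("trajectory shorter than one bin")
    which = np.floor(rel / bin_s).astype(int)
    mobile = 0
    for k in range(n_bins):
        mask = which == k
        if mode == "path":
            # steps starting inside the bin, including the one crossing out of it
            idx = np.nonzero(mask)[0]
            idx = idx[idx < len(traj) - 1]
            moved = float(np.hypot(traj.x[idx + 1] - traj.x[idx], traj.y[idx + 1] - traj.y[idx]).sum())
        else:
            idx = np.nonzero(mask)[0]
            lo, hi = idx[0], min(idx[-1] + 1, len(traj) - 1)
            moved = float(np.hypot(traj.x[hi] - traj.x[lo], traj.y[hi] - traj.y[lo]))
        if moved >= move_threshold_mm:
            mobile += 1
    return mobile / n_bins


def distance_travelled(traj: Trajectory, window: tuple[float, float] | None = None) -> float:
    """Summed Euclidean step length (mm) over a half-open time window.

    A step i -> i+1 belongs to the window containing t_i, so distances are
    additive over adjacent windows.
    """
    if len(traj) < 2:
        return 0.0
    if window is None:
        return float(traj.step_lengths().sum())
    start, end = window
    if end < start:
        raise ValueError("window end precedes start")
    t0 = traj.t[:-1]
    mask = (t0 >= start) & (t0 < end)
    return float(traj.step_lengths()[mask].sum())


@dataclass(frozen=True)
class ExclusionDecision:
    keep: bool
    reason: str | None = None


def exclusion_filter(
    distance_mm: float,
    activity: float,
    min_distance_mm: float = 200.0,
    min_activity: float = 0.10,
) -> ExclusionDecision:
    """Per-epoch exclusion: drop if distance < 200 mm or activity index < 10%."""
    if distance_mm < min_distance_mm:
        return ExclusionDecision(False, f"distance {distance_mm:g} mm < {min_distance_mm:g} mm")
    if activity < min_activity:
        return ExclusionDecision(False, f"activity index {activity:g} < {min_activity:g}")
    return ExclusionDecision(True, None)


@dataclass
class EpochRecord:
    """Per-epoch foraging outcome; latency and path metrics only for entries."""

    epoch: int
    entered: bool
    time_to_feed: float | None
    distance_mm: float | None
    path_efficiency: float | None
    censored: bool


@dataclass
class SnacMetrics:
    """Session-level foraging metrics aggregated over epochs."""

    entries: int
    n_epochs: int
    task_performance: float
    time_to_feed: list[float]
    path_efficiency: list[float]
    distance_travelled: list[float]
    records: list[EpochRecord]


def _first_entry(
    session: SnacSession, food_on: float, timeout_end: float, debounce: int = 2
) -> float | None:
    """Time of the first debounced alcove entry in [food_on, timeout_end), or None."""
    traj = session.trajectory
    mask = (traj.t >= food_on) & (traj.t < timeout_end)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return None
    # the candidate entry sample must fall in the food window; its debounce
    # confirmation samples may extend past the window end (food retracts at entry)
    ext = np.arange(idx[0], min(idx[-1] + debounce, len(traj)))
    # intersects == covers for points: boundary samples count as inside
    inside = shapely.intersects_xy(session.alcove, traj.x[ext], traj.y[ext])
    for i in idx:
        k = i - ext[0]
        if i + debounce - 1 < len(traj) and inside[k : k + debounce].all():
            return float(traj.t[i])
    return None


def snac_metrics(session: SnacSession, debounce: int = 2) -> SnacMetrics:
    """Foraging metrics for one SNAC session.

    An entry is the first sample inside the alcove polygon during the food
    window, debounced over two consecutive samples.  Epochs without an entry
    contribute a censored latency and no path metrics.  Path efficiency is
    direct distance over actual path length, capped at 1 for degenerate
    near-zero paths.
    """
    records: list[EpochRecord] = []
    latencies: list[float] = []
    efficiencies: list[float] = []
    distances: list[float] = []
    for k, (start, food_on, food_off) in enumerate(session.epochs):
        entry = _first_entry(session, food_on, food_off, debounce=debounce)
        if entry is None:
            records.append(EpochRecord(k, False, None, None, None, censored=True))
            continue
        latency = entry - food_on
        dist = distance_travelled(session.trajectory, (food_on, entry))
        direct = session.direct_distance[k] if k < len(session.direct_distance) else 0.0
        eff = min(1.0, direct / dist) if dist > 0 else 1.0
        records.append(EpochRecord(k, True, latency, dist, eff, censored=False))
        latencies.append(latency)
        efficiencies.append(eff)
        distances.append(dist)
    entries = sum(r.entered for r in records)
    n_epochs = len(session.epochs)
    return SnacMetrics(
        entries=entries,
        n_epochs=n_epochs,
        task_performance=entries / n_epochs if n_epochs else 0.0,
        time_to_feed=latencies,
        path_efficiency=efficiencies,
        distance_travelled=distances,
        records=records,
    )


def epoch_metrics_table(session: SnacSession, debounce: int = 2) -> pd.DataFrame:
    """Tidy per-fly per-epoch metric table with the keep/drop decision.

    Columns: fly_id, epoch, metric, value, kept, exclusion_reason.  The
    exclusion rule (distance < 200 mm or activity < 10%, measured over the
    food window) is applied per epoch.
    """
    metrics = snac_metrics(session, debounce=debounce)
    rows = []
    for rec, (start, food_on, food_off) in zip(metrics.records, session.epochs):
        window_dist = distance_travelled(session.trajectory, (food_on, food_off))
        mask = (session.trajectory.t >= food_on) & (session.trajectory.t < food_off)
        idx = np.nonzero(mask)[0]
        try:
            sub = Trajectory(
                session.trajectory.t[idx], session.trajectory.x[idx], session.trajectory.y[idx]
            )
            ai = activity_index(sub)
        except (MalformedTrajectoryError, InsufficientDataError):
            ai = 0.0
        decision = exclusion_filter(window_dist, ai)
        per_epoch = {
            "entered": float(rec.entered),
            "time_to_feed": rec.time_to_feed,
            "path_efficiency": rec.path_efficiency,
            "distance_travelled": rec.distance_mm,
            "activity": ai,
        }
        for metric, value in per_epoch.items():
            rows.append(
                {
                    "fly_id": session.fly_id,
                    "epoch": rec.epoch,
                    "metric": metric,
                    "value": value,
                    "kept": decision.keep,
                    "exclusion_reason": decision.reason,
                }
            )
    return pd.DataFrame(rows)
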