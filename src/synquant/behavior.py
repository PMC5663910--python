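"""Open-field trajectory metrics.

The motility of rats recovering from anesthesia is summarized from
timestamped barycenter tracks: pause events (the barycenter confined for
more than 10 s within a 2 cm-radius circle), entries into a central
rectangle of the cage (19 x 11 cm by default), path length and mean
speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "PauseEvent",
    "detect_pauses",
    "central_crossings",
    "motility_summary",
]


@dataclass
class Trajectory:
    times: np.ndarray        # s, strictly increasing
    positions: np.ndarray    # (n, 2) cm
    cage: tuple[float, float] = (38.0, 22.0)
    fps: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   cage: tuple[float, float] = (38.0, 22.0)) -> "Trajectory":
        """Build from a (t_s, x_cm, y_cm) table."""
        t = frame["t_s"].to_numpy(dtype=float)
        fps = 1.0 / np.median(np.diff(t)) if len(t) > 1 else None
        return cls(times=t,
                   positions=frame[["x_cm", "y_cm"]].to_numpy(dtype=float),
                   cage=cage, fps=fps)


@dataclass
class PauseEvent:
    start: float
    end: float
    anchor: tuple[float, float]

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_pauses(traj: Trajectory, radius: float = 2.0,
                  min_duration: float = 10.0,
                  anchor_mode: str = "first") -> list[PauseEvent]:
    """Maximal non-overlapping confinement intervals.

    A pause is an interval during which every position stays within
    ``radius`` cm of the interval's anchor and whose duration exceeds
    ``min_duration`` s.  The scan is greedy left-to-right: a candidate
    anchored at sample *i* is extended while positions remain confined;
    if long enough it is emitted and the scan resumes after it, otherwise
    the anchor advances one sample.

    ``anchor_mode='first'`` (default) anchors the circle at the first
    position of the candidate interval; ``'centroid'`` re-anchors at the
    running centroid, a more permissive alternative.
    """
    if radius <= 0 or min_duration <= 0:
        raise ValueError("radius and min_duration must be > 0")
    if anchor_mode not in ("first", "centroid"):
        raise ValueError("anchor_mode must be 'first' or 'centroid'")
    t, pos = traj.times, traj.positions
    n = len(t)
    if n == 0 or t[-1] - t[0] <= min_duration:
        return []
    events: list[PauseEvent] = []
    i = 0
    while i < n - 1:
        anchor = pos[i].copy()
        j = i + 1
        count = 1
        while j < n:
            if np.linalg.norm(pos[j] - anchor) > radius:
                break
            count += 1
            if anchor_mode == "centroid":
                anchor = anchor + (pos[j] - anchor) / count
            j += 1
        if t[j - 1] - t[i] > min_duration:
            events.append(PauseEvent(start=float(t[i]), end=float(t[j - 1]),
                                     anchor=(float(anchor[0]), float(anchor[1]))))
            i = j
        else:
            i += 1
    return events


def central_crossings(traj: Trajectory, area_w: float = 19.0,
                      area_h: float = 11.0) -> int:
    """Number of entries (outside -> inside transitions) into a rectangle
    of the given size centered in the cage."""
    w, h = traj.cage
    if area_w > w or area_h > h:
        raise ValueError("central area larger than cage")
    x0, x1 = (w - area_w) / 2, (w + area_w) / 2
    y0, y1 = (h - area_h) / 2, (h + area_h) / 2
    pos = traj.positions
    inside = ((pos[:, 0] >= x0) & (pos[:, 0] <= x1)
              & (pos[:, 1] >= y0) & (pos[:, 1] <= y1))
    if len(inside) == 0:
        return 0
    return int(np.sum(inside[1:] & ~inside[:-1]) + (1 if inside[0] else 0))


def motility_summary(traj: Trajectory, pauses: list[PauseEvent] | None = None,
                     area_w: float = 19.0, area_h: float = 11.0) -> dict:
    """Path length (cm), mean speed (cm/s), fraction of time paused and
    central-area crossing count for one session."""
    seg = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    path = float(seg.sum())
    duration = float(traj.times[-1] - traj.times[0]) if len(traj.times) > 1 else 0.0
    if pauses is None:
        pauses = detect_pauses(traj)
    paused = sum(p.duration for p in pauses)
    return {
        "path_length_cm": path,
        "mean_speed_cm_s": path / duration if duration > 0 else float("nan"),
        "time_paused_fraction": paused / duration if duration > 0 else float("nan"),
        "n_pauses": len(pauses),
        "central_crossings": central_crossings(traj, area_w, area_h),
    }
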