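"""Video-tracking tremor metric: center occupancy in a circular arena.

Wild-type flies wall-follow, tracing the arena periphery; tremoring mutants
move erratically and spend far more time near the center.  Tremor severity
is therefore scored as the fraction of analyzed frames the fly spends inside
a concentric disc whose radius is a fixed fraction (default 74.3%) of the
arena radius.  Only the last portion of the recording is analyzed (default:
last 5 min of a 10-min, 30 fps movie) so flies have settled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_stats

__all__ = [
    "Trajectory",
    "ChamberGeometry",
    "center_occupancy",
    "analysis_window",
    "path_length",
    "compare_tremor",
]

DEFAULT_FPS = 30.0
DEFAULT_INNER_RATIO = 0.743


@dataclass(frozen=True)
class Trajectory:
    """Frame-indexed x/y positions of a single fly."""

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fly_id: str = ""
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (frames.size == x.size == y.size):
            raise ValueError("frames, x, y must have equal length")
        if frames.size == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class ChamberGeometry:
    """Arena center/radius plus the inner-disc definition.

    The inner disc is ``inner_ratio * radius`` by default (scale-free, the
    quantity that transfers across camera setups).  ``inner_radius`` is an
    absolute override in the same units as the coordinates, for literal
    reproduction of a fixed-threshold analysis.
    """

    xc: float
    yc: float
    radius: float
    inner_ratio: float = DEFAULT_INNER_RATIO
    inner_radius: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 < self.inner_ratio < 1.0:
            raise ValueError("inner_ratio must lie in (0, 1)")
        if self.inner_radius is not None:
            if self.inner_radius <= 0:
                raise ValueError("inner_radius must be positive")
            if self.inner_radius >= self.radius:
                raise ValueError("inner_radius must be smaller than the arena radius")

    @property
    def effective_inner_radius(self) -> float:
        if self.inner_radius is not None:
            return self.inner_radius
        return self.inner_ratio * self.radius


def center_occupancy(traj: Trajectory, geom: ChamberGeometry) -> float:
    """Fraction of frames with (x-xc)^2 + (y-yc)^2 < r_in^2.

    The inequality is strict: a frame exactly on the circle counts as
    outside.  Frames missing from the trajectory (tracking dropouts) simply
    do not appear in either numerator or denominator.
    """
    r_in = geom.effective_inner_radius
    d2 = (traj.x - geom.xc) ** 2 + (traj.y - geom.yc) ** 2
    return float(np.mean(d2 < r_in * r_in))


def analysis_window(
    traj: Trajectory, *, total_s: float = 600.0, keep_last_s: float = 300.0
) -> Trajectory:
    """Restrict a trajectory to the final ``keep_last_s`` seconds of a
    ``total_s``-second recording, i.e. frames in
    ``[(total_s - keep_last_s) * fps, total_s * fps)``."""
    if keep_last_s <= 0 or keep_last_s > total_s:
        raise ValueError("need 0 < keep_last_s <= total_s")
    duration_s = (traj.frames[-1] + 1) / traj.fps
    if duration_s < keep_last_s:
        raise ValueError(
            f"recording of {duration_s:.1f}s is shorter than the {keep_last_s:.0f}s window"
        )
    start = int(round((total_s - keep_last_s) * traj.fps))
    stop = int(round(total_s * traj.fps))
    mask = (traj.frames >= start) & (traj.frames < stop)
    if not mask.any():
        raise ValueError("no frames fall inside the analysis window")
    return Trajectory(traj.frames[mask], traj.x[mask], traj.y[mask], traj.fly_id, traj.fps)


def path_length(traj: Trajectory) -> float:
    """Total traveled distance, in coordinate units."""
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


@dataclass(frozen=True)
class TremorReport:
    per_fly: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    kruskal: core_stats.KruskalWallisResult
    dunn: pd.DataFrame = field(repr=False, default=None)


def compare_tremor(
    occupancies: dict[str, np.ndarray],
    control: str,
    *,
    dunn_adjust: str = "bonferroni",
) -> TremorReport:
    """Compare per-fly center occupancies across genotypes
    (Kruskal-Wallis + Dunn vs control), with boxplot summaries
    (median and quartiles) per genotype."""
    if len(occupancies) < 2:
        raise ValueError("need at least 2 genotypes")
    rows = []
    for label, vals in occupancies.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"genotype {label!r} has no flies")
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"occupancies for {label!r} must lie in [0, 1]")
        for i, v in enumerate(vals):
            rows.append((label, i, v))
    per_fly = pd.DataFrame(rows, columns=["genotype", "fly", "occupancy"])
    summary = (
        per_fly.groupby("genotype")["occupancy"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75), n="count")
        .reset_index()
    )
    groups = {label: sub["occupancy"].to_numpy() for label, sub in per_fly.groupby("genotype")}
    kw = core_stats.kruskal_wallis(groups)
    dunn = core_stats.dunn_posthoc(groups, control, adjust=dunn_adjust)
    return TremorReport(per_fly=per_fly, summary=summary, kruskal=kw, dunn=dunn)
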