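"""Cleaning, visit segmentation and behavioral metrics for 3D flight tracks.

Tracks are sequences of (frame, x, y, z) points recorded at 50 frames/s in a
120 cm (x, lateral) x 200 cm (y, along the airflow, upwind positive) x 120 cm
(z, vertical) wind-tunnel arena, origin at the downwind floor-left corner.
The pipeline removes erroneous points (out-of-arena and isolated speed
spikes), linearly interpolates gaps of up to five missing frames (longer gaps
split the track), and smooths each axis with a cubic smoothing spline.
Cleaned tracks are segmented into visits - maximal runs of consecutive points
inside a target's cuboid region of interest - and per-visit duration, 3D path
length, tortuosity (path / entry-exit chord) and mean speed are computed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

__all__ = [
    "TrackParseError",
    "Track",
    "CleaningConfig",
    "Cuboid",
    "Visit",
    "TargetSummary",
    "ARENA_BOUNDS",
    "read_tracks",
    "write_tracks",
    "filter_outliers",
    "interpolate_gaps",
    "smooth_track",
    "clean_tracks",
    "build_cuboid",
    "no_target_cuboid",
    "segment_visits",
    "visit_metrics",
    "summarize_target",
    "heatmap_density",
]

#: arena extents in cm: ((xmin, xmax), (ymin, ymax), (zmin, zmax))
ARENA_BOUNDS = ((0.0, 120.0), (0.0, 200.0), (0.0, 120.0))

#: chords shorter than this make tortuosity ill-defined (reported as NaN)
MIN_CHORD_CM = 0.1


class TrackParseError(ValueError):
    """Malformed track table."""


@dataclass
class Track:
    """An ordered 3D point sequence with per-point provenance flags."""

    track_id: str
    frames: np.ndarray            # int, strictly increasing
    xyz: np.ndarray               # (n, 3) float, cm
    interpolated: np.ndarray      # bool, True where the point was filled in
    frame_rate_hz: float = 50.0
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.frames) == len(self.xyz) == len(self.interpolated)):
            raise ValueError("frames, xyz and flags must have equal length")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": self.track_id,
            "frame": self.frames,
            "x": self.xyz[:, 0], "y": self.xyz[:, 1], "z": self.xyz[:, 2],
            "status": np.where(self.interpolated, "interpolated", "observed"),
        })


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the track-cleaning pipeline.

    ``max_gap_frames``: longest run of missing frames that is interpolated
    (longer gaps split the track). ``outlier_speed_cms``: implied speed above
    which a point is an isolated spike if it holds toward both neighbors
    (~17x the mean flight speed by default). ``smoothing_parameter``: per-point
    smoothing-spline residual budget in cm^2 (0 = interpolating spline).
    """

    max_gap_frames: int = 5
    outlier_speed_cms: float = 400.0
    smoothing_parameter: float = 0.04
    arena_bounds: tuple = ARENA_BOUNDS

    def __post_init__(self) -> None:
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not self.outlier_speed_cms > 0:
            raise ValueError("outlier_speed_cms must be > 0")
        if self.smoothing_parameter < 0:
            raise ValueError("smoothing_parameter must be >= 0")


@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned region of interest around a target (buffer included).

    ``plane_y`` is set for vertical targets (the y coordinate of the target
    plane) and drives upwind/downwind labeling of visits.
    """

    label: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    z_range: tuple[float, float]
    orientation: str = "horizontal"
    plane_y: float | None = None

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Half-open membership test [min, max) on every axis."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        ok = np.ones(len(xyz), dtype=bool)
        for axis, (lo, hi) in enumerate((self.x_range, self.y_range, self.z_range)):
            ok &= (xyz[:, axis] >= lo) & (xyz[:, axis] < hi)
        return ok


@dataclass
class Visit:
    """A maximal contiguous in-cuboid track segment and its metrics."""

    track_id: str
    label: str
    entry_frame: int
    exit_frame: int
    frames: np.ndarray
    xyz: np.ndarray
    duration_s: float
    path_length_cm: float
    chord_cm: float
    tortuosity: float             # NaN when the chord is degenerate
    mean_speed_cms: float
    side: str | None = None       # upwind / downwind for vertical targets


@dataclass
class TargetSummary:
    """Per-target totals and means over visits, plus landing density."""

    label: str
    n_visits: int
    total_time_s: float
    total_distance_cm: float
    mean_tortuosity: float
    mean_speed_cms: float
    landings: int
    target_area_cm2: float
    landing_density_per_100cm2: float
    n_visits_upwind: int | None = None
    n_visits_downwind: int | None = None
    time_upwind_s: float | None = None
    time_downwind_s: float | None = None
    distance_upwind_cm: float | None = None
    distance_downwind_cm: float | None = None


# ---------------------------------------------------------------------------
# IO

_REQUIRED = ["track_id", "frame", "x", "y", "z"]


def read_tracks(source, frame_rate_hz: float = 50.0,
                sep: str | None = None) -> list[Track]:
    """Read tracks from a delimited text table with a header row.

    Requires columns track_id, frame, x, y, z. Malformed rows (non-numeric
    coordinates or frames) raise :class:`TrackParseError` naming the 1-based
    file line. Points are sorted by frame within each track.
    """
    df = pd.read_csv(source, sep=sep, engine="python", dtype=str,
                     skipinitialspace=True)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrackParseError(f"missing required column(s): {', '.join(missing)}")
    numeric = df[["frame", "x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:10]]  # +2: header is line 1
        raise TrackParseError(
            f"non-numeric value(s) on line(s) {', '.join(lines)}")
    df = df[["track_id"]].join(numeric)

    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.allclose(frames, np.round(frames)):
            raise TrackParseError(f"track {tid}: non-integer frame indices")
        frames = np.round(frames).astype(int)
        if len(np.unique(frames)) != len(frames):
            warnings.warn(f"track {tid}: duplicate frames dropped")
            _, keep = np.unique(frames, return_index=True)
            grp = grp.iloc[np.sort(keep)]
            frames = np.round(grp["frame"].to_numpy()).astype(int)
        tracks.append(Track(
            track_id=str(tid), frames=frames,
            xyz=grp[["x", "y", "z"]].to_numpy(),
            interpolated=np.zeros(len(grp), dtype=bool),
            frame_rate_hz=frame_rate_hz))
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks in the same CSV dialect :func:`read_tracks` accepts."""
    pd.concat([t.as_dataframe() for t in tracks],
              ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning

def _speeds_to_neighbors(track: Track) -> tuple[np.ndarray, np.ndarray]:
    dt = np.diff(track.frames) / track.frame_rate_hz
    step = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
    v = step / dt
    to_prev = np.concatenate(([np.inf], v))   # first point: no previous
    to_next = np.concatenate((v, [np.inf]))   # last point: no next
    return to_prev, to_next


def filter_outliers(track: Track, config: CleaningConfig = CleaningConfig()) -> Track:
    """Drop out-of-arena points and isolated speed spikes.

    A spike is a point whose implied speed to *both* surviving neighbors
    exceeds ``outlier_speed_cms`` (endpoints: to their only neighbor).
    Spike removal is iterated to a fixed point, which makes the operation
    idempotent. Removal creates frame gaps handled by
    :func:`interpolate_gaps`.
    """
    keep = np.ones(track.n_points, dtype=bool)
    for axis, (lo, hi) in enumerate(config.arena_bounds):
        keep &= (track.xyz[:, axis] >= lo) & (track.xyz[:, axis] <= hi)
    cur = _subset(track, keep)
    while cur.n_points >= 2:
        to_prev, to_next = _speeds_to_neighbors(cur)
        both = np.minimum(to_prev, to_next) > config.outlier_speed_cms
        if not both.any():
            break
        cur = _subset(cur, ~both)
    return cur


def _subset(track: Track, mask: np.ndarray) -> Track:
    return replace(track, frames=track.frames[mask], xyz=track.xyz[mask],
                   interpolated=track.interpolated[mask])


def interpolate_gaps(track: Track,
                     config: CleaningConfig = CleaningConfig()) -> list[Track]:
    """Fill short frame gaps linearly; split the track at long ones.

    Gaps of at most ``max_gap_frames`` missing frames are filled by per-axis
    linear interpolation and flagged interpolated; longer gaps split the
    track into separate tracks (ids suffixed ``.1``, ``.2``, ... when a split
    occurs).
    """
    if track.n_points == 0:
        return []
    gaps = np.diff(track.frames) - 1
    cut = np.flatnonzero(gaps > config.max_gap_frames)
    pieces = np.split(np.arange(track.n_points), cut + 1)
    out: list[Track] = []
    for pi, idx in enumerate(pieces):
        tid = track.track_id if len(pieces) == 1 else f"{track.track_id}.{pi + 1}"
        frames = track.frames[idx]
        full = np.arange(frames[0], frames[-1] + 1)
        xyz = np.column_stack([
            np.interp(full, frames, track.xyz[idx, a]) for a in range(3)])
        interp = ~np.isin(full, frames)
        flags = np.zeros(len(full), dtype=bool)
        flags[np.isin(full, frames)] = track.interpolated[idx]
        flags |= interp
        out.append(replace(track, track_id=tid, frames=full, xyz=xyz,
                           interpolated=flags))
    return out


def smooth_track(track: Track,
                 config: CleaningConfig = CleaningConfig()) -> Track:
    """Smooth each axis with a cubic smoothing spline evaluated at the
    original frames.

    The total residual budget is ``smoothing_parameter * n_points`` per axis
    (cm^2), so 0 reproduces the input exactly and straight-line tracks are
    invariant under any budget. Tracks of fewer than 4 points are returned
    unsmoothed with a warning.
    """
    if track.n_points < 4:
        warnings.warn(f"track {track.track_id}: too short to smooth "
                      f"({track.n_points} points)")
        return replace(track, smoothed=False)
    t = track.frames / track.frame_rate_hz
    s = config.smoothing_parameter * track.n_points
    xyz = np.column_stack([
        UnivariateSpline(t, track.xyz[:, a], k=3, s=s)(t) for a in range(3)])
    return replace(track, xyz=xyz, smoothed=True)


def clean_tracks(tracks: Sequence[Track],
                 config: CleaningConfig = CleaningConfig(),
                 smooth: bool = True) -> list[Track]:
    """Full cleaning pipeline: outlier filter, gap interpolation/splitting,
    optional spline smoothing."""
    out: list[Track] = []
    for track in tracks:
        for piece in interpolate_gaps(filter_outliers(track, config), config):
            if piece.n_points < 2:
                continue
            out.append(smooth_track(piece, config) if smooth else piece)
    return out


# ---------------------------------------------------------------------------
# Regions of interest and visits

def build_cuboid(footprint_x: tuple[float, float],
                 footprint_y: tuple[float, float],
                 orientation: str = "horizontal",
                 buffer_cm: float = 10.0,
                 label: str = "target",
                 arena_bounds: tuple = ARENA_BOUNDS) -> Cuboid:
    """Target cuboid: the XY footprint grown by ``buffer_cm`` per side, from
    the floor up to 30 cm (horizontal targets) or 60 cm (vertical targets).

    Extents falling outside the arena are clipped with a warning. Vertical
    cuboids record the target plane (footprint y mid-line) for
    upwind/downwind labeling.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation: {orientation!r}")
    height = 30.0 if orientation == "horizontal" else 60.0
    x = (footprint_x[0] - buffer_cm, footprint_x[1] + buffer_cm)
    y = (footprint_y[0] - buffer_cm, footprint_y[1] + buffer_cm)
    z = (0.0, height)
    (ax, ay, az) = arena_bounds
    clipped_x = (max(x[0], ax[0]), min(x[1], ax[1]))
    clipped_y = (max(y[0], ay[0]), min(y[1], ay[1]))
    clipped_z = (max(z[0], az[0]), min(z[1], az[1]))
    if (clipped_x, clipped_y, clipped_z) != (x, y, z):
        warnings.warn(f"cuboid {label!r} clipped to arena bounds")
    if clipped_x[0] >= clipped_x[1] or clipped_y[0] >= clipped_y[1]:
        raise ValueError(f"cuboid {label!r}: footprint outside arena")
    plane_y = (footprint_y[0] + footprint_y[1]) / 2 if orientation == "vertical" else None
    return Cuboid(label, clipped_x, clipped_y, clipped_z, orientation, plane_y)


def no_target_cuboid(width_cm: float = 30.0, length_cm: float = 40.0,
                     buffer_cm: float = 10.0,
                     arena_bounds: tuple = ARENA_BOUNDS,
                     label: str = "no-target") -> Cuboid:
    """Control cuboid with the dimensions of the large horizontal target,
    placed at the downwind end (low y), centered laterally."""
    (ax, _, _) = arena_bounds
    cx = (ax[0] + ax[1]) / 2
    fx = (cx - width_cm / 2, cx + width_cm / 2)
    fy = (buffer_cm + 10.0, buffer_cm + 10.0 + length_cm)
    return build_cuboid(fx, fy, "horizontal", buffer_cm, label, arena_bounds)


def segment_visits(track: Track, cuboid: Cuboid) -> list[Visit]:
    """Split a cleaned track into visits to one cuboid.

    A visit is a maximal run of consecutive points inside the half-open
    cuboid; runs of fewer than 2 points (a single 20 ms crossing at 50 fps)
    are discarded. Visits to vertical targets are labeled upwind/downwind by
    their mean y relative to the target plane.
    """
    inside = cuboid.contains(track.xyz)
    visits: list[Visit] = []
    n = track.n_points
    i = 0
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inside[j + 1]:
            j += 1
        if j - i + 1 >= 2:
            frames = track.frames[i:j + 1]
            xyz = track.xyz[i:j + 1]
            m = visit_metrics(xyz, frames, track.frame_rate_hz)
            side = None
            if cuboid.plane_y is not None:
                side = "upwind" if np.mean(xyz[:, 1]) >= cuboid.plane_y else "downwind"
            visits.append(Visit(track.track_id, cuboid.label,
                                int(frames[0]), int(frames[-1]),
                                frames, xyz, side=side, **m))
        i = j + 1
    return visits


def visit_metrics(xyz: np.ndarray, frames: np.ndarray,
                  frame_rate_hz: float = 50.0) -> dict:
    """Duration, 3D path length, chord, tortuosity and mean speed of a
    contiguous segment.

    duration = (last - first frame) / rate; path = summed 3D steps;
    tortuosity = path / entry-exit chord (NaN when the chord is shorter than
    0.1 cm); mean speed = path / duration.
    """
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    if len(xyz) < 2:
        raise ValueError("visit metrics need at least 2 points")
    duration = float(frames[-1] - frames[0]) / frame_rate_hz
    path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
    chord = float(np.linalg.norm(xyz[-1] - xyz[0]))
    tortuosity = path / chord if chord >= MIN_CHORD_CM else float("nan")
    return {"duration_s": duration, "path_length_cm": path, "chord_cm": chord,
            "tortuosity": tortuosity, "mean_speed_cms": path / duration}


def summarize_target(visits: Sequence[Visit], landings: int,
                     target_area_cm2: float, label: str | None = None) -> TargetSummary:
    """Totals and means over one target's visits, plus landing density
    (landings per 100 cm^2 of target surface).

    For vertical targets the upwind/downwind breakdown of visit counts, time
    and distance is included.
    """
    if not target_area_cm2 > 0:
        raise ValueError("target_area_cm2 must be > 0")
    labels = {v.label for v in visits}
    if label is None:
        label = labels.pop() if len(labels) == 1 else "target"
    elif labels and labels != {label}:
        raise ValueError(f"visits carry labels {labels}, expected {label!r}")
    tort = [v.tortuosity for v in visits if np.isfinite(v.tortuosity)]
    total_time = float(sum(v.duration_s for v in visits))
    summary = TargetSummary(
        label=label,
        n_visits=len(visits),
        total_time_s=total_time,
        total_distance_cm=float(sum(v.path_length_cm for v in visits)),
        mean_tortuosity=float(np.mean(tort)) if tort else float("nan"),
        mean_speed_cms=float(np.mean([v.mean_speed_cms for v in visits]))
        if visits else float("nan"),
        landings=int(landings),
        target_area_cm2=float(target_area_cm2),
        landing_density_per_100cm2=100.0 * landings / target_area_cm2,
    )
    sides = {v.side for v in visits}
    if sides & {"upwind", "downwind"}:
        up = [v for v in visits if v.side == "upwind"]
        down = [v for v in visits if v.side == "downwind"]
        summary.n_visits_upwind = len(up)
        summary.n_visits_downwind = len(down)
        summary.time_upwind_s = float(sum(v.duration_s for v in up))
        summary.time_downwind_s = float(sum(v.duration_s for v in down))
        summary.distance_upwind_cm = float(sum(v.path_length_cm for v in up))
        summary.distance_downwind_cm = float(sum(v.path_length_cm for v in down))
    return summary


def heatmap_density(tracks: Sequence[Track], plane: str = "XY",
                    bin_cm: float = 2.0,
                    arena_bounds: tuple = ARENA_BOUNDS):
    """2D histogram of track-point counts over an arena plane.

    Returns (grid, first-axis edges, second-axis edges); the grid sums to the
    number of points binned (points outside the arena are not counted).
    """
    if not bin_cm > 0:
        raise ValueError("bin_cm must be > 0")
    axes = {"XY": (0, 1), "YZ": (1, 2), "XZ": (0, 2)}
    if plane not in axes:
        raise ValueError(f"plane must be one of {sorted(axes)}")
    a, b = axes[plane]
    pts = (np.vstack([t.xyz for t in tracks])
           if tracks else np.empty((0, 3)))
    lo_a, hi_a = arena_bounds[a]
    lo_b, hi_b = arena_bounds[b]
    edges_a = np.arange(lo_a, hi_a + bin_cm, bin_cm)
    edges_b = np.arange(lo_b, hi_b + bin_cm, bin_cm)
    grid, _, _ = np.histogram2d(pts[:, a], pts[:, b], bins=(edges_a, edges_b))
    return grid, edges_a, edges_b
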