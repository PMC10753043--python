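"""Synthetic wind-tunnel flight tracks with known ground truth.

The simulator emulates the statistics the analysis pipeline is sensitive to:
a correlated random walk at 50 frames/s with speeds drawn about the 24 cm/s
mean flight speed of host-seeking mosquitoes, confined to the 120 x 200 x
120 cm arena by reflective walls, plus the acquisition defects the cleaning
stage targets (runs of missing frames and isolated spike points). Ground
truth is always taken from the clean track before corruption, so recovery of
visit counts and metrics after corruption + cleaning can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .tracks import ARENA_BOUNDS, Cuboid, Track, Visit, segment_visits

__all__ = [
    "SimulationConfig",
    "CorruptionRecord",
    "GroundTruth",
    "simulate_track",
    "corrupt_track",
    "make_visit_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Motion-model and corruption parameters.

    Only the mean speed (24 cm/s) and the arena extents are anchored to
    measurements on free-flying mosquitoes; speed spread, turning persistence
    and corruption rates are conventions chosen to look like wind-tunnel
    acquisitions (see docs/methods.md).
    """

    frame_rate_hz: float = 50.0
    mean_speed_cms: float = 24.0
    speed_sd_cms: float = 6.0
    persistence: float = 0.9          # 0 = uncorrelated, ->1 = straight flight
    arena_bounds: tuple = ARENA_BOUNDS
    duration_s: float = 30.0
    rng_seed: int = 0
    gap_rate: float = 0.01            # per-frame probability a gap starts
    gap_min_frames: int = 1
    gap_max_frames: int = 8
    spike_rate: float = 0.005         # per-frame probability of a spike point
    spike_magnitude_cm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("gap_rate", "spike_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.mean_speed_cms > 0 or self.speed_sd_cms < 0:
            raise ValueError("speeds must be positive")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not 1 <= self.gap_min_frames <= self.gap_max_frames:
            raise ValueError("gap length range invalid")


@dataclass
class CorruptionRecord:
    """Frame indices altered by :func:`corrupt_track`."""

    dropped_frames: list[int] = field(default_factory=list)
    spike_frames: list[int] = field(default_factory=list)

    @property
    def corrupted_frames(self) -> list[int]:
        return sorted(self.dropped_frames + self.spike_frames)


@dataclass
class GroundTruth:
    """What the analysis pipeline should recover.

    ``clean_tracks`` are the tracks before corruption; ``visits`` maps a
    cuboid label to the true visits of the clean tracks; ``corruption``
    records every altered frame per track.
    """

    clean_tracks: list[Track]
    visits: dict[str, list[Visit]] = field(default_factory=dict)
    corruption: dict[str, CorruptionRecord] = field(default_factory=dict)


def _truncated_normal_speeds(rng: np.random.Generator, n: int,
                             mean: float, sd: float) -> np.ndarray:
    speeds = rng.normal(mean, sd, size=n)
    while True:
        bad = speeds <= 0
        if not bad.any():
            return speeds
        speeds[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def simulate_track(config: SimulationConfig = SimulationConfig(),
                   track_id: str = "sim",
                   rng: np.random.Generator | None = None) -> tuple[Track, GroundTruth]:
    """Correlated random walk confined to the arena.

    Each frame the heading is a persistence-weighted blend of the previous
    heading and an isotropic random direction, and the step length is a
    positive (truncated-normal) speed divided by the frame rate. Walls
    reflect: the position is folded back and the heading component flipped,
    which preserves step lengths and hence the speed distribution.
    Deterministic given ``config.rng_seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = int(round(config.duration_s * config.frame_rate_hz))
    if n < 2:
        raise ValueError("duration_s too short for a track")
    bounds = np.asarray(config.arena_bounds, dtype=float)
    pos = bounds.mean(axis=1)
    heading = rng.normal(size=3)
    heading /= np.linalg.norm(heading)
    speeds = _truncated_normal_speeds(rng, n - 1, config.mean_speed_cms,
                                      config.speed_sd_cms)
    noise = rng.normal(size=(n - 1, 3))
    pts = np.empty((n, 3))
    pts[0] = pos
    w = config.persistence
    for i in range(n - 1):
        cand = w * heading + (1.0 - w) * noise[i] / np.linalg.norm(noise[i])
        norm = np.linalg.norm(cand)
        if norm < 1e-12:
            cand, norm = heading, 1.0
        heading = cand / norm
        step = heading * speeds[i] / config.frame_rate_hz
        nxt = pts[i] + step
        # reflect at walls (fold position, flip heading component)
        for a in range(3):
            lo, hi = bounds[a]
            if nxt[a] < lo:
                nxt[a] = 2 * lo - nxt[a]
                heading[a] = -heading[a]
            elif nxt[a] > hi:
                nxt[a] = 2 * hi - nxt[a]
                heading[a] = -heading[a]
        pts[i + 1] = nxt
    track = Track(track_id=track_id, frames=np.arange(n), xyz=pts,
                  interpolated=np.zeros(n, dtype=bool),
                  frame_rate_hz=config.frame_rate_hz)
    return track, GroundTruth(clean_tracks=[track])


def corrupt_track(track: Track,
                  config: SimulationConfig = SimulationConfig(),
                  rng: np.random.Generator | None = None,
                  gap_max_frames: int | None = None) -> tuple[Track, CorruptionRecord]:
    """Inject acquisition defects: runs of dropped frames and isolated spikes.

    Gap starts are drawn per frame at ``gap_rate`` with lengths uniform on
    [gap_min_frames, gap_max_frames]; spike points are displaced by
    ``spike_magnitude_cm`` in a random direction. The first and last frames
    are never corrupted, gaps do not touch each other, and spikes are kept
    isolated (not adjacent to gaps or other spikes) so each defect is exactly
    the kind the cleaning rules target. Every altered frame is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    gmax = config.gap_max_frames if gap_max_frames is None else gap_max_frames
    n = track.n_points
    record = CorruptionRecord()
    drop = np.zeros(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)   # frames unavailable for new defects
    blocked[:2] = blocked[-2:] = True
    starts = np.flatnonzero(rng.random(n) < config.gap_rate)
    for s in starts:
        length = int(rng.integers(config.gap_min_frames, gmax + 1))
        e = min(s + length, n - 2)
        if s < 2 or e <= s or blocked[max(0, s - 2):min(n, e + 2)].any():
            continue
        drop[s:e] = True
        blocked[max(0, s - 1):min(n, e + 1)] = True
    spike = np.zeros(n, dtype=bool)
    for s in np.flatnonzero(rng.random(n) < config.spike_rate):
        if blocked[max(0, s - 1):min(n, s + 2)].any() or drop[s]:
            continue
        spike[s] = True
        blocked[max(0, s - 1):min(n, s + 2)] = True
    xyz = track.xyz.copy()
    for s in np.flatnonzero(spike):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xyz[s] = xyz[s] + direction * config.spike_magnitude_cm
    record.dropped_frames = [int(track.frames[i]) for i in np.flatnonzero(drop)]
    record.spike_frames = [int(track.frames[i]) for i in np.flatnonzero(spike)]
    keep = ~drop
    corrupted = replace(track, frames=track.frames[keep], xyz=xyz[keep],
                        interpolated=track.interpolated[keep])
    return corrupted, record


# ---------------------------------------------------------------------------
# Planned-visit scenarios

def _outside_point(cuboid: Cuboid, margin: float, arena) -> np.ndarray:
    """A staging point outside the cuboid, aligned with its x/z center."""
    cx = (cuboid.x_range[0] + cuboid.x_range[1]) / 2
    cz = min((cuboid.z_range[0] + cuboid.z_range[1]) / 2, cuboid.z_range[1] - 2)
    lo_y, hi_y = arena[1]
    y = cuboid.y_range[0] - margin
    if y < lo_y + 3:
        y = min(cuboid.y_range[1] + margin, hi_y - 3)
    return np.array([cx, float(np.clip(y, lo_y + 3, hi_y - 3)), cz])


def make_visit_scenario(cuboids: Sequence[Cuboid],
                        visit_plan: Sequence[tuple[str, int, float]],
                        config: SimulationConfig = SimulationConfig(),
                        rng: np.random.Generator | None = None,
                        track_id: str = "scenario") -> tuple[list[Track], GroundTruth]:
    """Construct a track that pays each cuboid a planned number of visits.

    ``visit_plan`` lists (cuboid label, number of visits, dwell seconds per
    visit). During a dwell the track loops slowly on a small circle well
    inside the cuboid; between visits it retreats to a staging point outside
    every cuboid. Entries and exits cross the cuboid face in a single frame
    step, so the planned dwell maps exactly onto the segmented visit. Ground
    truth visits are computed from the constructed clean track.

    Raises ValueError for unknown labels or plans whose dwell time exceeds
    ``config.duration_s``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    by_label = {c.label: c for c in cuboids}
    for label, _, _ in visit_plan:
        if label not in by_label:
            raise ValueError(f"visit plan references unknown cuboid {label!r}")
    rate = config.frame_rate_hz
    total_dwell = sum(nv * dwell for _, nv, dwell in visit_plan)
    if total_dwell > config.duration_s:
        raise ValueError(
            f"planned dwell ({total_dwell:.1f} s) exceeds duration "
            f"({config.duration_s:.1f} s)")

    pts: list[np.ndarray] = []

    def goto(target: np.ndarray, step_cm: float = 6.0) -> None:
        cur = pts[-1]
        dist = float(np.linalg.norm(target - cur))
        n_steps = max(1, int(math.ceil(dist / step_cm)))
        for i in range(1, n_steps + 1):
            pts.append(cur + (target - cur) * i / n_steps)

    arena = config.arena_bounds
    first = by_label[visit_plan[0][0]] if visit_plan else cuboids[0]
    pts.append(_outside_point(first, 25.0, arena))
    for label, n_visits, dwell_s in visit_plan:
        cub = by_label[label]
        cx = (cub.x_range[0] + cub.x_range[1]) / 2
        cz = (cub.z_range[0] + cub.z_range[1]) / 2
        span = min(cub.x_range[1] - cub.x_range[0],
                   cub.y_range[1] - cub.y_range[0],
                   cub.z_range[1] - cub.z_range[0])
        loop_r = max(1.0, 0.25 * span)
        # enter through the y face nearest the staging side; the dwell loop
        # starts (and, closing on itself, ends) 4 cm inside that face, and
        # the porch sits 3 cm outside it, so entry and exit are short
        # single-frame hops: a dropped-frame gap at a transition can only be
        # bridged by an equally short chord, keeping recovered visit metrics
        # close to truth
        stage_y = _outside_point(cub, 25.0, arena)[1]
        if stage_y < cub.y_range[0]:
            center_y = cub.y_range[0] + 4.0 + loop_r
            start_angle = -np.pi / 2
            porch_y = cub.y_range[0] - 3.0
        else:
            center_y = cub.y_range[1] - 4.0 - loop_r
            start_angle = np.pi / 2
            porch_y = cub.y_range[1] + 3.0
        center = np.array([cx, center_y, cz])
        porch = np.array([cx, porch_y, cz])
        n_dwell = max(2, int(round(dwell_s * rate)) + 1)
        steps = max(1, n_dwell - 1)
        revs = max(1, int(round(steps / rate)))      # ~1 revolution per second
        omega = 2 * np.pi * revs / steps             # closes exactly
        for _ in range(n_visits):
            goto(porch)
            # hold outside for longer than any interpolatable gap, so dropped
            # frames around the excursion can never merge adjacent visits
            for j in range(12):
                ang = 2 * np.pi * j / 12
                pts.append(porch + np.array([1.0 * np.cos(ang), 0.0,
                                             1.0 * np.sin(ang)]))
            angles = start_angle + omega * np.arange(n_dwell)
            loop = np.column_stack((center[0] + loop_r * np.cos(angles),
                                    center[1] + loop_r * np.sin(angles),
                                    np.full(n_dwell, center[2])))
            pts.extend(loop)
            pts.append(porch.copy())
    # pad with a small deterministic hover circle at the final staging point
    n_total = int(round(config.duration_s * rate))
    hover_center = pts[-1].copy()
    i = 0
    while len(pts) < n_total:
        ang = 2 * np.pi * (i % int(rate)) / rate
        pts.append(hover_center + np.array([2.0 * np.cos(ang),
                                            2.0 * np.sin(ang), 0.0]))
        i += 1
    xyz = np.asarray(pts)
    track = Track(track_id=track_id, frames=np.arange(len(xyz)), xyz=xyz,
                  interpolated=np.zeros(len(xyz), dtype=bool),
                  frame_rate_hz=rate)
    truth = GroundTruth(clean_tracks=[track])
    for cub in cuboids:
        truth.visits[cub.label] = segment_visits(track, cub)
    # sanity: the construction must realize the plan exactly
    planned = {}
    for label, n_visits, _ in visit_plan:
        planned[label] = planned.get(label, 0) + n_visits
    for label, count in planned.items():
        got = len(truth.visits[label])
        if got != count:
            raise RuntimeError(
                f"scenario construction failed for {label!r}: "
                f"planned {count} visits, realized {got}")
    return [track], truth
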