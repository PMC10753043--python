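"""Ommatidial eye model for visual target detection distances.

Models a patch of adjacent ommatidia of a nocturnal mosquito compound eye as
circular receptive fields on a gaze-centered angular plane, projects circular
high-contrast targets (vertical, or lying flat on the floor and viewed
obliquely from flight height) into that plane, and computes per-ommatidium
stimulation as the fraction of each receptive field covered by the target's
angular image. The eye "detects" the target when the summed stimulation in
excess of a per-ommatidium threshold reaches a total threshold; sweeping the
eye-target distance yields the maximum detection distance.

All angular quantities are degrees; all lengths centimetres. The projection
is azimuthal-equidistant about the gaze direction (angular distances from the
gaze axis are preserved), and overlaps are planar polygon areas computed by
polygon clipping, so the model is accurate to second order for images within
a few tens of degrees of the gaze axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "ConfigurationError",
    "GeometryError",
    "EyeParameters",
    "OmmatidiumAxis",
    "TargetSpec",
    "AngularImage",
    "StimulationMap",
    "DetectionResult",
    "build_eye_array",
    "project_target",
    "ommatidium_stimulation",
    "eye_stimulation",
    "detection_distance",
    "export_stimulation_plot_data",
    "read_stimulation_plot_data",
]

#: inclusive-threshold slack for floating-point comparisons
_EPS = 1e-9


class ConfigurationError(ValueError):
    """Invalid model parameter."""


class GeometryError(ValueError):
    """Geometrically impossible eye/target arrangement."""


@dataclass(frozen=True)
class EyeParameters:
    """Angular geometry and thresholds of the modeled eye patch.

    Parameters
    ----------
    interommatidial_angle_deg:
        Angular spacing between adjacent ommatidial axes. Dark-adapted
        anopheline default 8.
    receptive_field_deg:
        Full angular width (diameter) of one ommatidium's circular receptive
        field; default 40, i.e. a 20 degree radius.
    n_rings:
        Number of concentric rings of ommatidia around the central axis;
        ring k holds 6k axes at angular radius ``k * interommatidial_angle``,
        so the default 3 rings give a 37-ommatidium patch.
    individual_threshold_pct:
        Minimum stimulation (percent of receptive-field area covered) for an
        ommatidium to contribute to the eye total.
    total_threshold_pct:
        Summed stimulation required for detection.
    summation:
        How supra-threshold ommatidia are summed: ``"excess"`` (default) sums
        stimulation in excess of ``individual_threshold_pct``; ``"supra_sum"``
        sums the full stimulation values.
    polygon_resolution:
        Vertices used to discretise circles and target outlines.
    scan_step_cm, scan_max_cm:
        Resolution and upper bound of the detection-distance sweep.
    """

    interommatidial_angle_deg: float = 8.0
    receptive_field_deg: float = 40.0
    n_rings: int = 3
    individual_threshold_pct: float = 20.0
    total_threshold_pct: float = 100.0
    polygon_resolution: int = 360
    scan_step_cm: float = 1.0
    scan_max_cm: float = 500.0
    summation: str = "excess"

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"{name}: {why} (got {getattr(self, name)!r})")

        if not self.interommatidial_angle_deg > 0:
            raise bad("interommatidial_angle_deg", "must be > 0")
        if not self.receptive_field_deg > 0:
            raise bad("receptive_field_deg", "must be > 0")
        if self.n_rings < 0:
            raise bad("n_rings", "must be >= 0")
        if not 0 <= self.individual_threshold_pct <= 100:
            raise bad("individual_threshold_pct", "must be in [0, 100]")
        if self.polygon_resolution < 16:
            raise bad("polygon_resolution", "must be >= 16")
        if not self.scan_step_cm > 0:
            raise bad("scan_step_cm", "must be > 0")
        if not self.scan_max_cm > 0:
            raise bad("scan_max_cm", "must be > 0")
        if self.summation not in ("excess", "supra_sum"):
            raise bad("summation", "must be 'excess' or 'supra_sum'")

    @property
    def rf_radius_deg(self) -> float:
        return self.receptive_field_deg / 2.0

    @property
    def n_ommatidia(self) -> int:
        return 1 + 3 * self.n_rings * (self.n_rings + 1)


@dataclass(frozen=True)
class OmmatidiumAxis:
    """One ommatidial optical axis, as an offset from the gaze direction."""

    index: int
    ring: int
    offset_deg: tuple[float, float]


@dataclass(frozen=True)
class TargetSpec:
    """A circular high-contrast target.

    ``distance_cm`` is the horizontal distance from the eye to the target
    center; it may be None in templates handed to :func:`detection_distance`.
    ``altitude_cm`` is the eye height above the target plane and applies to
    horizontal (floor-lying) targets only.
    """

    diameter_cm: float
    orientation: str = "vertical"
    distance_cm: float | None = None
    altitude_cm: float = 15.0

    def __post_init__(self) -> None:
        if not self.diameter_cm > 0:
            raise ConfigurationError(
                f"diameter_cm: must be > 0 (got {self.diameter_cm!r})")
        if self.orientation not in ("vertical", "horizontal"):
            raise ConfigurationError(
                f"orientation: must be 'vertical' or 'horizontal' "
                f"(got {self.orientation!r})")
        if self.distance_cm is not None and not self.distance_cm > 0:
            raise ConfigurationError(
                f"distance_cm: must be > 0 (got {self.distance_cm!r})")
        if self.orientation == "horizontal" and not self.altitude_cm > 0:
            raise ConfigurationError(
                f"altitude_cm: must be > 0 for horizontal targets "
                f"(got {self.altitude_cm!r})")


@dataclass(frozen=True)
class AngularImage:
    """Target outline projected into gaze-centered angular coordinates."""

    outline: Polygon
    source: TargetSpec

    @property
    def area_deg2(self) -> float:
        return self.outline.area


@dataclass(frozen=True)
class StimulationMap:
    """Per-ommatidium stimulation percentages and the detection verdict."""

    per_ommatidium_pct: tuple[float, ...]
    total_pct: float
    detected: bool


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a detection-distance sweep.

    ``sweep`` is an ordered list of ``(distance_cm, total_pct, detected)``;
    ``max_distance_cm`` is the largest swept distance with a detection, or
    None if the target is never detected in range.
    """

    max_distance_cm: float | None
    sweep: tuple[tuple[float, float, bool], ...]


def build_eye_array(params: EyeParameters) -> list[OmmatidiumAxis]:
    """Lay out the ommatidial axes of the modeled eye patch.

    One central axis plus ``n_rings`` concentric rings; ring k carries 6k
    axes evenly spaced on a circle of angular radius
    ``k * interommatidial_angle_deg``, giving the hexagon-like 1/6/12/18
    populations (37 axes at the default 3 rings).
    """
    axes = [OmmatidiumAxis(index=0, ring=0, offset_deg=(0.0, 0.0))]
    idx = 1
    for k in range(1, params.n_rings + 1):
        radius = k * params.interommatidial_angle_deg
        for j in range(6 * k):
            ang = 2.0 * math.pi * j / (6 * k)
            axes.append(OmmatidiumAxis(
                index=idx, ring=k,
                offset_deg=(radius * math.cos(ang), radius * math.sin(ang))))
            idx += 1
    return axes


def _circle_polygon(cx: float, cy: float, radius: float, resolution: int) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    return Polygon(np.column_stack((cx + radius * np.cos(t),
                                    cy + radius * np.sin(t))))


def project_target(target: TargetSpec, params: EyeParameters) -> AngularImage:
    """Project a circular target into gaze-centered angular coordinates.

    The gaze points at the target center. A vertical disk maps to a circle of
    angular radius ``arctan(radius / distance)`` centered on the gaze axis. A
    horizontal (floor-lying) disk is seen obliquely from ``altitude_cm`` above
    its plane: each of ``polygon_resolution`` boundary points is projected
    through the eye position and mapped azimuthal-equidistantly about the
    gaze, producing the foreshortened, vertically compressed outline.
    """
    if target.distance_cm is None:
        raise ConfigurationError("distance_cm: required to project a target")
    d = float(target.distance_cm)
    r = target.diameter_cm / 2.0
    res = params.polygon_resolution

    if target.orientation == "vertical":
        alpha = math.degrees(math.atan2(r, d))
        return AngularImage(_circle_polygon(0.0, 0.0, alpha, res), target)

    if d < r:
        raise GeometryError(
            f"horizontal target: eye (horizontal distance {d} cm) lies over "
            f"the target disk (radius {r} cm)")
    h = float(target.altitude_cm)
    eye = np.array([0.0, 0.0, h])
    gaze = np.array([d, 0.0, -h])
    gaze = gaze / np.linalg.norm(gaze)
    # elevation/azimuth basis of the plane normal to the gaze
    up = np.array([0.0, 0.0, 1.0])
    e_elev = up - up.dot(gaze) * gaze
    e_elev = e_elev / np.linalg.norm(e_elev)
    e_azim = np.cross(e_elev, gaze)

    t = np.linspace(0.0, 2.0 * np.pi, res, endpoint=False)
    boundary = np.column_stack((d + r * np.cos(t), r * np.sin(t), np.zeros(res)))
    view = boundary - eye
    view = view / np.linalg.norm(view, axis=1)[:, None]
    theta = np.degrees(np.arccos(np.clip(view.dot(gaze), -1.0, 1.0)))
    psi = np.arctan2(view.dot(e_elev), view.dot(e_azim))
    outline = Polygon(np.column_stack((theta * np.cos(psi), theta * np.sin(psi))))
    return AngularImage(outline, target)


def ommatidium_stimulation(image: AngularImage, axis: OmmatidiumAxis,
                           params: EyeParameters) -> float:
    """Percent of one receptive field covered by the target image.

    Receptive field = disk of radius ``receptive_field_deg / 2`` centered on
    the axis offset; the overlap is computed by polygon clipping. Degenerate
    (zero-area) images give 0.
    """
    rf = _circle_polygon(*axis.offset_deg, params.rf_radius_deg,
                         params.polygon_resolution)
    return _clip_pct(image.outline, rf)


def _clip_pct(outline: Polygon, rf: Polygon) -> float:
    if outline.is_empty or outline.area <= 0.0:
        return 0.0
    if not outline.intersects(rf):
        return 0.0
    pct = 100.0 * outline.intersection(rf).area / rf.area
    return float(min(100.0, max(0.0, pct)))


def summarize_stimulation(values: Sequence[float],
                          params: EyeParameters) -> tuple[float, bool]:
    """Reduce per-ommatidium percentages to (total_pct, detected).

    Ommatidia at or above ``individual_threshold_pct`` contribute; under the
    default ``"excess"`` summation each contributes its stimulation in excess
    of that threshold, under ``"supra_sum"`` its full value. Detection is
    ``total >= total_threshold_pct`` (inclusive, with float slack).
    """
    vals = np.asarray(values, dtype=float)
    supra = vals[vals >= params.individual_threshold_pct - _EPS]
    if params.summation == "excess":
        total = float(np.sum(supra - params.individual_threshold_pct))
    else:
        total = float(np.sum(supra))
    return total, bool(total >= params.total_threshold_pct - _EPS)


def eye_stimulation(image: AngularImage, eye: Sequence[OmmatidiumAxis],
                    params: EyeParameters) -> StimulationMap:
    """Stimulation of every ommatidium in the patch, plus the verdict."""
    if not eye:
        raise ConfigurationError("eye: must contain at least one ommatidium")
    rf_r = params.rf_radius_deg
    res = params.polygon_resolution
    outline = image.outline
    minx, miny, maxx, maxy = (outline.bounds if not outline.is_empty
                              else (0.0, 0.0, 0.0, 0.0))
    values: list[float] = []
    for axis in eye:
        cx, cy = axis.offset_deg
        # cheap reject: RF disk cannot meet the image's bounding box
        if (cx + rf_r < minx or cx - rf_r > maxx
                or cy + rf_r < miny or cy - rf_r > maxy):
            values.append(0.0)
            continue
        rf = _circle_polygon(cx, cy, rf_r, res)
        values.append(_clip_pct(outline, rf))
    total, detected = summarize_stimulation(values, params)
    return StimulationMap(tuple(values), total, detected)


def detection_distance(target_template: TargetSpec,
                       eye: Sequence[OmmatidiumAxis] | None = None,
                       params: EyeParameters = EyeParameters()) -> DetectionResult:
    """Sweep distance and return the largest one at which the eye detects.

    Distances run from ``scan_step_cm`` to ``scan_max_cm`` in ``scan_step_cm``
    increments (horizontal targets start past the disk edge, where the
    geometry is defined). The full sweep trace is returned; the maximum is
    the largest detected distance rather than the first threshold crossing,
    since horizontal-target stimulation need not be monotone in distance.
    """
    if eye is None:
        eye = build_eye_array(params)
    n_steps = int(math.floor(params.scan_max_cm / params.scan_step_cm + _EPS))
    distances = [params.scan_step_cm * i for i in range(1, n_steps + 1)]
    if target_template.orientation == "horizontal":
        radius = target_template.diameter_cm / 2.0
        distances = [d for d in distances if d >= radius]
    sweep: list[tuple[float, float, bool]] = []
    best: float | None = None
    for d in distances:
        target = replace(target_template, distance_cm=d)
        smap = eye_stimulation(project_target(target, params), eye, params)
        sweep.append((d, smap.total_pct, smap.detected))
        if smap.detected:
            best = d
    return DetectionResult(best, tuple(sweep))


def export_stimulation_plot_data(smap: StimulationMap, image: AngularImage,
                                 eye: Sequence[OmmatidiumAxis],
                                 params: EyeParameters = EyeParameters()) -> pd.DataFrame:
    """Plot-ready geometry: ommatidium circles with stimulation, plus the
    target outline, sufficient to redraw stimulation-map panels.

    Rows with ``kind == "ommatidium"`` carry one circle each (center, radius,
    stimulation); rows with ``kind == "outline"`` share id 0 and carry the
    image outline vertices in order.
    """
    rows = []
    for axis, pct in zip(eye, smap.per_ommatidium_pct):
        rows.append(("ommatidium", axis.index, axis.offset_deg[0],
                     axis.offset_deg[1], params.rf_radius_deg, pct))
    if image.outline.is_empty or image.outline.area <= 0.0:
        rows.append(("outline", 0, np.nan, np.nan, np.nan, np.nan))
    else:
        for x, y in list(image.outline.exterior.coords)[:-1]:
            rows.append(("outline", 0, x, y, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["kind", "id", "x_deg", "y_deg",
                                       "radius_deg", "stimulation_pct"])


def read_stimulation_plot_data(path) -> pd.DataFrame:
    """Read back a plot-data CSV written with ``DataFrame.to_csv(index=False)``."""
    return pd.read_csv(path, dtype={"kind": str, "id": int})
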