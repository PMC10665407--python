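"""Projection of pointing vectors and figure-frame assembly.

A *figure frame* is the planar polygon obtained by projecting one
subject's eight perimeter pointing vectors onto the frontal plane at unit
distance.  With per-axis angles (azimuth ``a``, polar ``p``) the projection
is ``x = tan(a), y = tan(p)``, which exactly inverts the wall geometry: an
ideal pointer to a wall target at horizontal offset X and vertical offset
Y cm, viewed from D cm, maps to (X/D, Y/D).  The ideal 3x3 matrix
(100 cm spacing, 192 cm distance) therefore projects to a perfect square
of side 2*100/192 in tangent units.

Targets are pointed at in randomized order; the frame is *reassembled*
here purely by target label, in a fixed perimeter walk, never re-sorted by
geometry — so a distorted mental configuration yields a faithfully
distorted (possibly self-crossing) polygon.  The center target is kept
aside for deviation analysis and excluded from the polygon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .io import (
    PERIMETER_ORDER,
    Paradigm,
    PointingRecord,
    TargetLabel,
)

__all__ = [
    "PlanarPoint",
    "FigureFrame",
    "DeviationSummary",
    "ProjectionRangeError",
    "FrameAssemblyError",
    "spherical_to_planar",
    "planar_to_spherical",
    "build_figure_frame",
    "ideal_frame",
    "angular_deviation",
    "frames_from_records",
]

#: Angles at or beyond this magnitude are rejected: so close to the rim of
#: the forward hemisphere the tangent-plane projection degenerates and a
#: different (e.g. stereographic) projection would be required.
MAX_PROJECTION_DEG = 89.0


class ProjectionRangeError(ValueError):
    """Angle too close to the rim of the forward hemisphere to project."""


class FrameAssemblyError(ValueError):
    """Records cannot be assembled into a complete figure frame."""


class PlanarPoint(NamedTuple):
    x: float
    y: float


def spherical_to_planar(azimuth_deg: float, polar_deg: float) -> PlanarPoint:
    """Project per-axis pointing angles onto the unit-distance frontal plane.

    ``x = tan(azimuth)``, ``y = tan(polar)``; both angles in degrees,
    azimuth positive rightward, polar positive upward.  Monotone in each
    angle, exact for the wall geometry (see module docstring).
    """
    for name, v in (("azimuth_deg", azimuth_deg), ("polar_deg", polar_deg)):
        if not math.isfinite(v) or abs(v) >= MAX_PROJECTION_DEG:
            raise ProjectionRangeError(
                f"{name}={v!r} outside projectable range (|angle| < "
                f"{MAX_PROJECTION_DEG} deg)"
            )
    return PlanarPoint(
        math.tan(math.radians(azimuth_deg)), math.tan(math.radians(polar_deg))
    )


def planar_to_spherical(x: float, y: float) -> tuple[float, float]:
    """Inverse of :func:`spherical_to_planar`, returning degrees."""
    return math.degrees(math.atan(x)), math.degrees(math.atan(y))


@dataclass(frozen=True)
class FigureFrame:
    """An eight-vertex planar polygon for one subject and paradigm.

    ``vertices`` is an (8, 2) array in the fixed perimeter order
    top_left, top_mid, top_right, mid_right, bottom_right, bottom_mid,
    bottom_left, mid_left.  Vertices of targets missing in lenient
    assembly are NaN and ``complete`` is False.
    """

    subject_id: str
    paradigm: Paradigm | None
    vertices: np.ndarray
    center_point: PlanarPoint | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (8, 2):
            raise FrameAssemblyError(
                f"frame must have exactly 8 vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    @property
    def vertex_map(self) -> Mapping[TargetLabel, PlanarPoint]:
        return {
            t: PlanarPoint(*self.vertices[i]) for i, t in enumerate(PERIMETER_ORDER)
        }

    def transformed(self, matrix: np.ndarray) -> "FigureFrame":
        """Frame with vertices (and center) mapped by a 2x2 linear map."""
        m = np.asarray(matrix, float)
        center = (
            None
            if self.center_point is None
            else PlanarPoint(*(m @ np.asarray(self.center_point)))
        )
        return FigureFrame(
            self.subject_id,
            self.paradigm,
            self.vertices @ m.T,
            center,
            self.complete,
        )


def build_figure_frame(
    records: Sequence[PointingRecord], strict: bool = True
) -> FigureFrame:
    """Assemble the figure frame from one subject x paradigm block.

    Input row order is irrelevant: vertices are placed by target label in
    the fixed perimeter order.  The center record, if present, is stored
    separately and excluded from the polygon.  In strict mode a missing or
    duplicated perimeter target raises; lenient mode leaves NaN vertices
    and marks the frame incomplete.
    """
    if not records:
        raise FrameAssemblyError("no records given")
    subjects = {r.subject_id for r in records}
    paradigms = {r.paradigm for r in records}
    if len(subjects) != 1 or len(paradigms) != 1:
        raise FrameAssemblyError(
            f"records span subjects {sorted(subjects)} and paradigms "
            f"{sorted(p.value for p in paradigms)}; expected one block"
        )
    by_target: dict[TargetLabel, PointingRecord] = {}
    for r in records:
        if r.target in by_target:
            raise FrameAssemblyError(
                f"duplicate target {r.target.value} for subject {r.subject_id!r}"
            )
        by_target[r.target] = r

    vertices = np.full((8, 2), np.nan)
    complete = True
    for i, t in enumerate(PERIMETER_ORDER):
        rec = by_target.get(t)
        if rec is None:
            if strict:
                raise FrameAssemblyError(
                    f"missing perimeter target {t.value} for subject "
                    f"{records[0].subject_id!r}, paradigm "
                    f"{records[0].paradigm.value}"
                )
            complete = False
            continue
        vertices[i] = spherical_to_planar(rec.azimuth_deg, rec.polar_deg)

    center = by_target.get(TargetLabel.CENTER)
    center_pt = (
        spherical_to_planar(center.azimuth_deg, center.polar_deg)
        if center is not None
        else None
    )
    return FigureFrame(
        records[0].subject_id, records[0].paradigm, vertices, center_pt, complete
    )


def ideal_frame(
    spacing_cm: float = 100.0,
    distance_cm: float = 192.0,
    paradigm: Paradigm | None = None,
) -> FigureFrame:
    """The primary figure: the error-free projection of the target matrix.

    A square of side ``2 * spacing_cm / distance_cm`` in tangent units with
    eight perimeter vertices and the center at the origin.
    """
    if spacing_cm <= 0 or distance_cm <= 0:
        raise ValueError("spacing_cm and distance_cm must be positive")
    u = spacing_cm / distance_cm
    vertices = np.array([t.grid for t in PERIMETER_ORDER], dtype=float) * u
    return FigureFrame("ideal", paradigm, vertices, PlanarPoint(0.0, 0.0))


def frames_from_records(
    records: Iterable[PointingRecord], strict: bool = True
) -> list[FigureFrame]:
    """All frames in a record collection, grouped by subject x paradigm.

    Frames are returned sorted by subject id then paradigm order, making
    downstream outputs deterministic regardless of input row order.
    """
    blocks: dict[tuple[str, Paradigm], list[PointingRecord]] = {}
    for r in records:
        blocks.setdefault((r.subject_id, r.paradigm), []).append(r)
    keys = sorted(blocks, key=lambda k: (k[0], k[1].order_index))
    return [build_figure_frame(blocks[k], strict=strict) for k in keys]


@dataclass(frozen=True)
class DeviationSummary:
    """Classical single-point angular deviations of a task vs a reference.

    Signed per-target deviations (test minus reference) per axis, plus the
    mean and sample SD of the absolute deviations — the classical
    accuracy measure that the figure-frame analysis complements.
    """

    reference_paradigm: Paradigm | None
    targets: tuple[TargetLabel, ...]
    azimuth_dev_deg: tuple[float, ...]
    polar_dev_deg: tuple[float, ...]
    mean_abs_azimuth_deg: float = field(init=False)
    sd_abs_azimuth_deg: float = field(init=False)
    mean_abs_polar_deg: float = field(init=False)
    sd_abs_polar_deg: float = field(init=False)

    def __post_init__(self) -> None:
        for axis, devs in (
            ("azimuth", self.azimuth_dev_deg),
            ("polar", self.polar_dev_deg),
        ):
            a = np.abs(np.asarray(devs, float))
            mean = float(a.mean()) if a.size else float("nan")
            sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
            object.__setattr__(self, f"mean_abs_{axis}_deg", mean)
            object.__setattr__(self, f"sd_abs_{axis}_deg", sd)


def angular_deviation(
    test: Sequence[PointingRecord], reference: Sequence[PointingRecord]
) -> DeviationSummary:
    """Per-target signed deviations of ``test`` from ``reference``.

    Both collections must cover the same targets for one subject (the
    reference is usually a calibration paradigm).
    """
    t_map = {r.target: r for r in test}
    r_map = {r.target: r for r in reference}
    if len(t_map) != len(test) or len(r_map) != len(reference):
        raise FrameAssemblyError("duplicate targets within test or reference")
    if set(t_map) != set(r_map):
        only_t = sorted(x.value for x in set(t_map) - set(r_map))
        only_r = sorted(x.value for x in set(r_map) - set(t_map))
        raise FrameAssemblyError(
            f"target mismatch (only in test: {only_t}; only in reference: {only_r})"
        )
    targets = tuple(t for t in TargetLabel if t in t_map)
    az = tuple(t_map[t].azimuth_deg - r_map[t].azimuth_deg for t in targets)
    pol = tuple(t_map[t].polar_deg - r_map[t].polar_deg for t in targets)
    ref_paradigms = {r.paradigm for r in reference}
    ref = ref_paradigms.pop() if len(ref_paradigms) == 1 else None
    return DeviationSummary(ref, targets, az, pol)
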