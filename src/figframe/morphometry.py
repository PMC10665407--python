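"""Rasterization and morphological descriptors of figure frames.

The raster is the canonical measurement domain: frames of impaired
subjects are frequently self-intersecting polygons, for which area and
perimeter are only well defined under an explicit fill rule.  Frames are
filled on a square canvas (2000 x 2000 px by default) under the even-odd
rule and all descriptors are measured on the binary region, mirroring a
classical binary-image morphometry workflow.  Closed-form vector
geometry (shoelace area, analytic perimeters, brute-force Feret) serves
as an independent oracle for simple polygons in the test-suite, not as
the measurement path.

Descriptors
-----------
area (pixel count), Crofton perimeter (digital-line intercept-count
estimate, 2-32 directions), circularity ``4*pi*A/P**2``, largest Feret diameter and
its angle, mean caliper ("average") diameter, solidity (area divided by
convex-hull area), maximum inscribed disc (radius and center from the
Euclidean distance transform), moment-equivalent ellipse, bounding box
and centroid.

Conventions: pixel coordinates are (x = column, y = row) with the row
axis pointing down; angles are reported counterclockwise from +x in the
world orientation (y up), in [0, 180).  The canvas world window is
[-extent, +extent] in tangent units on both axes; absolute pixel-valued
results therefore depend on ``canvas_px`` and ``extent`` and are not
comparable across different canvas settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _sk_polygon
from skimage.measure import perimeter_crofton as _sk_perimeter_crofton

from .frames import FigureFrame

__all__ = [
    "RasterShape",
    "ShapeDescriptors",
    "DescribeConfig",
    "rasterize",
    "area",
    "crofton_perimeter",
    "circularity",
    "feret",
    "average_diameter",
    "equivalent_disc_diameter",
    "solidity",
    "inscribed_disc",
    "fitted_ellipse",
    "describe",
    "describe_cohort",
]


@dataclass(frozen=True)
class RasterShape:
    """A binary pixel region with its world-to-pixel transform.

    ``grid[row, col]`` is True inside the region.  World coordinates
    (tangent units, y up) map to pixel-center coordinates via
    ``col = (x + extent) * scale - 0.5`` and
    ``row = (extent - y) * scale - 0.5`` with
    ``scale = canvas_px / (2 * extent)`` pixels per tangent unit.
    """

    grid: np.ndarray
    canvas_px: int
    extent: float
    degenerate: bool = False
    clipped: bool = False

    @property
    def scale(self) -> float:
        """Pixels per tangent unit."""
        return self.canvas_px / (2.0 * self.extent)

    def world_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        s = self.scale
        col = (xy[..., 0] + self.extent) * s - 0.5
        row = (self.extent - xy[..., 1]) * s - 0.5
        return np.stack([col, row], axis=-1)


def _world_to_pixel(verts: np.ndarray, canvas_px: int, extent: float) -> np.ndarray:
    s = canvas_px / (2.0 * extent)
    col = (verts[:, 0] + extent) * s - 0.5
    row = (extent - verts[:, 1]) * s - 0.5
    return np.column_stack([col, row])


def rasterize(
    frame: FigureFrame,
    canvas_px: int = 2000,
    extent: float = 1.2,
    fill_rule: str = "even_odd",
) -> RasterShape:
    """Fill a figure frame on a square binary canvas.

    Pixel centers inside the polygon under ``fill_rule`` (``"even_odd"``,
    the default, or ``"nonzero"`` winding) are set.  NaN vertices (from
    lenient assembly) are dropped.  Vertices outside the world window are
    clipped to the canvas and the raster is flagged ``clipped``; a polygon
    enclosing no pixel centers yields an empty raster flagged
    ``degenerate`` rather than an exception, so cohort runs continue past
    pathological frames.
    """
    if canvas_px < 64:
        raise ValueError("canvas_px must be >= 64")
    if extent <= 0:
        raise ValueError("extent must be positive")
    verts = frame.vertices[~np.isnan(frame.vertices).any(axis=1)]
    grid = np.zeros((canvas_px, canvas_px), dtype=bool)
    if len(verts) < 3:
        return RasterShape(grid, canvas_px, extent, degenerate=True)
    clipped = bool((np.abs(verts) > extent).any())
    pix = _world_to_pixel(verts, canvas_px, extent)
    if fill_rule == "even_odd":
        rr, cc = _sk_polygon(pix[:, 1], pix[:, 0], shape=grid.shape)
        grid[rr, cc] = True
    elif fill_rule == "nonzero":
        from matplotlib.path import Path as _MplPath

        lo = np.clip(np.floor(pix.min(axis=0)).astype(int), 0, canvas_px - 1)
        hi = np.clip(np.ceil(pix.max(axis=0)).astype(int), 0, canvas_px - 1)
        cols = np.arange(lo[0], hi[0] + 1)
        rows = np.arange(lo[1], hi[1] + 1)
        cg, rg = np.meshgrid(cols, rows)
        pts = np.column_stack([cg.ravel(), rg.ravel()])
        inside = _MplPath(pix).contains_points(pts)
        grid[pts[inside, 1], pts[inside, 0]] = True
    else:
        raise ValueError(f"unknown fill_rule {fill_rule!r}")
    return RasterShape(
        grid, canvas_px, extent, degenerate=not grid.any(), clipped=clipped
    )


def area(raster: RasterShape) -> int:
    """Region area as the count of set pixels."""
    return int(raster.grid.sum())


def area_world(raster: RasterShape) -> float:
    """Region area in tangent units squared."""
    return area(raster) / raster.scale**2


#: Digital-line direction sets for the intercept-count estimator, as
#: (dx, dy) lattice steps.  Parallel digital lines in direction (a, b)
#: have perpendicular spacing 1/sqrt(a^2 + b^2); each direction is
#: weighted by the angular sector it represents (Voronoi weights on the
#: half-circle).
_CROFTON_DIRS: dict[int, tuple[tuple[int, int], ...]] = {
    8: ((1, 0), (0, 1), (1, 1), (1, -1), (2, 1), (1, 2), (2, -1), (1, -2)),
}
_CROFTON_DIRS[16] = _CROFTON_DIRS[8] + (
    (3, 1), (1, 3), (3, -1), (1, -3), (3, 2), (2, 3), (3, -2), (2, -3),
)
_CROFTON_DIRS[24] = _CROFTON_DIRS[16] + (
    (4, 1), (1, 4), (4, -1), (1, -4), (4, 3), (3, 4), (4, -3), (3, -4),
)
_CROFTON_DIRS[32] = _CROFTON_DIRS[24] + (
    (5, 2), (2, 5), (5, -2), (2, -5), (5, 1), (1, 5), (5, -1), (1, -5),
)


def _crofton_digital(grid: np.ndarray, dirs: Sequence[tuple[int, int]]) -> float:
    angles = np.array([math.atan2(b, a) % math.pi for a, b in dirs])
    order = np.argsort(angles)
    gaps = np.diff(np.concatenate([angles[order], [angles[order][0] + math.pi]]))
    weights = np.empty(len(dirs))
    weights[order] = (gaps + np.roll(gaps, 1)) / (2.0 * math.pi)
    H, W = grid.shape

    def sl(n: int, d: int) -> tuple[slice, slice]:
        return (
            (slice(d, n), slice(0, n - d))
            if d >= 0
            else (slice(0, n + d), slice(-d, n))
        )

    total = 0.0
    for (a, b), w in zip(dirs, weights):
        sy, py = sl(H, b)
        sx, px = sl(W, a)
        n_chords = np.count_nonzero(grid[sy, sx] & ~grid[py, px])
        total += w * n_chords / math.hypot(a, b)
    return math.pi * total


def crofton_perimeter(raster: RasterShape, n_directions: int = 32) -> float:
    """Cauchy-Crofton perimeter estimate in pixels.

    The boundary length is estimated from chord (line-intercept) counts
    along families of parallel digital lines, one family per direction,
    each direction weighted by the angular sector it covers.  2 and 4
    directions use the classical discrete weights (ImageJ/MorphoLibJ
    convention); those variants carry a known ~5% bias on straight edges
    at unsampled orientations (e.g. axis-aligned squares under 4
    directions).  The default of 32 directions keeps the estimate within
    about 0.4% for convex shapes at any orientation while remaining exact
    on discs.  Features thinner than the largest sampling step (~5.4 px
    at 32 directions) may be under-counted; choose fewer directions for
    very thin structures.
    """
    if not raster.grid.any():
        return 0.0
    if n_directions in (2, 4):
        return float(_sk_perimeter_crofton(raster.grid, directions=n_directions))
    if n_directions in _CROFTON_DIRS:
        return _crofton_digital(raster.grid, _CROFTON_DIRS[n_directions])
    raise ValueError("n_directions must be one of 2, 4, 8, 16, 24, 32")


def circularity(area_value: float, perimeter: float) -> tuple[float, float]:
    """``4*pi*A/P**2`` as ``(clamped, raw)``; NaN when the perimeter is 0.

    Crofton noise on near-circular regions can push the raw ratio slightly
    above 1; the clamped value is capped at 1 and the raw value retained.
    """
    if not perimeter > 0:
        return float("nan"), float("nan")
    raw = 4.0 * math.pi * area_value / perimeter**2
    return min(raw, 1.0), raw


# ---------------------------------------------------------------------------
# point-set helpers (pixel regions and vector polygons share one code path)


def _region_points(region) -> np.ndarray:
    """Region as an (N, 2) float array of (x, y-up) points.

    For a raster, the boundary pixel centers with the row axis negated so
    that geometry downstream is in the world orientation; for an array
    input, the points themselves.
    """
    if isinstance(region, RasterShape):
        g = region.grid
        if not g.any():
            return np.empty((0, 2))
        boundary = g & ~ndimage.binary_erosion(g)
        rr, cc = np.nonzero(boundary)
        return np.column_stack([cc.astype(float), -rr.astype(float)])
    pts = np.asarray(region, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected a RasterShape or an (N, 2) point array")
    return pts


def _hull_vertices(pts: np.ndarray) -> np.ndarray:
    if len(pts) <= 2:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts
    return pts[hull.vertices]


def feret(region) -> tuple[float, float]:
    """Largest Feret diameter and its angle.

    The maximum pairwise distance over region points, evaluated on the
    convex hull (the maximizing pair is always a pair of hull vertices).
    The angle is in degrees counterclockwise from +x in [0, 180); ties are
    broken toward the smaller angle.  A single-point region has diameter 0
    and angle 0.  ``region`` may be a :class:`RasterShape` (pixel units)
    or an (N, 2) point array.
    """
    pts = _region_points(region)
    if len(pts) == 0:
        return float("nan"), float("nan")
    if len(pts) == 1:
        return 0.0, 0.0
    hull = _hull_vertices(pts)
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    dmax2 = d2.max()
    if dmax2 == 0.0:
        return 0.0, 0.0
    ii, jj = np.nonzero(d2 >= dmax2 * (1.0 - 1e-12))
    angles = np.degrees(np.arctan2(diff[ii, jj, 1], diff[ii, jj, 0])) % 180.0
    angles[np.isclose(angles, 180.0)] = 0.0
    return float(math.sqrt(dmax2)), float(angles.min())


def average_diameter(region, n_directions: int = 180) -> float:
    """Mean caliper (Feret) diameter over equally spaced directions.

    Caliper width — the extent of the projection of the region onto a
    direction — is averaged over ``n_directions`` directions in [0, pi).
    Direction-independent for a disc; ``4*s/pi`` for a square of side
    ``s``; scales linearly with the region.
    """
    pts = _region_points(region)
    if len(pts) == 0:
        return float("nan")
    hull = _hull_vertices(pts)
    theta = np.arange(n_directions) * math.pi / n_directions
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = hull @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.mean())


def equivalent_disc_diameter(area_value: float) -> float:
    """Diameter of the disc with the same area, ``2*sqrt(A/pi)``."""
    return 2.0 * math.sqrt(max(area_value, 0.0) / math.pi)


def solidity(region) -> float:
    """Region area over convex-hull area, in (0, 1]; NaN when degenerate.

    For a raster both areas are pixel counts: the hull of the region is
    filled on the same grid (union with the region, so the ratio can never
    exceed 1 through discretization).  For a vector polygon the shoelace
    and hull areas are used — meaningful for simple polygons only.
    """
    if isinstance(region, RasterShape):
        g = region.grid
        n = g.sum()
        if n == 0:
            return float("nan")
        boundary = g & ~ndimage.binary_erosion(g)
        rr, cc = np.nonzero(boundary)
        pts = np.column_stack([cc.astype(float), rr.astype(float)])
        if len(pts) <= 2:
            return float("nan")
        try:
            hull = ConvexHull(pts)
        except QhullError:
            return float("nan")
        hv = pts[hull.vertices]
        hr, hc = _sk_polygon(hv[:, 1], hv[:, 0], shape=g.shape)
        hull_mask = g.copy()
        hull_mask[hr, hc] = True
        return float(n / hull_mask.sum())
    pts = np.asarray(region, float)
    a = _shoelace(pts)
    if a == 0.0:
        return float("nan")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float("nan")
    return float(a / hull.volume)


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def inscribed_disc(raster: RasterShape) -> tuple[float, tuple[float, float]]:
    """Radius and center (x=col, y=row px) of the largest inscribed disc.

    The center maximizes the Euclidean distance transform of the region;
    the radius is that maximum distance, so the disc lies inside the
    region by construction.  NaN for an empty raster.
    """
    g = raster.grid
    if not g.any():
        return float("nan"), (float("nan"), float("nan"))
    dist = ndimage.distance_transform_edt(g)
    idx = int(np.argmax(dist))
    row, col = divmod(idx, g.shape[1])
    return float(dist.flat[idx]), (float(col), float(row))


def fitted_ellipse(
    raster: RasterShape,
) -> tuple[tuple[float, float], float, float, float]:
    """Moment-equivalent ellipse: ``((cx, cy), semi_major, semi_minor, angle)``.

    The ellipse with the same second-order central moments as the region
    (semi-axis = 2 standard deviations along each principal axis, the
    uniform-density convention).  Center in pixel (x=col, y=row)
    coordinates; angle of the major axis counterclockwise from +x in the
    world orientation, degrees in [0, 180), reported as 0 when the two
    axes are equal within rounding (disc, square).  NaN when degenerate.
    """
    g = raster.grid
    nan = float("nan")
    if not g.any():
        return (nan, nan), nan, nan, nan
    rr, cc = np.nonzero(g)
    cx, cy = float(cc.mean()), float(rr.mean())
    x = cc - cc.mean()
    y = -(rr - rr.mean())  # world orientation, y up
    cov = np.cov(np.stack([x, y]), bias=True)
    if not np.isfinite(cov).all():
        return (cx, cy), nan, nan, nan
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0:
        return (cx, cy), nan, nan, nan
    semi_major = 2.0 * math.sqrt(evals[1])
    semi_minor = 2.0 * math.sqrt(max(evals[0], 0.0))
    if (evals[1] - evals[0]) / evals[1] < 1e-4:
        angle = 0.0  # isotropic: orientation undefined, tie-broken to 0
    else:
        vx, vy = evecs[:, 1]
        angle = math.degrees(math.atan2(vy, vx)) % 180.0
    return (cx, cy), semi_major, semi_minor, angle


# ---------------------------------------------------------------------------
# descriptor record and pipeline


_ALL_FIELDS = frozenset(
    {
        "area",
        "perimeter",
        "circularity",
        "feret",
        "avg_diameter",
        "solidity",
        "inscribed_disc",
        "ellipse",
        "bbox",
        "centroid",
    }
)


@dataclass(frozen=True)
class DescribeConfig:
    """Measurement settings for :func:`describe`.

    ``avg_diameter_method`` selects what the ``avg_diameter_px`` column
    reports: the mean caliper diameter (``"caliper"``, default) or the
    equivalent-disc diameter ``2*sqrt(A/pi)`` (``"equivalent_disc"``);
    both are always available in the record.  ``fields`` restricts the
    computed descriptor groups (None = all) — useful in large
    simulations where only one or two descriptors are needed.
    """

    canvas_px: int = 2000
    extent: float = 1.2
    fill_rule: str = "even_odd"
    crofton_directions: int = 32
    n_caliper_directions: int = 180
    avg_diameter_method: str = "caliper"
    fields: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.avg_diameter_method not in ("caliper", "equivalent_disc"):
            raise ValueError(
                f"unknown avg_diameter_method {self.avg_diameter_method!r}"
            )
        if self.fields is not None:
            unknown = set(self.fields) - _ALL_FIELDS
            if unknown:
                raise ValueError(f"unknown descriptor fields {sorted(unknown)}")
            object.__setattr__(self, "fields", frozenset(self.fields))

    def wants(self, name: str) -> bool:
        return self.fields is None or name in self.fields


@dataclass
class ShapeDescriptors:
    """The morphometric record of one figure frame.

    Lengths and areas are in pixels of the measurement canvas (see module
    docstring on comparability); ``*_world`` fields are in tangent units.
    Fields that could not be computed are NaN with the reason recorded in
    ``missing``.
    """

    subject_id: str
    paradigm: str | None
    canvas_px: int
    extent: float
    area_px: float = float("nan")
    area_world: float = float("nan")
    perimeter_px: float = float("nan")
    perimeter_world: float = float("nan")
    circularity: float = float("nan")
    circularity_raw: float = float("nan")
    feret_max_px: float = float("nan")
    feret_angle_deg: float = float("nan")
    avg_diameter_px: float = float("nan")
    caliper_diameter_px: float = float("nan")
    equiv_disc_diameter_px: float = float("nan")
    solidity: float = float("nan")
    inscribed_radius_px: float = float("nan")
    inscribed_cx_px: float = float("nan")
    inscribed_cy_px: float = float("nan")
    ellipse_cx_px: float = float("nan")
    ellipse_cy_px: float = float("nan")
    ellipse_semi_major_px: float = float("nan")
    ellipse_semi_minor_px: float = float("nan")
    ellipse_angle_deg: float = float("nan")
    bbox_min_col: float = float("nan")
    bbox_min_row: float = float("nan")
    bbox_max_col: float = float("nan")
    bbox_max_row: float = float("nan")
    centroid_col: float = float("nan")
    centroid_row: float = float("nan")
    degenerate: bool = False
    clipped: bool = False
    missing: str = ""

    def to_row(self) -> dict:
        return asdict(self)


def describe(frame: FigureFrame, config: DescribeConfig = DescribeConfig()) -> ShapeDescriptors:
    """Rasterize a frame and compute the full descriptor suite.

    Component failures (degenerate regions, zero perimeters) yield NaN
    fields with a reason in ``missing`` instead of raising, so a cohort
    run never aborts on one pathological frame.
    """
    raster = rasterize(
        frame, config.canvas_px, config.extent, fill_rule=config.fill_rule
    )
    d = ShapeDescriptors(
        subject_id=frame.subject_id,
        paradigm=frame.paradigm.value if frame.paradigm else None,
        canvas_px=config.canvas_px,
        extent=config.extent,
        degenerate=raster.degenerate,
        clipped=raster.clipped,
    )
    missing: list[str] = []
    if raster.degenerate:
        if config.wants("area"):
            d.area_px = 0.0
            d.area_world = 0.0
        if config.wants("perimeter"):
            d.perimeter_px = 0.0
            d.perimeter_world = 0.0
        d.missing = "all:degenerate-empty-region"
        return d

    a = area(raster)
    if config.wants("area"):
        d.area_px = float(a)
        d.area_world = a / raster.scale**2
    if config.wants("perimeter") or config.wants("circularity"):
        p = crofton_perimeter(raster, config.crofton_directions)
        if config.wants("perimeter"):
            d.perimeter_px = p
            d.perimeter_world = p / raster.scale
        if config.wants("circularity"):
            d.circularity, d.circularity_raw = circularity(a, p)
            if math.isnan(d.circularity):
                missing.append("circularity:zero-perimeter")
    if config.wants("feret"):
        d.feret_max_px, d.feret_angle_deg = feret(raster)
    if config.wants("avg_diameter"):
        d.caliper_diameter_px = average_diameter(raster, config.n_caliper_directions)
        d.equiv_disc_diameter_px = equivalent_disc_diameter(a)
        d.avg_diameter_px = (
            d.caliper_diameter_px
            if config.avg_diameter_method == "caliper"
            else d.equiv_disc_diameter_px
        )
    if config.wants("solidity"):
        d.solidity = solidity(raster)
        if math.isnan(d.solidity):
            missing.append("solidity:degenerate-hull")
    if config.wants("inscribed_disc"):
        d.inscribed_radius_px, (d.inscribed_cx_px, d.inscribed_cy_px) = inscribed_disc(
            raster
        )
    if config.wants("ellipse"):
        (cx, cy), maj, mino, ang = fitted_ellipse(raster)
        d.ellipse_cx_px, d.ellipse_cy_px = cx, cy
        d.ellipse_semi_major_px, d.ellipse_semi_minor_px = maj, mino
        d.ellipse_angle_deg = ang
        if math.isnan(maj):
            missing.append("ellipse:degenerate-moments")
    if config.wants("bbox") or config.wants("centroid"):
        rr, cc = np.nonzero(raster.grid)
        if config.wants("bbox"):
            d.bbox_min_col, d.bbox_max_col = float(cc.min()), float(cc.max())
            d.bbox_min_row, d.bbox_max_row = float(rr.min()), float(rr.max())
        if config.wants("centroid"):
            d.centroid_col, d.centroid_row = float(cc.mean()), float(rr.mean())
    d.missing = ";".join(missing)
    return d


def describe_cohort(
    frames: Iterable[FigureFrame], config: DescribeConfig = DescribeConfig()
) -> pd.DataFrame:
    """Descriptor table: one row per frame (subject x paradigm)."""
    return pd.DataFrame([describe(f, config).to_row() for f in frames])
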