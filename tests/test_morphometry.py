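"""Descriptor suite vs closed-form and brute-force geometry oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.draw import polygon as sk_polygon

from figframe.frames import ideal_frame
from figframe.io import Paradigm
from figframe.morphometry import (
    DescribeConfig,
    RasterShape,
    area,
    average_diameter,
    circularity,
    crofton_perimeter,
    describe,
    describe_cohort,
    equivalent_disc_diameter,
    feret,
    fitted_ellipse,
    inscribed_disc,
    rasterize,
    solidity,
)

from conftest import make_disc_raster, make_frame, make_square_raster, shoelace


def polygon_raster(vertices_px, canvas=600) -> RasterShape:
    v = np.asarray(vertices_px, float)
    grid = np.zeros((canvas, canvas), dtype=bool)
    rr, cc = sk_polygon(v[:, 1], v[:, 0], shape=grid.shape)
    grid[rr, cc] = True
    return RasterShape(grid, canvas, extent=1.2)


# ---------------------------------------------------------------- rasterize


def test_ideal_frame_pixel_count_matches_analytic_area():
    r = rasterize(ideal_frame())
    expected = (200 / 192) ** 2 / 2.4**2 * 2000**2  # ~753,520 px
    assert area(r) == pytest.approx(expected, rel=0.005)


def test_area_scales_quadratically_with_frame_size():
    base = ideal_frame()
    half = base.transformed(0.5 * np.eye(2))
    ratio = area(rasterize(half)) / area(rasterize(base))
    assert ratio == pytest.approx(0.25, rel=0.01)


def test_bowtie_fills_two_lobes_under_even_odd_rule():
    # crossed frame: left/right columns swapped on the top edge
    u = 100 / 192
    v = np.array(
        [
            [u, u],       # top_left -> swapped to the right
            [0.0, u],
            [-u, u],      # top_right -> swapped to the left
            [u, 0.0],
            [u, -u],
            [0.0, -u],
            [-u, -u],
            [-u, 0.0],
        ]
    )
    r = rasterize(make_frame(v))
    # vector oracle: the even-odd region of this crossed polygon is the two
    # side triangles plus the lower half; compute by splitting at the
    # self-intersection (0, 0) of edges (u,u)->(-u,u)... simpler: compare
    # against a fine winding-parity reference on a coarse grid
    xs = np.linspace(-1.2, 1.2, 241)
    inside = 0
    closed = np.vstack([v, v[0]])
    for x in xs:
        for y in xs:
            crossings = 0
            for (x1, y1), (x2, y2) in zip(closed[:-1], closed[1:]):
                if (y1 > y) != (y2 > y):
                    xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                    if xc > x:
                        crossings += 1
            inside += crossings % 2
    oracle_area = inside * (2.4 / 240) ** 2
    assert area(r) / r.scale**2 == pytest.approx(oracle_area, rel=0.02)
    # both lobes present: pixels on the left and on the right of center row
    mid = r.grid[r.grid.shape[0] // 2]
    assert mid[: len(mid) // 3].any() and mid[-len(mid) // 3 :].any()


def test_degenerate_zero_area_frame_yields_flagged_empty_raster():
    v = np.tile([0.1, 0.2], (8, 1))  # all vertices identical
    r = rasterize(make_frame(v))
    assert r.degenerate
    assert area(r) == 0


def test_rasterize_flags_clipped_frames():
    v = ideal_frame().vertices * 3.0  # outside +-1.2 window
    r = rasterize(make_frame(v))
    assert r.clipped


def test_nonzero_winding_rule_matches_even_odd_on_simple_polygons():
    f = ideal_frame()
    a_eo = area(rasterize(f, fill_rule="even_odd"))
    a_nz = area(rasterize(f, fill_rule="nonzero"))
    assert a_nz == pytest.approx(a_eo, rel=0.002)


def test_raster_area_matches_shoelace_for_simple_polygons(rng):
    for _ in range(5):
        v = ideal_frame().vertices + rng.normal(0, 0.04, (8, 2))
        f = make_frame(v)
        r = rasterize(f)
        assert area(r) / r.scale**2 == pytest.approx(shoelace(v), rel=0.005)


# ------------------------------------------------------------------ crofton


def test_crofton_perimeter_of_disc_matches_2_pi_r():
    r = make_disc_raster(250, canvas=600)
    for nd in (4, 16):
        assert crofton_perimeter(r, nd) == pytest.approx(2 * math.pi * 250, rel=0.01)


def test_crofton_16_direction_square_within_2_percent_any_rotation():
    for ang in (0.0, 17.0, 45.0):
        t = math.radians(ang)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        v = (np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) * 250.0) @ R.T + 500
        r = polygon_raster(v, canvas=1000)
        assert crofton_perimeter(r, 16) == pytest.approx(2000.0, rel=0.02)


def test_crofton_4_direction_has_the_documented_axis_aligned_bias():
    # continuous 4-direction limit for an axis-aligned square:
    # pi * (1 + sqrt(2)) / 2 * side = 0.948 * (4 * side)
    r = make_square_raster(500, canvas=600)
    expected = math.pi * (1 + math.sqrt(2)) / 2 * 500
    assert crofton_perimeter(r, 4) == pytest.approx(expected, rel=0.005)


def test_crofton_empty_raster_is_zero():
    r = RasterShape(np.zeros((100, 100), bool), 100, 1.2)
    assert crofton_perimeter(r) == 0.0


def test_crofton_rejects_unknown_direction_counts(square_raster):
    with pytest.raises(ValueError):
        crofton_perimeter(square_raster(100), 5)


# -------------------------------------------------------------- circularity


def test_circularity_closed_forms_and_raster():
    assert circularity(math.pi * 5**2, 2 * math.pi * 5)[0] == pytest.approx(1.0)
    clamped, raw = circularity(1.0, 4.0)  # unit square, analytic
    assert raw == pytest.approx(math.pi / 4)
    r = rasterize(ideal_frame())
    c, _ = circularity(area(r), crofton_perimeter(r))
    assert c == pytest.approx(math.pi / 4, rel=0.03)


def test_circularity_clamped_at_one_with_raw_retained():
    clamped, raw = circularity(100.0, 30.0)  # impossible ratio > 1
    assert clamped == 1.0
    assert raw > 1.0


def test_circularity_zero_perimeter_is_missing():
    assert all(math.isnan(v) for v in circularity(10.0, 0.0))


# -------------------------------------------------------------------- feret


def test_feret_of_square_is_the_diagonal_at_45_degrees():
    r = make_square_raster(400, canvas=600)
    d, ang = feret(r)
    # pixel centers span side-1 px
    assert d == pytest.approx(399 * math.sqrt(2), rel=0.005)
    assert ang == pytest.approx(45.0, abs=1.0)


def test_feret_equals_brute_force_over_all_boundary_pixel_pairs(rng):
    for _ in range(4):
        v = (ideal_frame().vertices + rng.normal(0, 0.12, (8, 2))) * 80 + 120
        r = polygon_raster(v, canvas=240)
        if not r.grid.any():
            continue
        from scipy import ndimage

        boundary = r.grid & ~ndimage.binary_erosion(r.grid)
        rr, cc = np.nonzero(boundary)
        pts = np.column_stack([cc, rr]).astype(float)
        brute = cdist(pts, pts).max()
        d, _ = feret(r)
        assert d == pytest.approx(brute, abs=1e-9)


def test_feret_of_oriented_segment_recovers_length_and_angle():
    L, ang = 300.0, 30.0
    t = math.radians(ang)
    x0, y0 = 150.0, 450.0
    pts = np.column_stack(
        [
            x0 + np.linspace(0, L, 400) * math.cos(t),
            y0 - np.linspace(0, L, 400) * math.sin(t),
        ]
    )
    grid = np.zeros((600, 600), bool)
    grid[np.round(pts[:, 1]).astype(int), np.round(pts[:, 0]).astype(int)] = True
    d, a = feret(RasterShape(grid, 600, 1.2))
    assert d == pytest.approx(L, rel=0.01)
    assert a == pytest.approx(ang, abs=1.0)


def test_feret_single_pixel_is_zero():
    grid = np.zeros((100, 100), bool)
    grid[50, 50] = True
    assert feret(RasterShape(grid, 100, 1.2)) == (0.0, 0.0)


# --------------------------------------------------------- average diameter


def test_average_diameter_of_disc_is_its_diameter():
    r = make_disc_raster(200, canvas=500)
    assert average_diameter(r) == pytest.approx(400, rel=0.01)


def test_average_diameter_of_square_is_4s_over_pi():
    r = make_square_raster(400, canvas=600)
    assert average_diameter(r) == pytest.approx(4 * 399 / math.pi, rel=0.01)


def test_average_diameter_scales_linearly():
    a = average_diameter(make_square_raster(150, canvas=600))
    b = average_diameter(make_square_raster(450, canvas=600))
    assert b / a == pytest.approx(3.0, rel=0.02)


def test_equivalent_disc_diameter_closed_form():
    assert equivalent_disc_diameter(math.pi * 7**2) == pytest.approx(14.0)


# ----------------------------------------------------------------- solidity


def test_convex_frame_has_solidity_one():
    assert solidity(rasterize(ideal_frame())) == pytest.approx(1.0, abs=0.01)


def test_arrowhead_solidity_one_half_vector_and_raster():
    # notched quadrilateral: shoelace area 2, hull (triangle) area 4
    v = np.array([[0.0, 0.0], [4.0, 1.0], [0.0, 2.0], [2.0, 1.0]])
    assert shoelace(v) == pytest.approx(2.0)
    assert solidity(v) == pytest.approx(0.5, abs=1e-9)
    r = polygon_raster(v * 120 + np.array([50, 150]), canvas=600)
    assert solidity(r) == pytest.approx(0.5, abs=0.02)


def test_solidity_decreases_monotonically_as_vertex_pulled_inward():
    vals = []
    for pull in (0.0, 0.3, 0.6, 0.9):
        v = ideal_frame().vertices.copy()
        v[3] = v[3] * (1 - pull) + np.array([-0.3, 0.0]) * pull  # mid_right inward
        vals.append(solidity(rasterize(make_frame(v), canvas_px=500)))
    assert all(b < a + 1e-6 for a, b in zip(vals, vals[1:]))
    assert vals[-1] < vals[0] - 0.05


def test_collinear_region_solidity_is_missing():
    grid = np.zeros((100, 100), bool)
    grid[50, 10:90] = True
    assert math.isnan(solidity(RasterShape(grid, 100, 1.2)))


# ------------------------------------------------------------ inscribed disc


def test_inscribed_disc_of_square_and_disc():
    s = make_square_raster(301, canvas=400)
    radius, (cx, cy) = inscribed_disc(s)
    assert radius == pytest.approx(301 / 2, abs=1.5)
    assert cx == pytest.approx(199.5, abs=1.0) and cy == pytest.approx(199.5, abs=1.0)
    d = make_disc_raster(120, canvas=300)
    radius, (cx, cy) = inscribed_disc(d)
    assert radius == pytest.approx(120, abs=1.5)
    assert cx == pytest.approx(149.5, abs=1.0)


def test_inscribed_disc_matches_exhaustive_search_on_L_shape():
    grid = np.zeros((96, 96), bool)
    grid[10:90, 10:40] = True
    grid[60:90, 10:90] = True
    r = RasterShape(grid, 96, 1.2)
    radius, (cx, cy) = inscribed_disc(r)
    fg = np.column_stack(np.nonzero(grid))  # (row, col)
    bg = np.column_stack(np.nonzero(~grid))
    dists = cdist(fg, bg).min(axis=1)  # distance to nearest background pixel
    best = dists.argmax()
    assert radius == pytest.approx(dists[best], abs=1e-9)
    # disc containment: every pixel of the disc around the center is foreground
    yy, xx = np.mgrid[0:96, 0:96]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 < (radius - 1e-9) ** 2
    assert grid[inside].all()


def test_inscribed_disc_empty_raster_missing():
    radius, center = inscribed_disc(RasterShape(np.zeros((80, 80), bool), 80, 1.2))
    assert math.isnan(radius)


# ------------------------------------------------------------ fitted ellipse


def test_ellipse_of_disc_is_isotropic_with_zero_orientation():
    r = make_disc_raster(150, canvas=400)
    (cx, cy), a, b, ang = fitted_ellipse(r)
    assert a == pytest.approx(b, rel=0.01)
    assert a == pytest.approx(150, rel=0.01)  # 2*sigma of a disc = r
    assert ang == 0.0
    assert cx == pytest.approx(199.5, abs=0.5)


def test_ellipse_of_square_has_semi_axes_side_over_sqrt3():
    r = make_square_raster(360, canvas=500)
    _, a, b, _ = fitted_ellipse(r)
    assert a == pytest.approx(360 / math.sqrt(3), rel=0.01)
    assert b == pytest.approx(360 / math.sqrt(3), rel=0.01)


def test_ellipse_orientation_follows_a_30_degree_rotation():
    rect = np.array([[-200, -80], [200, -80], [200, 80], [-200, 80]], float)
    r0 = polygon_raster(rect + 300, canvas=600)
    _, a0, b0, ang0 = fitted_ellipse(r0)
    assert ang0 == pytest.approx(0.0, abs=1.0)
    t = math.radians(30)
    R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    # rotate in world orientation: flip row axis for the pixel fixture
    rot = (rect @ R.T) * np.array([1, -1]) + 300
    r1 = polygon_raster(rot, canvas=600)
    _, a1, b1, ang1 = fitted_ellipse(r1)
    assert ang1 == pytest.approx(30.0, abs=1.0)
    assert a1 == pytest.approx(a0, rel=0.01)
    assert b1 == pytest.approx(b0, rel=0.01)


# ----------------------------------------------------------------- describe


def test_describe_ideal_frame_composite_values():
    d = describe(ideal_frame())
    r = rasterize(ideal_frame())
    side_px = (200 / 192) * r.scale
    assert d.solidity == pytest.approx(1.0, abs=0.01)
    assert d.circularity == pytest.approx(math.pi / 4, rel=0.03)
    assert d.feret_max_px == pytest.approx(side_px * math.sqrt(2), rel=0.01)
    assert d.avg_diameter_px == pytest.approx(4 * side_px / math.pi, rel=0.01)
    assert d.inscribed_radius_px == pytest.approx(side_px / 2, rel=0.01)
    assert d.ellipse_semi_major_px == pytest.approx(side_px / math.sqrt(3), rel=0.01)
    assert not d.degenerate and d.missing == ""


def test_describe_gross_outlier_vertex_breaks_convexity_and_grows_feret():
    ref = describe(ideal_frame())
    v = ideal_frame().vertices.copy()
    v[0] = [-1.1, 1.1]  # top_left far out
    d = describe(make_frame(v))
    assert d.solidity < ref.solidity - 0.02
    assert d.feret_max_px > ref.feret_max_px


def test_describe_zero_area_frame_continues_with_missing_fields():
    frames = [ideal_frame(), make_frame(np.tile([0.2, 0.2], (8, 1)))]
    table = describe_cohort(frames)
    assert len(table) == 2
    bad = table.iloc[1]
    assert bad["degenerate"]
    assert bad["area_px"] == 0.0
    assert math.isnan(bad["solidity"])
    assert "degenerate" in bad["missing"]


def test_describe_field_subset_skips_other_descriptors():
    d = describe(
        ideal_frame(),
        DescribeConfig(canvas_px=256, fields=frozenset({"area"})),
    )
    assert d.area_px > 0
    assert math.isnan(d.solidity) and math.isnan(d.feret_max_px)


def test_avg_diameter_method_switch():
    cfg = DescribeConfig(canvas_px=500, avg_diameter_method="equivalent_disc")
    d = describe(ideal_frame(), cfg)
    assert d.avg_diameter_px == d.equiv_disc_diameter_px
    assert d.caliper_diameter_px > d.equiv_disc_diameter_px  # square: 4s/pi > 2s/sqrt(pi)


# ------------------------------------------------- invariances (quick form)


def _random_frames(n, rng):
    base = ideal_frame().vertices * np.array([1.25, 0.8])
    return [make_frame(base + rng.normal(0, 0.05, (8, 2))) for _ in range(n)]


def test_rotation_invariance_and_scale_covariance_quick(rng):
    cfg = DescribeConfig(canvas_px=800)
    for f in _random_frames(3, rng):
        d0 = describe(f, cfg)
        t = math.radians(25.0)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        d1 = describe(f.transformed(R), cfg)
        for attr in ("area_px", "perimeter_px", "solidity", "avg_diameter_px", "feret_max_px"):
            assert getattr(d1, attr) == pytest.approx(getattr(d0, attr), rel=0.02)
        d2 = describe(f.transformed(0.6 * np.eye(2)), cfg)
        assert d2.area_px == pytest.approx(0.36 * d0.area_px, rel=0.01)
        assert d2.perimeter_px == pytest.approx(0.6 * d0.perimeter_px, rel=0.01)
        assert d2.feret_max_px == pytest.approx(0.6 * d0.feret_max_px, rel=0.01)


def test_resolution_convergence_1000_vs_2000():
    f = ideal_frame()
    lo = describe(f, DescribeConfig(canvas_px=1000))
    hi = describe(f, DescribeConfig(canvas_px=2000))
    assert lo.area_world == pytest.approx(hi.area_world, rel=0.01)
    assert lo.perimeter_world == pytest.approx(hi.perimeter_world, rel=0.01)
    assert lo.circularity == pytest.approx(hi.circularity, rel=0.01)
    assert lo.solidity == pytest.approx(hi.solidity, rel=0.01)
    assert lo.feret_max_px / 1000 == pytest.approx(hi.feret_max_px / 2000, rel=0.01)
    assert lo.avg_diameter_px / 1000 == pytest.approx(hi.avg_diameter_px / 2000, rel=0.01)
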