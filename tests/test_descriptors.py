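"""Shape descriptors against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
import shapely
from scipy import ndimage as ndi
from shapely import MultiPoint

from nucleoshape import (
    eccentricity_and_axes,
    elliptic_fourier,
    form_factor,
    mean_negative_curvature,
    measure_nucleus,
    point_asymmetry,
    radial_asymmetry,
    resample_contour,
    solidity,
    trace_contour,
)
from nucleoshape.descriptors import ContourTrace, elliptic_fourier_coefficients

from conftest import disk_graded, ellipse_graded, polar_shape, random_blob


# ---------------------------------------------------------------- contours
class TestTraceContour:
    def test_disk_polygon_area_matches_shoelace_of_circle(self):
        trace = trace_contour(disk_graded(50.0))
        assert trace.area == pytest.approx(math.pi * 50**2, rel=0.01)

    def test_square_polygon_area(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        trace = trace_contour(mask, smooth_sigma=0.0)
        assert trace.area == pytest.approx(100.0, abs=1.0)

    def test_single_pixel_object_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        with pytest.raises(ValueError):
            trace_contour(mask)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        mask[25:35, 25:35] = True
        with pytest.raises(ValueError, match="components"):
            trace_contour(mask)

    def test_contour_closed_and_counter_clockwise(self):
        trace = trace_contour(disk_graded(20.0))
        assert np.allclose(trace.points[0], trace.points[-1])
        x = trace.points[:, 1]
        y = -trace.points[:, 0]
        assert 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]) > 0


# ------------------------------------------------------------- form factor
class TestFormFactor:
    def test_analytic_circle_is_exactly_one(self):
        for r in (1.0, 17.0, 50.0):
            assert form_factor(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0, abs=1e-12)

    def test_analytic_square_is_pi_over_four(self):
        s = 7.0
        assert form_factor(s**2, 4 * s) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_rasterized_disk_close_to_one(self):
        trace = trace_contour(disk_graded(50.0))
        assert form_factor(trace.area, trace.perimeter) == pytest.approx(1.0, abs=0.02)

    def test_values_above_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert form_factor(100.0, 1.0) == 1.0

    @pytest.mark.parametrize("area,perim", [(0.0, 1.0), (1.0, 0.0), (-2.0, 3.0)])
    def test_non_positive_inputs_rejected(self, area, perim):
        with pytest.raises(ValueError):
            form_factor(area, perim)


# ------------------------------------------------------------ eccentricity
class TestEccentricity:
    def test_disk_nearly_zero(self):
        ecc, ratio = eccentricity_and_axes(disk_graded(50.0) >= 0.5)
        assert ecc < 0.05
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipse_closed_form(self):
        ecc, ratio = eccentricity_and_axes(ellipse_graded(60.0, 30.0) >= 0.5)
        assert ecc == pytest.approx(math.sqrt(3) / 2, abs=0.02)
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_rotation_invariance(self):
        e0, _ = eccentricity_and_axes(ellipse_graded(60.0, 30.0) >= 0.5)
        e37, _ = eccentricity_and_axes(ellipse_graded(60.0, 30.0, rotation=math.radians(37)) >= 0.5)
        assert e37 == pytest.approx(e0, abs=0.02)

    def test_degenerate_line_reports_eccentricity_one(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 3:17] = True
        ecc, ratio = eccentricity_and_axes(mask)
        assert ecc == 1.0 and math.isinf(ratio)


# ---------------------------------------------------------------- solidity
def _hull_oracle_solidity(mask: np.ndarray) -> float:
    """Independent pixel-counting solidity: shapely hull of pixel centres,
    exact count of pixel centres covered by the hull."""
    pts = np.argwhere(mask)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(1e-9)
    rr, cc = np.mgrid[: mask.shape[0], : mask.shape[1]]
    grid = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]).astype(float))
    return len(pts) / int(shapely.contains(hull, grid).sum())


class TestSolidity:
    def test_convex_disk_close_to_one(self):
        assert solidity(disk_graded(50.0) >= 0.5) >= 0.98

    def test_plus_sign_matches_hull_oracle(self):
        """Crossing 10x50 bars: hull is an octagon of 1660 pixel centres,
        solidity 900/1660 = 0.5422 — identical by both routes."""
        mask = np.zeros((50, 50), bool)
        mask[20:30, :] = True
        mask[:, 20:30] = True
        value = solidity(mask)
        assert value == _hull_oracle_solidity(mask)
        assert value == pytest.approx(900 / 1660, abs=1e-12)

    def test_notched_disk_less_solid_than_disk(self):
        disk = disk_graded(40.0) >= 0.5
        rr, cc = np.mgrid[: disk.shape[0], : disk.shape[1]]
        c = disk.shape[0] / 2
        wedge = (np.abs(np.arctan2(rr - c, cc - c)) < 0.35) & (np.hypot(rr - c, cc - c) > 12)
        notched = disk & ~wedge
        assert solidity(notched) < solidity(disk)

    def test_matches_brute_force_on_random_blobs(self, rng):
        for _ in range(15):
            blob = random_blob(rng)
            assert solidity(blob) == _hull_oracle_solidity(blob)


# --------------------------------------------------------------- curvature
class TestMeanNegativeCurvature:
    def test_convex_disk_has_none(self):
        assert mean_negative_curvature(trace_contour(disk_graded(50.0))) == 0.0

    def test_peanut_matches_polar_curvature_formula(self):
        """r(t) = 50(1 + 0.4 cos 2t): the polar curvature formula
        kappa = (r^2 + 2r'^2 - r r'') / (r^2 + r'^2)^(3/2) evaluated densely
        gives the arc-length-weighted mean over the concave stretches."""
        th = np.linspace(0.0, 2 * math.pi, 20000, endpoint=False)
        r = 50 * (1 + 0.4 * np.cos(2 * th))
        rp = -40.0 * np.sin(2 * th)
        rpp = -80.0 * np.cos(2 * th)
        kappa = (r**2 + 2 * rp**2 - r * rpp) / (r**2 + rp**2) ** 1.5
        ds = np.sqrt(r**2 + rp**2)
        concave = kappa < 0
        oracle = float((kappa[concave] * ds[concave]).sum() / ds[concave].sum())

        pts = np.column_stack([-r * np.sin(th), r * np.cos(th)])
        trace = ContourTrace(np.vstack([pts, pts[:1]]))
        value = mean_negative_curvature(trace, sigma_frac=0.0, n_points=512)
        assert value == pytest.approx(oracle, rel=0.05)
        assert value < 0

    def test_bilobed_more_negative_than_monolobed_of_same_area(self):
        def make(amp):
            graded, _ = polar_shape(
                lambda t: 50 * (1 + amp * np.cos(2 * t)) / math.sqrt(1 + amp**2 / 2),
                (70, 70), (140, 140),
            )
            return trace_contour(graded)

        bi = mean_negative_curvature(make(0.4))
        mono = mean_negative_curvature(make(0.0))
        assert bi < mono

    def test_too_short_contour_rejected(self):
        pts = np.column_stack([np.zeros(9), np.arange(9.0)])
        pts[-1] = pts[0]
        with pytest.raises(ValueError, match="32"):
            mean_negative_curvature(ContourTrace(pts))


# -------------------------------------------------------- elliptic Fourier
def _analytic_trace(radius_fn, n=1500):
    th = np.linspace(0.0, 2 * math.pi, n)
    r = radius_fn(th)
    pts = np.column_stack([-r * np.sin(th), r * np.cos(th)])
    pts[-1] = pts[0]
    return ContourTrace(pts)


class TestEllipticFourier:
    def test_circle_needs_one_harmonic(self):
        trace = _analytic_trace(lambda t: np.full_like(t, 50.0))
        assert elliptic_fourier(trace, "harmonics_needed") == 1

    def test_mild_ellipse_needs_one_harmonic_and_tiny_ratio(self):
        trace = _analytic_trace(lambda t: 45 * 30 / np.sqrt((30 * np.cos(t)) ** 2 + (45 * np.sin(t)) ** 2))
        assert elliptic_fourier(trace, "harmonics_needed") == 1
        assert elliptic_fourier(trace, "coefficient_ratio") < 0.01

    def test_star_shape_matches_dft_oracle(self):
        """r(t) = 50(1 + 0.2 cos 4t): harmonic energies from a plain FFT of
        the arc-length-resampled complex contour must reproduce the
        coefficient ratio."""
        trace = _analytic_trace(lambda t: 50 * (1 + 0.2 * np.cos(4 * t)), n=2001)
        impl = elliptic_fourier(trace, "coefficient_ratio", n_fixed=20)
        rs = resample_contour(trace, 4096).points[:-1]
        z = rs[:, 1] - 1j * rs[:, 0]
        F = np.fft.fft(z) / len(z)
        energy = np.abs(F[1:21]) ** 2 + np.abs(F[-1:-21:-1]) ** 2
        oracle = float(energy[1:].sum() / energy[0])
        assert impl == pytest.approx(oracle, rel=0.10)
        assert elliptic_fourier(trace, "harmonics_needed") > 1

    def test_coefficients_shape_and_rotation_invariant_energy(self):
        trace = _analytic_trace(lambda t: 50 * (1 + 0.2 * np.cos(4 * t)), n=2001)
        coeffs = elliptic_fourier_coefficients(trace, 12)
        assert coeffs.shape == (12, 4)
        rot = math.radians(23)
        th = np.linspace(0.0, 2 * math.pi, 2001)
        r = 50 * (1 + 0.2 * np.cos(4 * th))
        pts = np.column_stack([-r * np.sin(th + rot), r * np.cos(th + rot)])
        pts[-1] = pts[0]
        ratio0 = elliptic_fourier(trace, "coefficient_ratio")
        ratio1 = elliptic_fourier(ContourTrace(pts), "coefficient_ratio")
        assert ratio1 == pytest.approx(ratio0, rel=0.02)

    def test_short_contour_rejected(self):
        trace = resample_contour(_analytic_trace(lambda t: np.full_like(t, 30.0)), 32)
        with pytest.raises(ValueError, match="64"):
            elliptic_fourier(trace, "coefficient_ratio")


# ---------------------------------------------------------------- symmetry
class TestRadialAsymmetry:
    def test_disk_mostly_inside_inscribed_circle(self):
        count, frac = radial_asymmetry(disk_graded(50.0) >= 0.5)
        assert frac < 0.05

    def test_bar_fraction_matches_analytic_circle(self):
        """10x100 bar: inscribed circle radius 5, expected fraction about
        1 - pi*25/1000 = 0.9215; checked against exact pixel counting."""
        mask = np.zeros((20, 110), bool)
        mask[5:15, 5:105] = True
        count, frac = radial_asymmetry(mask)
        assert frac == pytest.approx(1 - math.pi * 25 / 1000, abs=0.05)
        dist = ndi.distance_transform_edt(mask)
        centre = np.unravel_index(np.argmax(dist), mask.shape)
        coords = np.argwhere(mask)
        oracle = int((np.hypot(*(coords - centre).T) > dist.max() + 1e-9).sum())
        assert count == oracle

    def test_fraction_bounded_on_random_blobs(self, rng):
        for _ in range(10):
            _, frac = radial_asymmetry(random_blob(rng))
            assert 0.0 <= frac <= 1.0


def _point_asymmetry_oracle(mask: np.ndarray) -> int:
    coords = np.argwhere(mask)
    c = coords.mean(axis=0)
    count = 0
    for p in coords:
        q = (math.floor(2 * c[0] - p[0] + 0.5), math.floor(2 * c[1] - p[1] + 0.5))
        if not (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1] and mask[q]):
            count += 1
    return count


class TestPointAsymmetry:
    def test_centrally_symmetric_rectangle(self):
        mask = np.zeros((30, 40), bool)
        mask[8:22, 5:35] = True
        count, frac = point_asymmetry(mask)
        assert frac <= 0.02

    def test_right_triangle_strongly_asymmetric_brute_force(self):
        mask = np.tri(40, 40, dtype=bool)
        count, frac = point_asymmetry(mask)
        assert frac > 0.2
        assert count == _point_asymmetry_oracle(mask)

    def test_count_never_exceeds_area(self, rng):
        for _ in range(10):
            blob = random_blob(rng)
            count, frac = point_asymmetry(blob)
            assert count <= blob.sum()
            assert count == _point_asymmetry_oracle(blob)


# ------------------------------------------------------------- invariances
def _lobed_radius(t):
    # a clearly anisotropic lobed nucleus: elliptical base plus a 5-fold lobe
    base = 48 * 36 / np.sqrt((36 * np.cos(t)) ** 2 + (48 * np.sin(t)) ** 2)
    return base * (1 + 0.08 * np.cos(5 * t))


def _descriptor_vector(graded):
    mask = graded >= 0.5
    trace = trace_contour(graded)
    ecc, _ = eccentricity_and_axes(mask)
    return {
        "form_factor": form_factor(trace.area, trace.perimeter),
        "eccentricity": ecc,
        "solidity": solidity(mask),
        "radial_frac": radial_asymmetry(mask)[1],
        "point_frac": point_asymmetry(mask)[1],
        "efd_ratio": elliptic_fourier(trace, "coefficient_ratio"),
        "area": trace.area,
        "perimeter": trace.perimeter,
    }


def test_scale_invariance_at_double_resolution():
    g1, _ = polar_shape(_lobed_radius, (62, 62), (124, 124))
    g2, _ = polar_shape(lambda t: 2 * _lobed_radius(t), (124, 124), (248, 248))
    d1, d2 = _descriptor_vector(g1), _descriptor_vector(g2)
    for key in ("form_factor", "solidity", "efd_ratio"):
        assert d2[key] == pytest.approx(d1[key], rel=0.02), key
    for key in ("eccentricity", "radial_frac", "point_frac"):
        # fraction-valued metrics: 0.02 absolute (their pixel-count
        # discretisation does not shrink relative error for small values)
        assert abs(d2[key] - d1[key]) < 0.02, key
    assert d2["area"] == pytest.approx(4 * d1["area"], rel=0.02)
    assert d2["perimeter"] == pytest.approx(2 * d1["perimeter"], rel=0.02)


def test_rotation_invariance_before_rasterization():
    g1, _ = polar_shape(_lobed_radius, (62, 62), (124, 124))
    g2, _ = polar_shape(_lobed_radius, (62, 62), (124, 124), rotation=math.radians(29))
    d1, d2 = _descriptor_vector(g1), _descriptor_vector(g2)
    for key in ("form_factor", "solidity", "efd_ratio"):
        assert d2[key] == pytest.approx(d1[key], rel=0.02), key
    for key in ("eccentricity", "radial_frac", "point_frac"):
        assert abs(d2[key] - d1[key]) < 0.02, key


def test_shape_panel_ordering():
    """Circle / 2:1 ellipse / bi-lobed / deeply lobulated: the lobulated
    shape scores the minimum solidity and form factor, and the ellipse the
    maximum eccentricity of the circle-ellipse pair."""
    shapes = {
        "circle": disk_graded(45.0),
        "ellipse": ellipse_graded(60.0, 30.0),
        "bilobed": polar_shape(lambda t: 45 * (1 + 0.35 * np.cos(2 * t)), (70, 70), (140, 140))[0],
        "lobulated": polar_shape(
            lambda t: 45 * (1 + 0.22 * np.cos(3 * t) + 0.15 * np.cos(5 * t)), (75, 75), (150, 150)
        )[0],
    }
    d = {name: _descriptor_vector(g) for name, g in shapes.items()}
    assert min(d, key=lambda k: d[k]["solidity"]) == "lobulated"
    assert min(d, key=lambda k: d[k]["form_factor"]) == "lobulated"
    assert d["ellipse"]["eccentricity"] > d["circle"]["eccentricity"]


def test_nucleus_record_internally_consistent(rng):
    blob = random_blob(rng)
    rec = measure_nucleus(blob)
    assert rec.form_factor == pytest.approx(
        4 * math.pi * rec.area_px / rec.perimeter_px**2, abs=1e-9
    )
    assert 0 < rec.solidity <= 1
    assert 0 <= rec.radial_asymmetry_frac <= 1
    assert 0 <= rec.point_asymmetry_frac <= 1
    assert rec.mean_negative_curvature <= 0
    assert rec.efd_harmonics_needed >= 1
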