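import numpy as np
import pytest

from trimorph import morphometry as mm
from trimorph import synth_valve as sv
from trimorph.errors import (
    DegenerateGeometryError,
    IncompleteAnnotationError,
    InvalidParameterError,
)
from conftest import rigid_transform

ELLIPSE_PERIMETER = 146.76754955  # 4 a E(e^2), a=25.1, b=21.55


def circle_landmarks(r=20.0, z=0.0):
    ang = np.arange(18) * 20.0
    th = np.deg2rad(ang)
    annular = np.column_stack([r * np.cos(th), r * np.sin(th), np.full(18, z)])
    free = np.column_stack(
        [0.5 * r * np.cos(th), 0.5 * r * np.sin(th), np.full(18, z - 5.0)]
    )
    return mm.AnnulusLandmarks(angles_deg=ang, annular=annular, free_margin=free)


class TestLongAxis:
    def test_planar_circle_normal(self):
        axis = mm.define_long_axis(circle_landmarks())
        assert abs(np.dot(axis.direction, [0, 0, 1])) > 1 - 1e-9

    def test_direction_points_toward_free_margin(self):
        axis = mm.define_long_axis(circle_landmarks())
        assert axis.direction @ np.array([0, 0, -1.0]) > 0  # free margin at z - 5

    def test_translation_equivariance(self):
        lm = circle_landmarks()
        lm2 = mm.AnnulusLandmarks(
            angles_deg=lm.angles_deg,
            annular=lm.annular + [0, 0, 10.0],
            free_margin=lm.free_margin + [0, 0, 10.0],
        )
        a1 = mm.define_long_axis(lm)
        a2 = mm.define_long_axis(lm2)
        assert a2.origin == pytest.approx(a1.origin + [0, 0, 10.0])
        assert a2.direction == pytest.approx(a1.direction)

    def test_saddle_phantom_axis_within_1_degree(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(
            annulus=saddle_annulus, tenting_profile="paraboloid", tenting_depth=8.0
        )
        axis = mm.define_long_axis(mm.landmarks_from_phantom(spec))
        cosang = abs(np.dot(axis.direction, saddle_annulus.axis_direction))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0

    def test_collinear_points_rejected(self):
        ang = np.arange(18) * 20.0
        line = np.column_stack([np.arange(18.0), np.zeros(18), np.zeros(18)])
        lm = mm.AnnulusLandmarks(angles_deg=ang, annular=line, free_margin=line)
        with pytest.raises(DegenerateGeometryError):
            mm.define_long_axis(lm)


class TestGeneratePlanes:
    def test_18_stations_20_degrees(self):
        axis = mm.LongAxis(origin=np.zeros(3), direction=np.array([0, 0, 1.0]))
        planes = mm.generate_planes(axis)
        assert len(planes.angles_deg) == 18
        assert np.diff(planes.angles_deg) == pytest.approx(20.0)

    def test_opposite_halfplanes_coplanar(self):
        axis = mm.LongAxis(origin=np.zeros(3), direction=np.array([0, 0, 1.0]))
        planes = mm.generate_planes(axis)
        d0, d9 = planes.direction(0), planes.direction(9)
        assert d0 == pytest.approx(-d9, abs=1e-12)

    def test_rotating_reference_permutes_stations(self):
        axis = mm.LongAxis(origin=np.zeros(3), direction=np.array([0, 0, 1.0]))
        planes = mm.generate_planes(axis)
        rot = np.deg2rad(20.0)
        d1 = planes.direction(1)
        rotated = np.cos(rot) * planes.u_vec + np.sin(rot) * planes.v_vec
        assert d1 == pytest.approx(rotated, abs=1e-12)


class TestExtractLandmarks:
    def test_phantom_circle_points_on_circle(self, flat_spec):
        lm = mm.landmarks_from_phantom(flat_spec)
        r = np.linalg.norm(lm.annular[:, :2], axis=1)
        assert r == pytest.approx(20.0, abs=0.25)

    def test_annotation_roundtrip(self, tmp_path, paraboloid_spec):
        from trimorph import io as tio

        ann = sv.phantom_annotation(paraboloid_spec)
        path = tmp_path / "a.json"
        tio.save_annotation(ann, path)
        lm1 = mm.extract_landmarks(ann)
        lm2 = mm.extract_landmarks(path)
        assert np.allclose(lm1.annular, lm2.annular)
        assert np.allclose(lm1.free_margin, lm2.free_margin)

    def test_missing_station_reported(self, paraboloid_spec):
        ann = sv.phantom_annotation(paraboloid_spec)
        removed = ann["planes"].pop(3)  # drops stations 60 and 240 deg
        with pytest.raises(IncompleteAnnotationError) as exc:
            mm.extract_landmarks(ann)
        assert removed["plane_angle_deg"] in exc.value.missing_angles_deg


class TestFitAnnulus:
    def test_circle_exact(self):
        fit = mm.fit_annulus(circle_landmarks())
        assert fit.rms_residual < 1e-9
        assert fit.centroid == pytest.approx([0, 0, 0], abs=1e-9)
        plane = mm.best_fit_plane(fit.polyline)
        l2d, l3d = mm.compute_perimeters(fit, plane)
        assert l3d == pytest.approx(2 * np.pi * 20, abs=1e-3 * 125.664)

    def test_saddle_coefficient_recovered(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(annulus=saddle_annulus, tenting_profile="flat")
        lm = mm.landmarks_from_phantom(spec)
        fit = mm.fit_annulus(lm)
        assert fit.model.cos_coeffs[2, 2] == pytest.approx(5.0, abs=1e-6)

    def test_fourier_order4_exactness(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(annulus=saddle_annulus, tenting_profile="flat")
        fit = mm.fit_annulus(mm.landmarks_from_phantom(spec))
        assert fit.rms_residual < 1e-9

    def test_jitter_mean_perimeter_bias_below_1pct(self):
        # Monte-Carlo: 0.5 mm isotropic landmark jitter, 100 seeds
        lm0 = circle_landmarks()
        ref = 2 * np.pi * 20
        perims = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lm = mm.AnnulusLandmarks(
                angles_deg=lm0.angles_deg,
                annular=lm0.annular + rng.normal(0, 0.5, size=(18, 3)),
                free_margin=lm0.free_margin,
            )
            fit = mm.fit_annulus(lm)
            plane = mm.best_fit_plane(fit.polyline)
            _, l3d = mm.compute_perimeters(fit, plane)
            perims.append(l3d)
        assert abs(np.mean(perims) - ref) / ref < 0.01

    def test_underdetermined_rejected(self):
        lm = circle_landmarks()
        with pytest.raises(InvalidParameterError):
            mm.fit_annulus(lm, order=9)


class TestBestFitPlane:
    def test_coplanar_zero_residual(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.normal(size=20), rng.normal(size=20), np.full(20, 3.0)]
        )
        plane = mm.best_fit_plane(pts)
        assert np.abs(plane.signed_distance(pts)).max() < 1e-9

    def test_saddle_symmetric_plane(self, saddle_annulus):
        pts = saddle_annulus.evaluate(np.linspace(0, 2 * np.pi, 720, endpoint=False))
        plane = mm.best_fit_plane(pts)
        assert abs(np.dot(plane.normal, [0, 0, 1])) > 1 - 1e-9
        assert abs(plane.point[2]) < 1e-6

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 3))
        p1 = mm.best_fit_plane(pts)
        p2 = mm.best_fit_plane(pts + [1.0, 2.0, 3.0])
        assert p2.point == pytest.approx(p1.point + [1.0, 2.0, 3.0])
        assert abs(np.dot(p1.normal, p2.normal)) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            mm.best_fit_plane(pts)


class TestPlanarMetrics:
    def _fit_plane(self, spec):
        lm = mm.landmarks_from_phantom(spec)
        fit = mm.fit_annulus(lm)
        axis = mm.define_long_axis(lm)
        plane = mm.best_fit_plane(
            fit.polyline, orient_with=-axis.direction,
            weights=mm._arc_weights(fit.polyline),
        )
        return lm, fit, plane

    def test_circle_perimeters(self, flat_spec):
        _, fit, plane = self._fit_plane(flat_spec)
        l2d, l3d = mm.compute_perimeters(fit, plane)
        assert l2d == pytest.approx(125.66, abs=0.05)
        assert l3d == pytest.approx(125.66, abs=0.05)

    def test_saddle_l3d_exceeds_l2d(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(annulus=saddle_annulus, tenting_profile="flat")
        _, fit, plane = self._fit_plane(spec)
        l2d, l3d = mm.compute_perimeters(fit, plane)
        assert l3d > l2d

    def test_ellipse_perimeter_oracle(self, ellipse_annulus):
        spec = sv.LeafletPhantomSpec(annulus=ellipse_annulus, tenting_profile="flat")
        _, fit, plane = self._fit_plane(spec)
        l2d, _ = mm.compute_perimeters(fit, plane)
        assert l2d == pytest.approx(ELLIPSE_PERIMETER, rel=0.002)

    def test_sampling_refinement_converged(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(annulus=saddle_annulus, tenting_profile="flat")
        lm = mm.landmarks_from_phantom(spec)
        f1 = mm.fit_annulus(lm, n_samples=360)
        f2 = mm.fit_annulus(lm, n_samples=720)
        plane = mm.best_fit_plane(f1.polyline)
        for a, b in zip(mm.compute_perimeters(f1, plane), mm.compute_perimeters(f2, plane)):
            assert abs(a - b) / b < 1e-4

    def test_circle_areas(self, flat_spec):
        _, fit, plane = self._fit_plane(flat_spec)
        a2d, a3d = mm.compute_areas(fit, plane)
        assert a2d == pytest.approx(1256.64, rel=1e-3)
        assert a3d == pytest.approx(1256.64, rel=1e-3)

    def test_saddle_a3d_exceeds_a2d(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(annulus=saddle_annulus, tenting_profile="flat")
        _, fit, plane = self._fit_plane(spec)
        a2d, a3d = mm.compute_areas(fit, plane)
        assert a3d > a2d

    def test_ellipse_area_closed_form(self, ellipse_annulus):
        spec = sv.LeafletPhantomSpec(annulus=ellipse_annulus, tenting_profile="flat")
        _, fit, plane = self._fit_plane(spec)
        a2d, _ = mm.compute_areas(fit, plane)
        assert a2d == pytest.approx(np.pi * 25.1 * 21.55, rel=1e-3)

    def test_circle_diameters(self, flat_spec):
        _, fit, plane = self._fit_plane(flat_spec)
        dmax, dmin = mm.compute_diameters(fit, plane)
        assert dmax == pytest.approx(40.0, rel=1e-3)
        assert dmin == pytest.approx(40.0, rel=1e-3)

    def test_ellipse_diameters(self, ellipse_annulus):
        spec = sv.LeafletPhantomSpec(annulus=ellipse_annulus, tenting_profile="flat")
        _, fit, plane = self._fit_plane(spec)
        dmax, dmin = mm.compute_diameters(fit, plane)
        assert dmax == pytest.approx(50.2, rel=0.005)
        assert dmin == pytest.approx(43.1, rel=0.005)

    def test_diameters_rotation_invariant(self, ellipse_annulus):
        spec = sv.LeafletPhantomSpec(annulus=ellipse_annulus, tenting_profile="flat")
        lm = mm.landmarks_from_phantom(spec)
        d_ref = mm.compute_diameters(mm.fit_annulus(lm))
        ang = np.deg2rad(37.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1.0],
            ]
        )
        lm2 = mm.AnnulusLandmarks(
            angles_deg=lm.angles_deg,
            annular=lm.annular @ rot.T,
            free_margin=lm.free_margin @ rot.T,
        )
        d_rot = mm.compute_diameters(mm.fit_annulus(lm2))
        assert d_rot[0] == pytest.approx(d_ref[0], rel=1e-4)
        assert d_rot[1] == pytest.approx(d_ref[1], rel=1e-4)


class TestLeafletSurface:
    def _pipeline(self, spec):
        lm = mm.landmarks_from_phantom(spec)
        fit = mm.fit_annulus(lm)
        axis = mm.define_long_axis(lm)
        plane = mm.best_fit_plane(
            fit.polyline, orient_with=-axis.direction,
            weights=mm._arc_weights(fit.polyline),
        )
        return lm, fit, plane

    def test_flat_mesh_in_plane(self, flat_spec):
        lm, fit, plane = self._pipeline(flat_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        assert np.abs(plane.signed_distance(mesh.vertices)).max() < 1e-6

    def test_paraboloid_vertices_on_surface(self, paraboloid_spec):
        lm, fit, plane = self._pipeline(paraboloid_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        # vertex depth must match the paraboloid profile h (1 - (rho/r)^2)
        xy = mesh.vertices[:, :2]
        rho = np.linalg.norm(xy, axis=1)
        expected = -9.549 * np.clip(1 - (rho / 20.0) ** 2, 0, None)
        assert np.abs(mesh.vertices[:, 2] - expected).max() < 0.1

    def test_free_margin_points_in_mesh(self, paraboloid_spec):
        lm, fit, plane = self._pipeline(paraboloid_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        for p in lm.free_margin:
            d = np.linalg.norm(mesh.vertices - p, axis=1).min()
            assert d < 1e-9

    def test_all_vertices_referenced(self, paraboloid_spec):
        lm, fit, plane = self._pipeline(paraboloid_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        assert set(np.unique(mesh.triangles)) == set(range(len(mesh.vertices)))

    def test_flat_mesh_zero_tenting(self, flat_spec):
        lm, fit, plane = self._pipeline(flat_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        assert mm.tenting_volume(mesh, plane) == pytest.approx(0.0, abs=1e-9)

    def test_paraboloid_tenting_volume(self, paraboloid_spec):
        lm, fit, plane = self._pipeline(paraboloid_spec)
        mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
        tvol = mm.tenting_volume(mesh, plane)
        assert tvol == pytest.approx(6.0, rel=0.02)

    def test_tenting_scales_linearly_with_depth(self, circle_annulus):
        vols = []
        for h in (4.0, 8.0):
            spec = sv.LeafletPhantomSpec(
                annulus=circle_annulus, tenting_profile="paraboloid", tenting_depth=h
            )
            lm, fit, plane = self._pipeline(spec)
            mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
            vols.append(mm.tenting_volume(mesh, plane))
        assert vols[1] == pytest.approx(2 * vols[0], rel=1e-6)

    def test_tenting_monotone_in_depth(self, circle_annulus):
        prev = -1.0
        for h in (2.0, 5.0, 9.0):
            spec = sv.LeafletPhantomSpec(
                annulus=circle_annulus, tenting_profile="cone", tenting_depth=h
            )
            lm, fit, plane = self._pipeline(spec)
            mesh = mm.reconstruct_leaflet_surface(lm, fit, plane)
            v = mm.tenting_volume(mesh, plane)
            assert v > prev
            prev = v


class TestRunMorphometry:
    def test_circle_flat_closed_forms(self, flat_spec):
        res = mm.run_morphometry(flat_spec)
        assert res.L2D == pytest.approx(125.66, abs=0.1)
        assert res.L3D == pytest.approx(125.66, abs=0.1)
        assert res.A2D == pytest.approx(1256.64, rel=2e-3)
        assert res.A3D == pytest.approx(1256.64, rel=2e-3)
        assert res.Dmax == pytest.approx(40.0, rel=1e-3)
        assert res.Dmin == pytest.approx(40.0, rel=1e-3)
        assert res.Tvol == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, paraboloid_spec):
        r1 = mm.run_morphometry(paraboloid_spec).as_dict()
        r2 = mm.run_morphometry(paraboloid_spec).as_dict()
        assert r1 == r2

    def test_result_invariants(self, saddle_annulus):
        spec = sv.LeafletPhantomSpec(
            annulus=saddle_annulus, tenting_profile="paraboloid", tenting_depth=8.0
        )
        res = mm.run_morphometry(spec)
        assert res.L3D >= res.L2D
        assert res.A3D >= res.A2D
        assert res.Dmax >= res.Dmin
        assert res.Tvol >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed, saddle_annulus):
        spec = sv.LeafletPhantomSpec(
            annulus=saddle_annulus, tenting_profile="paraboloid", tenting_depth=8.0
        )
        lm = mm.landmarks_from_phantom(spec)
        ref = mm.run_morphometry(lm).as_dict()
        rot, trans = rigid_transform(np.random.default_rng(seed))
        lm2 = mm.AnnulusLandmarks(
            angles_deg=lm.angles_deg,
            annular=lm.annular @ rot.T + trans,
            free_margin=lm.free_margin @ rot.T + trans,
            traces=[t @ rot.T + trans for t in lm.traces],
        )
        moved = mm.run_morphometry(lm2).as_dict()
        for k, v in ref.items():
            if abs(v) < 1e-9:
                assert abs(moved[k]) < 1e-9
            else:
                assert abs(moved[k] - v) / abs(v) < 1e-3
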