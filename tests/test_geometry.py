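import math
import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

from cochleagen.equations import NormalisationContext, denormalize, parameter_set
from cochleagen.geometry import (
    BoundaryLandmarks,
    GeometryError,
    assemble_cross_section,
    basal_canal_width,
    bezier_point,
    build_spiral_ligament,
    construct_internal_landmarks,
    line_outline_intersection,
)
from cochleagen.synth import canonical_boundary

from conftest import de_casteljau


def _quiet_construct(boundary, params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return construct_internal_landmarks(boundary, params)


class TestBasalCanalWidth:
    def test_distance_to_medial_midpoint(self):
        bl = canonical_boundary(1.0).points.copy()
        bl.update(LS=(0.0, 0.0), MSVS=(2.0, 1.0), MSTS=(2.0, -1.0))
        assert basal_canal_width(BoundaryLandmarks(bl)) == pytest.approx(2.0)

    def test_translation_invariance(self, basal_boundary):
        shifted = basal_boundary.transformed(lambda p: p + np.array([5.0, -3.0]))
        assert basal_canal_width(shifted) == pytest.approx(
            basal_canal_width(basal_boundary)
        )

    def test_degenerate_rejected(self):
        bl = canonical_boundary(1.0).points.copy()
        bl.update(LS=(0.0, 0.0), MSVS=(0.0, 0.0), MSTS=(0.0, 0.0))
        with pytest.raises(GeometryError):
            basal_canal_width(BoundaryLandmarks(bl))


class TestBezier:
    def test_endpoint_interpolation(self):
        ctrl = np.array([[0, 0], [1, 2], [3, 3], [4, 1], [5, 0]], float)
        np.testing.assert_allclose(bezier_point(ctrl, 0.0), ctrl[0])
        np.testing.assert_allclose(bezier_point(ctrl, 1.0), ctrl[-1])

    def test_matches_de_casteljau_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            ctrl = rng.normal(size=(5, 2))
            for t in rng.uniform(0, 1, size=7):
                expect = de_casteljau(ctrl, t)
                np.testing.assert_allclose(
                    bezier_point(ctrl, t), expect, atol=1e-12
                )

    def test_parameter_out_of_range_rejected(self):
        ctrl = np.zeros((5, 2))
        with pytest.raises(ValueError):
            bezier_point(ctrl, 1.2)
        with pytest.raises(ValueError):
            bezier_point(ctrl, -0.1)


class TestLineOutlineIntersection:
    def test_agrees_with_brute_force_sampling(self, basal_boundary):
        outline = basal_boundary.outline()
        origin = np.array([1.0, 0.0])
        dense = outline.sample(200_000)
        dense = np.vstack([dense, dense[:1]])
        for angle in np.linspace(0.0, 2 * math.pi, 9, endpoint=False):
            hit = line_outline_intersection(origin, angle, outline)
            d = np.array([math.cos(angle), math.sin(angle)])
            # brute force: nearest polyline crossing along the ray
            rel = dense - origin
            proj = rel @ d
            perp = rel @ np.array([-d[1], d[0]])
            sign = np.sign(perp)
            idx = np.nonzero((sign[:-1] != sign[1:]) & (proj[:-1] > 0))[0]
            assert len(idx) > 0
            ts = []
            for i in idx:
                a, b = dense[i], dense[i + 1]
                e = b - a
                den = d[0] * e[1] - d[1] * e[0]
                w = a - origin
                t = (w[0] * e[1] - w[1] * e[0]) / den
                ts.append(t)
            t_bf = min(t for t in ts if t > 0)
            np.testing.assert_allclose(hit, origin + t_bf * d, atol=1e-6)

    def test_origin_outside_rejected(self, basal_boundary):
        outline = basal_boundary.outline()
        with pytest.raises(GeometryError):
            line_outline_intersection([10.0, 10.0], 0.0, outline)


class TestConstruction:
    def test_zero_wa_places_a_at_ls_height(self, basal_boundary):
        ps = parameter_set(0.0).with_value("Wa", 0.0)
        mm = denormalize(ps, NormalisationContext(2.0))
        lm = _quiet_construct(basal_boundary, mm)
        assert lm["a"][1] == pytest.approx(basal_boundary["LS"][1], abs=1e-9)

    def test_zero_alpha_gives_horizontal_lamina(self, basal_boundary):
        ps = parameter_set(0.0).with_value("alpha", 0.0)
        mm = denormalize(ps, NormalisationContext(2.0))
        lm = _quiet_construct(basal_boundary, mm)
        assert lm["g"][1] == pytest.approx(lm["a"][1], abs=1e-9)

    def test_k_between_a_and_h_on_the_lamina_line(self, basal_landmarks):
        a, k, h = (basal_landmarks[n] for n in "akh")
        u = (h - a) / np.linalg.norm(h - a)
        ta, tk, th = 0.0, (k - a) @ u, (h - a) @ u
        assert ta < tk < th
        # k lies on the line through a and h
        perp = abs((k - a)[0] * u[1] - (k - a)[1] * u[0])
        assert perp < 1e-9

    def test_landmarks_annotated_with_parameters(self, basal_landmarks):
        assert "Wa" in basal_landmarks.provenance["a"]
        assert "alpha" in basal_landmarks.provenance["g"]
        assert "Hsg" in basal_landmarks.provenance["i"]

    def test_normalised_parameters_rejected(self, basal_boundary):
        with pytest.raises(GeometryError, match="mm"):
            construct_internal_landmarks(basal_boundary, parameter_set(0.0))


class TestLigamentCurves:
    def _landmarks_with_mild_midpoints(self, basal_boundary):
        # small offsets keep the mid-landmarks well clear of the caps so
        # the t=0.5 interpolation can be asserted exactly
        ps = (
            parameter_set(0.0)
            .with_value("Hkn", 0.20)
            .with_value("phi_en", 0.04)
            .with_value("Hkm", 0.25)
            .with_value("phi_fm", 0.03)
        )
        mm = denormalize(ps, NormalisationContext(2.0))
        return _quiet_construct(basal_boundary, mm)

    def test_endpoints_and_middle_interpolation(self, basal_boundary):
        lm = self._landmarks_with_mild_midpoints(basal_boundary)
        curve_ek, curve_kd = build_spiral_ligament(lm)
        np.testing.assert_allclose(curve_ek(0.0), lm["c"], atol=1e-12)
        np.testing.assert_allclose(curve_ek(1.0), lm["k"], atol=1e-12)
        np.testing.assert_allclose(curve_ek(0.5), lm["e"], atol=1e-9)
        np.testing.assert_allclose(curve_kd(0.5), lm["f"], atol=1e-9)

    def test_zero_perpendicular_offset_places_e_on_chord(self, basal_boundary):
        ps = (
            parameter_set(0.0)
            .with_value("Hkn", 0.15)
            .with_value("phi_en", 0.0)
        )
        mm = denormalize(ps, NormalisationContext(2.0))
        lm = _quiet_construct(basal_boundary, mm)
        k, c, e = lm["k"], lm["c"], lm["e"]
        u = (c - k) / np.linalg.norm(c - k)
        along = (e - k) @ u
        perp = abs((e - k)[0] * u[1] - (e - k)[1] * u[0])
        assert perp < 1e-9
        assert along == pytest.approx(0.30, abs=1e-9)  # Hkn * 2 mm


class TestAssembly:
    def test_region_and_interface_cardinality(self, basal_geometry):
        names = sorted(r.name for r in basal_geometry.regions)
        assert names == sorted(
            [
                "scala_tympani", "scala_vestibuli", "scala_media",
                "spiral_ligament", "spiral_lamina_nerve", "modiolar_bone",
            ]
        )
        assert sorted(f.name for f in basal_geometry.interfaces) == sorted(
            [
                "temporal_bone", "basilar_membrane",
                "reissner_membrane", "stria_vascularis",
            ]
        )

    def test_regions_simple_and_disjoint(self, basal_geometry):
        polys = [(r.name, Polygon(r.boundary)) for r in basal_geometry.regions]
        for name, poly in polys:
            assert poly.is_valid, name
        for i, (n1, p1) in enumerate(polys):
            for n2, p2 in polys[i + 1:]:
                assert p1.intersection(p2).area <= 1e-6 * min(p1.area, p2.area)

    def test_basilar_membrane_runs_from_a_through_k(self, basal_geometry):
        bm = basal_geometry.interface("basilar_membrane").path
        lm = basal_geometry.internal
        np.testing.assert_allclose(bm[0], lm["a"], atol=1e-12)
        assert any(np.allclose(p, lm["k"], atol=1e-12) for p in bm)

    def test_interface_surface_resistance_positive(self, basal_geometry):
        for f in basal_geometry.interfaces:
            assert f.surface_resistance > 0

    @pytest.mark.parametrize("theta", [0.0, 90.0, 180.0, 270.0, 360.0,
                                       450.0, 540.0, 630.0, 720.0])
    def test_full_angular_range_assembles(self, theta):
        bl = canonical_boundary(2.0)
        ps = parameter_set(theta)
        mm = denormalize(ps, NormalisationContext(basal_canal_width(bl)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lm = construct_internal_landmarks(bl, mm)
            geom = assemble_cross_section(bl, lm, mm, theta)
        assert len(geom.regions) == 6
        assert len(geom.interfaces) == 4


class TestEquivariance:
    def _construct(self, boundary, width):
        ps = parameter_set(0.0)
        mm = denormalize(ps, NormalisationContext(width))
        return _quiet_construct(boundary, mm)

    def test_scale_equivariance(self, basal_boundary):
        lm1 = self._construct(basal_boundary, 2.0)
        s = 3.7
        scaled = basal_boundary.transformed(lambda p: s * p)
        lm2 = self._construct(scaled, 2.0 * s)
        for name in lm1.names:
            np.testing.assert_allclose(
                lm2[name], s * lm1[name], rtol=1e-9, atol=1e-9
            )

    def test_rigid_motion_equivariance(self, basal_boundary):
        lm1 = self._construct(basal_boundary, 2.0)
        ang = 0.7
        R = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        t = np.array([4.2, -1.3])
        moved = basal_boundary.transformed(lambda p: R @ p + t)
        lm2 = self._construct(moved, 2.0)
        for name in lm1.names:
            np.testing.assert_allclose(
                lm2[name], R @ lm1[name] + t, atol=1e-8
            )

    def test_mirror_equivariance(self, basal_boundary):
        # a mirrored (contralateral) boundary produces mirrored landmarks
        M = np.array([[-1.0, 0.0], [0.0, 1.0]])
        lm1 = self._construct(basal_boundary, 2.0)
        mirrored = basal_boundary.transformed(lambda p: M @ p)
        lm2 = self._construct(mirrored, 2.0)
        for name in lm1.names:
            np.testing.assert_allclose(lm2[name], M @ lm1[name], atol=1e-8)
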