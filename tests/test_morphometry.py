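import numpy as np
import pytest
from dataclasses import replace

from oomorph.morphometry import (
    MeasurementError,
    RegionGeometry,
    measure_regions,
    polygon_geometry,
    region_geometry,
    relative_features,
    shape_descriptors,
)
from oomorph.phantom import PhantomSpec, generate_phantom, truth_geometry, \
    _sample_geometry

from conftest import ellipse_spec


def ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def analytic_geom(a: float, b: float, region="ooplasm") -> RegionGeometry:
    return RegionGeometry(region=region, area=np.pi * a * b,
                          perimeter=ramanujan_perimeter(a, b),
                          major_axis=2 * a, minor_axis=2 * b,
                          hull_area=np.pi * a * b)


class TestRegionGeometry:
    @pytest.mark.parametrize("a,b,rot", [(50, 50, 0.0), (60, 50, 0.0),
                                         (60, 50, 0.6), (75, 40, 1.1)])
    def test_raster_ellipse_oracle(self, a, b, rot):
        """Measured A, Lp, Lmaj, Lmin on zero-jitter rasterized ellipses
        match pi*a*b / Ramanujan / 2a / 2b within raster tolerances."""
        spec = replace(ellipse_spec(a, b), rotation=rot)
        _, labels, _ = generate_phantom(spec, 0)
        g = region_geometry(labels, "ooplasm")
        assert g.area == pytest.approx(np.pi * a * b, rel=0.015)
        assert g.perimeter == pytest.approx(ramanujan_perimeter(a, b), rel=0.02)
        assert g.major_axis == pytest.approx(2 * a, rel=0.01)
        assert g.minor_axis == pytest.approx(2 * b, rel=0.01)

    def test_circle_axes(self):
        _, labels, _ = generate_phantom(ellipse_spec(50, 50), 0)
        g = region_geometry(labels, "ooplasm")
        assert g.major_axis == pytest.approx(100, rel=0.01)
        assert g.minor_axis == pytest.approx(100, rel=0.01)

    def test_convex_region_hull_equals_area(self):
        _, labels, _ = generate_phantom(ellipse_spec(60, 50), 0)
        g = region_geometry(labels, "ooplasm")
        assert g.hull_area == pytest.approx(g.area, rel=0.005)

    def test_filled_convention_ordering(self):
        _, labels, _ = generate_phantom(PhantomSpec(), 5)
        geoms = measure_regions(labels)
        assert geoms["ooplasm"].area <= geoms["pvs"].area <= geoms["zp"].area

    def test_absent_region_rejected(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[20:40, 20:40] = 1
        with pytest.raises(MeasurementError):
            region_geometry(labels, "pvs")

    def test_tiny_region_rejected(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[30:33, 30:33] = 1
        with pytest.raises(MeasurementError, match="50"):
            region_geometry(labels, "ooplasm")

    def test_invalid_geometry_rejected(self):
        with pytest.raises(MeasurementError):
            RegionGeometry("ooplasm", area=-1, perimeter=10, major_axis=5,
                           minor_axis=4, hull_area=2)
        with pytest.raises(MeasurementError):
            RegionGeometry("ooplasm", area=1, perimeter=10, major_axis=3,
                           minor_axis=4, hull_area=2)


class TestShapeDescriptors:
    def test_analytic_circle_is_one_everywhere(self):
        g = RegionGeometry("ooplasm", area=np.pi * 50**2,
                           perimeter=2 * np.pi * 50, major_axis=100,
                           minor_axis=100, hull_area=np.pi * 50**2)
        d = shape_descriptors(g)
        assert d.circularity == pytest.approx(1.0, abs=1e-12)
        assert d.roundness == pytest.approx(1.0, abs=1e-12)
        assert d.aspect_ratio == 1.0
        assert d.solidity == 1.0

    def test_two_to_one_ellipse_aspect(self):
        d = shape_descriptors(analytic_geom(60, 30))
        assert d.aspect_ratio == pytest.approx(2.0)

    def test_notched_square_solidity(self):
        """Square with a rectangular notch of 4% of its area: S = 0.96,
        against exact polygon areas of the shape and its convex hull."""
        # 100x100 square, 20x20 notch cut at the middle of the top edge
        pts = np.array([(0, 0), (0, 100), (100, 100), (100, 60),
                        (80, 60), (80, 40), (100, 40), (100, 0)], dtype=float)
        g = polygon_geometry(pts, region="ooplasm")
        assert g.area == pytest.approx(10000 - 400)
        assert g.hull_area == pytest.approx(10000)
        assert shape_descriptors(g).solidity == pytest.approx(0.96)

    def test_degenerate_geometry_raises(self):
        g = analytic_geom(60, 50)
        bad = RegionGeometry("ooplasm", area=g.area, perimeter=g.perimeter,
                             major_axis=g.major_axis, minor_axis=g.minor_axis,
                             hull_area=g.hull_area)
        object.__setattr__(bad, "perimeter", 0.0)
        with pytest.raises(MeasurementError):
            shape_descriptors(bad)


class TestRelativeFeatures:
    def test_identity_ratios(self):
        g = analytic_geom(60, 50)
        geoms = {r: replace(g, region=r) for r in ("ooplasm", "pvs", "zp")}
        rel = relative_features(geoms)
        assert len(rel) == 12
        assert all(v == pytest.approx(1.0) for v in rel.values())

    def test_analytic_area_ratio(self):
        geoms = {"ooplasm": analytic_geom(55, 50, "ooplasm"),
                 "pvs": analytic_geom(60, 55, "pvs"),
                 "zp": analytic_geom(70, 65, "zp")}
        rel = relative_features(geoms)
        assert rel["ooplasm_vs_pvs_area_ratio"] == pytest.approx(2750 / 3300)
        assert rel["ooplasm_vs_pvs_major_axis_ratio"] == pytest.approx(55 / 60)

    def test_hull_area_never_ratioed(self):
        geoms = {r: analytic_geom(60, 50, r) for r in ("ooplasm", "pvs", "zp")}
        assert not any("hull" in k for k in relative_features(geoms))

    def test_missing_region_rejected(self):
        with pytest.raises(MeasurementError, match="zp"):
            relative_features({"ooplasm": analytic_geom(55, 50),
                               "pvs": analytic_geom(60, 55)})

    def test_population_mean_recovers_generator_ratio(self):
        """Seed-7 population of 500: mean ooplasm-vs-ZP major-axis ratio
        within 0.02 of the generator's configured 0.70."""
        rng = np.random.default_rng(7)
        vals = [relative_features(truth_geometry(
            _sample_geometry(PhantomSpec(), rng)))["ooplasm_vs_zp_major_axis_ratio"]
            for _ in range(500)]
        assert np.mean(vals) == pytest.approx(0.70, abs=0.02)

    def test_monotone_nesting_ordering(self):
        _, labels, _ = generate_phantom(PhantomSpec(), 17)
        rel = relative_features(measure_regions(labels))
        for m in ("major_axis", "minor_axis", "perimeter", "area"):
            assert rel[f"ooplasm_vs_zp_{m}_ratio"] <= rel[f"ooplasm_vs_pvs_{m}_ratio"]


class TestInvariances:
    def test_rotation_invariance(self, zero_jitter_spec):
        base = replace(zero_jitter_spec, zp_outer_axes=(85.0, 75.0))
        ref = None
        for rot in (0.0, 0.4, 0.9, 1.4):
            _, labels, _ = generate_phantom(replace(base, rotation=rot), 0)
            d = shape_descriptors(region_geometry(labels, "ooplasm"))
            rel = relative_features(measure_regions(labels))
            vec = np.array([d.aspect_ratio, d.circularity, d.roundness,
                            d.solidity, rel["ooplasm_vs_zp_major_axis_ratio"]])
            if ref is None:
                ref = vec
            else:
                assert np.allclose(vec, ref, rtol=0.01)

    def test_scale_invariance(self, zero_jitter_spec):
        """Rendering the same analytic phantom at 2x resolution changes every
        dimensionless descriptor and ratio by less than the raster tolerance."""
        small = replace(zero_jitter_spec, zp_outer_axes=(60.0, 52.0),
                        zp_thickness=12.0, image_size=160)
        big = replace(zero_jitter_spec, zp_outer_axes=(120.0, 104.0),
                      zp_thickness=24.0, image_size=320)
        vals = []
        for spec in (small, big):
            _, labels, _ = generate_phantom(spec, 0)
            d = shape_descriptors(region_geometry(labels, "ooplasm"))
            rel = relative_features(measure_regions(labels))
            vals.append(np.array([d.aspect_ratio, d.circularity, d.roundness,
                                  d.solidity] + [rel[k] for k in sorted(rel)]))
        assert np.allclose(vals[0], vals[1], rtol=0.015)
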