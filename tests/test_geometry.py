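import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from windkite import geometry as geo


angles = st.floats(min_value=-720.0, max_value=720.0,
                   allow_nan=False, allow_infinity=False)


class TestGreatCircleDistance:
    def test_identity_is_zero(self):
        assert geo.great_circle_distance(36.0, -5.6, 36.0, -5.6) == 0.0

    def test_against_independent_spherical_formula(self):
        # Vincenty arctan form on the sphere: an independent great-circle
        # routine, algebraically distinct from the haversine
        rng = np.random.default_rng(42)
        for _ in range(100):
            lat1, lat2 = rng.uniform(-80, 80, 2)
            lon1, lon2 = rng.uniform(-179, 179, 2)
            p1, p2 = np.radians([lat1, lat2])
            dl = np.radians(lon2 - lon1)
            num = np.hypot(np.cos(p2) * np.sin(dl),
                           np.cos(p1) * np.sin(p2)
                           - np.sin(p1) * np.cos(p2) * np.cos(dl))
            den = (np.sin(p1) * np.sin(p2)
                   + np.cos(p1) * np.cos(p2) * np.cos(dl))
            expected = geo.EARTH_RADIUS_M * np.arctan2(num, den)
            got = geo.great_circle_distance(lat1, lon1, lat2, lon2)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-6)

    def test_short_east_west_arc(self):
        # 0.01 deg of longitude at 36 N is about 0.9 km
        d = geo.great_circle_distance(36.0, -5.6, 36.0, -5.59)
        assert d == pytest.approx(899.7, rel=0.01)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(7)
        a = rng.uniform([-80, -179], [80, 179], size=(100, 2))
        b = rng.uniform([-80, -179], [80, 179], size=(100, 2))
        d_ab = geo.great_circle_distance(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d_ba = geo.great_circle_distance(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d_ab, d_ba, rtol=1e-12)
        assert np.all(d_ab >= 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="lat1"):
            geo.great_circle_distance(np.nan, 0.0, 1.0, 1.0)


class TestInitialBearing:
    def test_cardinal_directions(self):
        assert geo.initial_bearing(36.0, -5.6, 36.1, -5.6) == pytest.approx(0.0)
        east = geo.initial_bearing(36.0, -5.6, 36.0, -5.59)
        assert east == pytest.approx(90.0, abs=0.1)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            geo.initial_bearing(36.0, -5.6, 36.0, -5.6)

    def test_reverse_bearing_differs_by_180(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lat1 = rng.uniform(-60, 60)
            lon1 = rng.uniform(-170, 170)
            lat2 = lat1 + rng.uniform(-0.02, 0.02)
            lon2 = lon1 + rng.uniform(-0.02, 0.02)
            if lat1 == lat2 and lon1 == lon2:
                continue
            fwd = geo.initial_bearing(lat1, lon1, lat2, lon2)
            back = geo.initial_bearing(lat2, lon2, lat1, lon1)
            diff = geo.angular_deviation(fwd, back + 180.0)
            assert diff < 0.05  # nearby points: negligible convergence effect


class TestAngularDeviation:
    @pytest.mark.parametrize("h, b, expected", [
        (0.0, 0.0, 0.0),
        (350.0, 10.0, 20.0),
        (90.0, 300.0, 150.0),
        (0.0, 180.0, 180.0),
    ])
    def test_examples(self, h, b, expected):
        assert geo.angular_deviation(h, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(h=angles, b=angles)
    def test_symmetric_bounded_and_periodic(self, h, b):
        d = geo.angular_deviation(h, b)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(geo.angular_deviation(b, h), abs=1e-9)
        assert d == pytest.approx(geo.angular_deviation(h + 360.0, b), abs=1e-6)
        assert d == pytest.approx(geo.angular_deviation(h, b - 720.0), abs=1e-6)


class TestFacingIndicator:
    def test_strict_60_degree_boundary(self):
        assert geo.facing_indicator(0.0) == 1
        assert geo.facing_indicator(59.99) == 1
        assert geo.facing_indicator(60.0) == 0
        assert geo.facing_indicator(180.0) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geo.facing_indicator(-1.0)
        with pytest.raises(ValueError):
            geo.facing_indicator(181.0)

    def test_uniform_headings_face_one_third_of_the_time(self):
        # the 120-degree facing cone covers a third of the circle
        rng = np.random.default_rng(0)
        headings = rng.uniform(0.0, 360.0, size=100_000)
        dev = geo.angular_deviation(headings, 0.0)
        phat = geo.facing_indicator(dev).mean()
        se = np.sqrt((1 / 3) * (2 / 3) / 100_000)
        assert abs(phat - 1.0 / 3.0) < 3 * se


class TestWindComponent:
    @pytest.mark.parametrize("speed, dfrom, bearing, expected", [
        (10.0, 270.0, 90.0, 10.0),   # westerly pushes due east
        (10.0, 270.0, 270.0, -10.0),  # opposed
        (10.0, 270.0, 0.0, 0.0),      # orthogonal
    ])
    def test_examples(self, speed, dfrom, bearing, expected):
        got = geo.wind_component_towards(speed, dfrom, bearing)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            geo.wind_component_towards(-1.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(s=st.floats(0, 50), d=angles, b=angles)
    def test_antisymmetric_and_bounded(self, s, d, b):
        c = geo.wind_component_towards(s, d, b)
        assert abs(c) <= s + 1e-9
        assert c == pytest.approx(
            -geo.wind_component_towards(s, d, b + 180.0), abs=1e-6)

    def test_matches_vector_arithmetic(self):
        # independent oracle: explicit 2-D wind vector projected on the
        # unit bearing vector
        rng = np.random.default_rng(12)
        for _ in range(200):
            s = rng.uniform(0, 30)
            d = rng.uniform(0, 360)
            b = rng.uniform(0, 360)
            to = np.radians(d + 180.0)
            wind_vec = s * np.array([np.sin(to), np.cos(to)])  # (east, north)
            unit_b = np.array([np.sin(np.radians(b)), np.cos(np.radians(b))])
            assert geo.wind_component_towards(s, d, b) == pytest.approx(
                wind_vec @ unit_b, abs=1e-9)


class TestTurbineHeight:
    def test_absent_hub_uses_ratio_rule(self):
        assert geo.max_turbine_height(80.0) == 120.0

    def test_hub_plus_radius(self):
        assert geo.max_turbine_height(80.0, 80.0) == 120.0
        assert geo.max_turbine_height(60.0, 100.0) == 130.0

    def test_nonpositive_rotor_rejected(self):
        with pytest.raises(ValueError):
            geo.max_turbine_height(0.0)


class TestHeightClass:
    @pytest.mark.parametrize("h, H, expected", [
        (100.0, 120.0, geo.HeightClass.LOW),
        (120.0, 120.0, geo.HeightClass.LOW),     # inclusive at H
        (120.1, 120.0, geo.HeightClass.MEDIUM),
        (240.0, 120.0, geo.HeightClass.MEDIUM),  # inclusive at 2H
        (300.0, 120.0, geo.HeightClass.HIGH),
        (-5.0, 120.0, geo.HeightClass.LOW),      # GPS error clamps to LOW
    ])
    def test_boundaries(self, h, H, expected):
        assert geo.height_class(h, H) is expected

    def test_exhaustive_and_exclusive_on_grid(self):
        heights = np.linspace(-10.0, 500.0, 201)
        for H in (60.0, 120.0, 150.0):
            classes = geo.height_class(heights, H)
            assert set(np.unique(classes)) <= {"low", "medium", "high"}
            assert np.all((classes == "low") | (classes == "medium")
                          | (classes == "high"))

    def test_invalid_turbine_height_rejected(self):
        with pytest.raises(ValueError):
            geo.height_class(10.0, 0.0)


class TestDomainTypes:
    def test_track_point_validation(self):
        with pytest.raises(ValueError, match="heading"):
            geo.TrackPoint("b1", np.datetime64("2013-08-15T10:00"),
                           -5.6, 36.0, 50.0, 5.0, 360.0)
        with pytest.raises(ValueError, match="lat"):
            geo.TrackPoint("b1", np.datetime64("2013-08-15T10:00"),
                           -5.6, 96.0, 50.0, 5.0, 10.0)

    def test_turbine_max_height_property(self):
        t = geo.Turbine("t1", -5.6, 36.0, rotor_diameter=80.0)
        assert t.max_height == 120.0

    def test_wind_record_validation(self):
        with pytest.raises(ValueError):
            geo.WindRecord(np.datetime64("2013-08-15T10:00"), 370.0, 5.0)
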