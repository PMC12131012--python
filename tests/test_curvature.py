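"""Curvature statistics: cleaning rules, trapezoid area, inter-sensor angles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from parabospine.core import BackplateGeometry, DistanceStream, GravitySegment
from parabospine.curvature import (
    clamp_missing_segment,
    enclosed_area,
    exclude_below_sips,
    intersensor_angles,
    normalize_area,
    parabola_order_check,
    repair_bra_sensor,
    window_mean_profile,
)

from conftest import make_profile

LONG = BackplateGeometry.from_backplate("long")
SHORT = BackplateGeometry.from_backplate("short")


def oracle_angle(d1, d2, d3, spacing):
    """Independent planar-geometry oracle: atan2-based angle magnitude plus
    a cross-product side test against the chord."""
    p1 = np.array([d1, 0.0])
    p2 = np.array([d2, spacing])
    p3 = np.array([d3, 2 * spacing])
    u, v = p1 - p2, p3 - p2
    cross = u[0] * v[1] - u[1] * v[0]
    raw = np.degrees(np.arctan2(abs(cross), np.dot(u, v)))
    side = d2 - (d1 + d3) / 2.0
    if side > 0:
        return raw
    if side < 0:
        return 360.0 - raw
    return 180.0


def _stream(values, times=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[0]) if times is None else np.asarray(times, float)
    return DistanceStream(
        time_s=t, values_mm=values, accel_gz=np.ones(values.shape[0]), sample_rate_hz=1.0
    )


WINDOW = GravitySegment("earth", 1, "pre_earth", 0.0, 9.0)


class TestWindowMeanProfile:
    def test_constant_stream(self):
        prof = window_mean_profile(_stream(np.full((10, 15), 50.0)), WINDOW)
        assert np.allclose(prof.values_mm, 50.0)
        assert not prof.included[0]  # topmost sensor always excluded

    def test_symmetric_drift_averages_out(self):
        ramp = np.linspace(49, 51, 10)[:, None] * np.ones((1, 15))
        prof = window_mean_profile(_stream(ramp), WINDOW)
        assert np.allclose(prof.values_mm, 50.0)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(20, 100, size=(40, 15))
        t = np.linspace(0, 39, 40)
        win = GravitySegment("micro", 2, "micro", 10.0, 25.0)
        prof = window_mean_profile(_stream(vals, t), win)
        mask = (t >= 10.0) & (t <= 25.0)
        assert np.allclose(prof.values_mm, vals[mask].mean(axis=0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            window_mean_profile(
                _stream(np.full((5, 15), 50.0)), GravitySegment("earth", 1, "pre_earth", 100.0, 117.0)
            )


class TestRepairBraSensor:
    def test_neighbour_mean(self):
        vals = np.full(15, 50.0)
        vals[4], vals[5], vals[6] = 40.0, 99.0, 44.0
        repaired = repair_bra_sensor(make_profile(vals), 6)
        assert repaired.value(6) == pytest.approx(42.0)
        assert 6 in repaired.repaired

    def test_equal_neighbours_identity(self):
        vals = np.full(15, 55.0)
        assert repair_bra_sensor(make_profile(vals), 8).value(8) == pytest.approx(55.0)

    @pytest.mark.parametrize("idx", [1, 15])
    def test_boundary_sensors_rejected(self, idx):
        with pytest.raises(ValueError):
            repair_bra_sensor(make_profile(np.full(15, 50.0)), idx)

    def test_missing_neighbour_rejected(self):
        vals = np.full(15, 50.0)
        vals[6] = np.nan
        with pytest.raises(ValueError, match="neighbour"):
            repair_bra_sensor(make_profile(vals), 8)


class TestClampMissingSegment:
    def test_floor_sensors_clamped_to_16(self):
        vals = np.full(15, 50.0)
        vals[8] = np.nan  # sensor 9
        out = clamp_missing_segment(make_profile(vals), LONG)
        assert out.value(9) == pytest.approx(16.0)

    def test_sensor_2_clamped_to_120(self):
        vals = np.full(15, 50.0)
        vals[1] = np.nan
        out = clamp_missing_segment(make_profile(vals), LONG)
        assert out.value(2) == pytest.approx(120.0)

    def test_no_missing_is_identity(self):
        prof = make_profile(np.full(15, 50.0))
        out = clamp_missing_segment(prof, LONG)
        assert np.array_equal(out.values_mm, prof.values_mm)

    def test_other_sensor_left_missing_with_warning(self):
        vals = np.full(15, 50.0)
        vals[5] = np.nan  # sensor 6: no principled bound
        with pytest.warns(UserWarning, match="left missing"):
            out = clamp_missing_segment(make_profile(vals), LONG)
        assert np.isnan(out.value(6))


class TestExcludeBelowSips:
    @pytest.mark.parametrize(
        "trunk_cm, geom, removed",
        [
            (49.0, LONG, []),  # sensor 15 sits exactly at 49 cm: kept
            (42.0, LONG, [14, 15]),  # 45.5 and 49 cm below C7
            (40.0, SHORT, [15]),  # 42 cm below C7
        ],
    )
    def test_exclusion_arithmetic(self, trunk_cm, geom, removed):
        out = exclude_below_sips(make_profile(np.full(15, 50.0)), trunk_cm, geom)
        excluded = [i + 1 for i in range(15) if not out.included[i]]
        assert excluded == sorted({1, *removed})  # sensor 1 excluded a priori

    def test_degenerate_trunk_rejected(self):
        with pytest.raises(ValueError):
            exclude_below_sips(make_profile(np.full(15, 50.0)), 2.0, LONG)


class TestEnclosedArea:
    def test_rectangle(self):
        # 14 included sensors at 50 mm, 13 gaps of 35 mm
        assert enclosed_area(make_profile(np.full(15, 50.0)), LONG) == pytest.approx(
            13 * 35.0 * 50.0
        )

    def test_zero_profile(self):
        vals = np.full(15, 0.0)
        assert enclosed_area(make_profile(vals), LONG) == 0.0

    def test_three_sensor_hand_trapezoid(self):
        vals = np.full(15, np.nan)
        vals[1:4] = [20.0, 30.0, 40.0]
        inc = np.zeros(15, bool)
        inc[1:4] = True
        assert enclosed_area(make_profile(vals, inc), SHORT) == pytest.approx(
            25.0 * 30 + 35.0 * 30
        )

    def test_gap_splits_into_blocks(self):
        inc = np.ones(15, bool)
        inc[0] = inc[7] = False  # gap at sensor 8
        vals = np.full(15, 50.0)
        with pytest.warns(UserWarning, match="gap"):
            area = enclosed_area(make_profile(vals, inc), LONG)
        assert area == pytest.approx((5 * 35 + 6 * 35) * 50.0)

    def test_missing_included_value_rejected(self):
        vals = np.full(15, 50.0)
        vals[6] = np.nan
        with pytest.raises(ValueError, match="missing"):
            enclosed_area(make_profile(vals), LONG)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(20, 80, 15)
        prof = make_profile(vals)
        span = 13 * LONG.spacing_mm
        a0 = enclosed_area(prof, LONG)
        a1 = enclosed_area(make_profile(vals + 7.5), LONG)
        assert a1 - a0 == pytest.approx(7.5 * span)


class TestIntersensorAngles:
    def test_collinear_is_exactly_180(self):
        angles = intersensor_angles(make_profile(np.full(15, 50.0)), LONG)
        assert all(a == 180.0 for a in angles.values())

    def test_lordotic_oracle_case(self):
        vals = np.full(15, np.nan)
        vals[1:4] = [0.0, 10.0, 0.0]
        inc = np.zeros(15, bool)
        inc[1:4] = True
        angles = intersensor_angles(make_profile(vals, inc), SHORT)
        assert angles == {3: pytest.approx(143.13, abs=0.01)}

    def test_kyphotic_oracle_case(self):
        vals = np.full(15, np.nan)
        vals[1:4] = [10.0, 0.0, 10.0]
        inc = np.zeros(15, bool)
        inc[1:4] = True
        angles = intersensor_angles(make_profile(vals, inc), SHORT)
        assert angles == {3: pytest.approx(216.87, abs=0.01)}

    def test_mirror_symmetry_maps_theta_to_360_minus_theta(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(30, 70, 15)
        prof = make_profile(base)
        a = intersensor_angles(prof, LONG)
        # mirror each profile about its local chords: negate deviations
        mirrored = base.copy()
        mirrored[1:-1] = (base[:-2] + base[2:]) / 2 - (base[1:-1] - (base[:-2] + base[2:]) / 2)
        b = intersensor_angles(make_profile(mirrored), LONG)
        # only interior sensors whose neighbours are unchanged mirror exactly
        for i in (3, 6, 9, 12):
            if i in a and i in b:
                chord = (base[i - 2] + base[i]) / 2
                mchord = (mirrored[i - 2] + mirrored[i]) / 2
                if np.isclose(chord, mchord):
                    assert b[i] == pytest.approx(360.0 - a[i], abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(20, 80, 15)
        a = intersensor_angles(make_profile(vals), LONG)
        b = intersensor_angles(make_profile(vals + 12.0), LONG)
        for i in a:
            assert b[i] == pytest.approx(a[i], abs=1e-9)

    @pytest.mark.parametrize("geom", [LONG, SHORT])
    def test_thousand_random_profiles_match_oracle(self, geom):
        rng = np.random.default_rng(42)
        for _ in range(500):
            vals = rng.uniform(16, 120, 15)
            prof = make_profile(vals)
            angles = intersensor_angles(prof, geom)
            for i, ang in angles.items():
                exp = oracle_angle(vals[i - 2], vals[i - 1], vals[i], geom.spacing_mm)
                assert ang == pytest.approx(exp, rel=1e-9, abs=1e-9)


class TestNormalizeArea:
    def test_grand_mean_examples(self):
        out = normalize_area(np.array([95.0, 100.0, 105.0]))
        assert out == pytest.approx([95.0, 100.0, 105.0])

    def test_mean_normalization_closure_is_exact(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(15000, 30000, 37)
        assert normalize_area(areas).mean() == pytest.approx(100.0, abs=1e-12)

    def test_earth_mean_mode(self):
        areas = np.array([80.0, 80.0, 60.0])
        mask = np.array([True, True, False])
        out = normalize_area(areas, mode="earth_mean", earth_mask=mask)
        assert out[2] == pytest.approx(75.0)
        assert out[0] == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_area(np.zeros(3))


class TestParabolaOrderCheck:
    @staticmethod
    def _frame(matrix):
        rows = []
        for pid, vals in enumerate(matrix):
            for k, v in enumerate(vals):
                rows.append({"participant": f"P{pid}", "parabola": k + 1, "value": v})
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        df = self._frame(np.tile([100.0, 100.0, 100.0, 100.0], (6, 1)) + np.arange(6)[:, None])
        res, exclude = parabola_order_check(df)
        assert res.statistic == 0.0 and res.p_raw == 1.0 and not exclude

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = self._frame(rng.normal(100.0, 2.0, size=(12, 5)))
            _, exclude = parabola_order_check(df)
            hits += exclude
        assert 0.015 <= hits / reps <= 0.095  # binomial 95% band around 0.05

    def test_strong_drift_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            base = rng.normal(100.0, 1.0, size=(10, 6))
            base += np.linspace(0.0, 5.0, 6)[None, :]  # monotone drift
            _, exclude = parabola_order_check(self._frame(base))
            hits += exclude
        assert hits >= 18


class TestFlatteningMonotonicity:
    def test_area_gap_shrinks_with_flattening(self, noiseless_flight):
        from parabospine.curvature import enclosed_area, window_mean_profile
        from parabospine.syncseg import cut_window, segment_gravity
        from parabospine.synth import simulate_distance_stream, simulate_flight_profile

        from conftest import make_participant

        trace = simulate_flight_profile(noiseless_flight, seed=0)
        gaps = []
        for scale in (3.0, 2.0, 1.0, 0.0):
            flat = np.zeros(15)
            flat[6:12] = scale
            p = make_participant(micro_flattening=flat, noise_sd=0.0, drift=0.0)
            ds = simulate_distance_stream(trace, p, seed=0)
            areas = {"earth": [], "micro": []}
            for seg in segment_gravity(trace):
                if seg.condition not in areas:
                    continue
                win = cut_window(seg, 17.0)
                prof = window_mean_profile(ds, win)
                areas[seg.condition].append(enclosed_area(prof, p.geometry))
            gaps.append(np.mean(areas["earth"]) - np.mean(areas["micro"]))
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] == pytest.approx(0.0, abs=1e-9)
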