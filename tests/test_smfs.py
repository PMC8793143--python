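"""Force-curve conditioning, IO, rupture detection and classification."""

import numpy as np
import pytest

from forcebind.io import CurveDialect, read_force_curve, read_force_curves, write_force_curve
from forcebind.smfs import (
    ForceCurve,
    RuptureEvent,
    classify_specific,
    correct_baseline_and_contact,
    detect_rupture_events,
    to_tip_separation,
)
from forcebind.synthetic import SmfsScenario, simulate_force_curve
from forcebind.wlc import wlc_force


def _flat_curve(n=256, k=50.0, noise=0.0, rng=None):
    force = np.zeros(n) if rng is None else rng.normal(0.0, noise, n)
    return ForceCurve(
        time=np.arange(n) * 1e-3,
        piezo_position=np.arange(n) * 0.2,
        force=force,
        spring_constant=k,
        retraction_speed=200.0,
        curve_id="flat",
    )


class TestCurveIO:
    def test_write_read_round_trip_is_exact(self, tmp_path):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=2.0, seed=5)
        curve, _ = simulate_force_curve(scenario, 1000.0, seed=7)
        path = tmp_path / "curve.tsv"
        write_force_curve(curve, path)
        back = read_force_curve(path)
        np.testing.assert_array_equal(back.time, curve.time)
        np.testing.assert_array_equal(back.piezo_position, curve.piezo_position)
        np.testing.assert_array_equal(back.force, curve.force)
        assert back.spring_constant == curve.spring_constant
        assert back.retraction_speed == curve.retraction_speed
        assert back.curve_id == curve.curve_id

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_force_curve(path)

    def test_missing_spring_constant_rejected(self, tmp_path):
        path = tmp_path / "nok.tsv"
        path.write_text("time_s\tpiezo_nm\tforce_pN\n" +
                        "".join(f"{i * 1e-3}\t{i * 0.2}\t0.0\n" for i in range(20)))
        with pytest.raises(ValueError, match="spring"):
            read_force_curve(path)

    def test_newton_per_meter_deflection_dialect_scales_by_50(self, tmp_path):
        # header k = 0.05 N/m -> 50 pN/nm; deflection column in nm
        path = tmp_path / "defl.tsv"
        rows = "".join(f"{i * 1e-3}\t{i * 0.2}\t{0.1}\n" for i in range(20))
        path.write_text("# spring_constant: 0.05 N/m\n"
                        "time_s\tpiezo_nm\tdeflection_nm\n" + rows)
        dialect = CurveDialect(deflection_col="deflection_nm")
        curve = read_force_curve(path, dialect)
        assert curve.spring_constant == pytest.approx(50.0)
        np.testing.assert_allclose(curve.force, 5.0)  # 0.1 nm * 50 pN/nm

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        rows = "".join(f"{0.0}\t{i * 0.2}\t0.0\n" for i in range(20))
        path.write_text("# spring_constant: 50 pN/nm\ntime_s\tpiezo_nm\tforce_pN\n" + rows)
        with pytest.raises(ValueError, match="bad"):
            read_force_curve(path)

    def test_directory_read(self, tmp_path):
        curve = _flat_curve()
        write_force_curve(curve, tmp_path / "a.tsv")
        write_force_curve(curve, tmp_path / "b.tsv")
        assert len(read_force_curves(tmp_path)) == 2


class TestBaselineAndContact:
    def test_zero_curve_unchanged_contact_at_origin(self):
        curve = _flat_curve()
        corrected, contact = correct_baseline_and_contact(curve)
        np.testing.assert_allclose(corrected.force, 0.0, atol=1e-12)
        assert contact == curve.piezo_position[0]

    def test_linear_tilt_removed_to_numerical_precision(self):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=0.0,
                                nonspecific_probability=0.0, seed=3)
        curve, _ = simulate_force_curve(scenario, 1000.0, seed=3, tilt=(4.0, 0.05))
        corrected, _ = correct_baseline_and_contact(curve)
        n_tail = int(0.3 * len(corrected))
        assert abs(np.mean(corrected.force[-n_tail:])) < 1e-9

    def test_known_contact_offset_recovered_within_one_sample(self):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=0.0,
                                nonspecific_probability=0.0, seed=3)
        curve, truth = simulate_force_curve(scenario, 1000.0, seed=3, contact_offset=12.0)
        dz = np.diff(curve.piezo_position)[0]
        _, contact = correct_baseline_and_contact(curve)
        assert abs(contact - truth["contact"]) <= dz

    def test_too_short_baseline_tail_rejected(self):
        with pytest.raises(ValueError, match="tail"):
            correct_baseline_and_contact(_flat_curve(n=20), baseline_fraction=0.1)


class TestTipSeparation:
    def test_zero_force_equals_piezo(self):
        curve = _flat_curve()
        np.testing.assert_array_equal(to_tip_separation(curve), curve.piezo_position)

    def test_constant_force_uniform_shift(self):
        curve = _flat_curve()
        curve.force = np.full(len(curve), 100.0)
        np.testing.assert_allclose(
            to_tip_separation(curve), curve.piezo_position - 100.0 / 50.0
        )

    def test_stiff_cantilever_limit_reproduces_piezo(self):
        curve = _flat_curve(k=1e9)
        curve.force = np.full(len(curve), 100.0)
        np.testing.assert_allclose(to_tip_separation(curve), curve.piezo_position,
                                   atol=1e-6)


class TestRuptureDetection:
    def test_flat_noise_curve_yields_no_events(self, rng):
        curve = _flat_curve(n=2048, noise=5.0, rng=rng)
        corrected, _ = correct_baseline_and_contact(curve)
        assert detect_rupture_events(corrected) == []

    def test_single_rupture_force_within_ten_piconewton(self):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=5.0,
                                nonspecific_probability=0.0, seed=21)
        hits = 0
        rng = np.random.default_rng(21)
        for _ in range(25):
            curve, truth = simulate_force_curve(scenario, 1000.0, rng)
            corrected, _ = correct_baseline_and_contact(curve)
            events = [e for e in detect_rupture_events(corrected) if e.specific]
            assert len(events) == 1
            if abs(events[0].rupture_force - truth["rupture_force"]) <= 10.0:
                hits += 1
        assert hits >= 23  # a couple of noise-driven outliers allowed

    def test_two_ruptures_reported_in_order_of_separation(self, rng):
        # two tethers: short one breaks at ~15 nm, long one at ~34 nm; a very
        # stiff cantilever keeps separation equal to the piezo axis
        k = 1e5
        z = np.arange(0, 60, 0.1)
        force = np.zeros_like(z)
        b1 = z <= 15.0
        force[b1] += wlc_force(np.clip(z[b1], 0, 15.0), 0.38, 16.5)
        b2 = z <= 34.0
        force[b2] += wlc_force(np.clip(z[b2], 0, 34.0), 0.38, 36.0)
        force += rng.normal(0, 2.0, z.size)
        curve = ForceCurve(z / 1000.0, z, force, k, 1000.0, "two")
        events = detect_rupture_events(curve)
        assert len(events) == 2
        assert events[0].rupture_distance < events[1].rupture_distance
        assert events[0].rupture_distance == pytest.approx(15.0, abs=2.0)
        assert events[1].rupture_distance == pytest.approx(34.0, abs=2.0)

    def test_event_count_invariant_under_baseline_tilt(self):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=5.0, seed=9)
        counts = []
        for tilt in (None, (6.0, 0.04)):
            curve, _ = simulate_force_curve(scenario, 1000.0, seed=9, tilt=tilt)
            corrected, _ = correct_baseline_and_contact(curve)
            counts.append(len(detect_rupture_events(corrected)))
        assert counts[0] == counts[1]

    def test_detected_events_have_positive_loading_rate(self):
        scenario = SmfsScenario(specific_probability=1.0, noise_sigma=5.0, seed=17)
        rng = np.random.default_rng(17)
        for _ in range(20):
            curve, _ = simulate_force_curve(scenario, 1000.0, rng)
            corrected, _ = correct_baseline_and_contact(curve)
            for event in detect_rupture_events(corrected):
                assert event.apparent_loading_rate > 0


class TestClassifySpecific:
    def _event(self, distance, quality=0.95, rate=1e4):
        return RuptureEvent(
            rupture_force=100.0, rupture_distance=distance,
            apparent_loading_rate=rate, contour_length=35.0,
            persistence_length=0.38, fit_quality=quality,
        )

    def test_near_contact_adhesion_is_nonspecific(self):
        assert not classify_specific(self._event(5.0))

    def test_linker_consistent_event_is_specific(self):
        assert classify_specific(self._event(34.0))

    def test_unfit_event_nonspecific_regardless_of_distance(self):
        assert not classify_specific(self._event(34.0, quality=0.0))

    def test_distance_window_scales_with_linker_contour(self):
        assert classify_specific(self._event(20.0), linker_contour=35.0)
        assert not classify_specific(self._event(20.0), linker_contour=60.0)
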