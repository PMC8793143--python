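"""QCM-D conditioning, mass models, Voigt inversion and stage accounting."""

import numpy as np
import pytest

from forcebind.io import read_qcm_trace, write_qcm_trace
from forcebind.qcmd import (
    LiquidParams,
    FilmParams,
    QcmTrace,
    StageBoundaries,
    VoigtFilmModel,
    align_and_smooth,
    align_trace,
    frequency_change,
    sauerbrey_mass,
    stage_mass_sum,
    surface_concentration,
    voinova_response,
    voinova_series,
)
from forcebind.synthetic import QcmScenario, simulate_qcm_adsorption


def _trace(values_by_overtone, t_end=2400.0, dt=10.0, stages=(600.0, 1800.0, 2400.0)):
    """Build a trace from {overtone: callable(t) or scalar}."""
    time = np.arange(0.0, t_end + dt / 2, dt)
    delta_f, delta_d = {}, {}
    for n, value in values_by_overtone.items():
        arr = value(time) if callable(value) else np.full_like(time, float(value))
        delta_f[n] = arr
        delta_d[n] = np.zeros_like(time)
    return QcmTrace(time, delta_f, delta_d, StageBoundaries(*stages))


class TestAlignment:
    def test_constant_trace_becomes_zero(self):
        trace = align_trace(_trace({9: -12.5}))
        np.testing.assert_allclose(trace.delta_f[9], 0.0, atol=1e-12)
        assert trace.stages.baseline_end == 0.0

    def test_alignment_is_idempotent(self):
        trace = _trace({9: lambda t: -0.01 * t})
        once = align_trace(trace)
        twice = align_trace(once)
        np.testing.assert_allclose(once.delta_f[9], twice.delta_f[9], atol=1e-12)
        np.testing.assert_allclose(once.time, twice.time)

    def test_step_smooths_to_ramp_with_preserved_midpoint(self):
        # step of -30 Hz at t=1200; 240 s moving average -> linear ramp of
        # width 240 s centered on the step, half-amplitude at the step
        step_at = 1200.0
        trace = _trace({9: lambda t: np.where(t >= step_at, -30.0, 0.0)}, dt=1.0)
        smoothed = align_and_smooth(trace, window=240.0)
        t = smoothed.time + 600.0  # undo the alignment shift for indexing
        f = smoothed.delta_f[9]
        at = lambda tq: f[np.argmin(np.abs(t - tq))]
        assert at(step_at) == pytest.approx(-15.0, abs=0.3)
        assert at(step_at - 150.0) == pytest.approx(0.0, abs=0.2)
        assert at(step_at + 150.0) == pytest.approx(-30.0, abs=0.2)
        # ramp region is linear in between
        ramp = f[(t > step_at - 100) & (t < step_at + 100)]
        assert np.all(np.diff(ramp) <= 1e-9)

    def test_window_exceeding_span_rejected(self):
        with pytest.raises(ValueError, match="window"):
            align_and_smooth(_trace({9: 0.0}, t_end=100.0, stages=(30.0, 60.0, 100.0)),
                             window=240.0)


class TestFrequencyChange:
    def test_plateau_through_wash(self):
        trace = _trace({9: lambda t: np.where(t >= 650.0, -31.0, 0.0)})
        assert frequency_change(trace, 9, "include_wash") == pytest.approx(-31.0)
        assert frequency_change(trace, 9, "exclude_wash") == pytest.approx(-31.0)

    def test_wash_rebound_separates_the_two_modes(self):
        def f(t):
            out = np.zeros_like(t)
            out[(t >= 650.0) & (t <= 1800.0)] = -31.0
            out[t > 1800.0] = -20.0
            return out
        trace = _trace({9: f})
        assert frequency_change(trace, 9, "include_wash") == pytest.approx(-20.0)
        assert frequency_change(trace, 9, "exclude_wash") == pytest.approx(-31.0)

    def test_zero_trace_gives_zero(self):
        assert frequency_change(_trace({9: 0.0}), 9) == 0.0

    def test_modes_agree_when_wash_is_flat(self):
        trace = _trace({9: lambda t: np.where(t >= 650.0, -14.0, 0.0)})
        incl = frequency_change(trace, 9, "include_wash")
        excl = frequency_change(trace, 9, "exclude_wash")
        assert incl == excl

    def test_missing_overtone_rejected(self):
        with pytest.raises(ValueError, match="overtone"):
            frequency_change(_trace({9: 0.0}), 5)


class TestSauerbrey:
    def test_mass_sensitivity_constant(self):
        # C = Zq / (2 f0^2) = 17.6 ng/(cm^2 Hz) for a 5 MHz crystal
        assert sauerbrey_mass(-1.0, 1) == pytest.approx(17.6, abs=0.01)

    def test_zero_shift_zero_mass(self):
        assert sauerbrey_mass(0.0, 9) == 0.0

    def test_native_scale_shift_on_ninth_overtone(self):
        assert sauerbrey_mass(-31.0, 9) == pytest.approx(60.6, abs=0.1)

    def test_even_overtone_rejected(self):
        with pytest.raises(ValueError):
            sauerbrey_mass(-10.0, 4)


def _sla_exact(h_nm, rho1, eta1, mu1, liquid, n, f0=5e6, zq=8.8e6):
    """Independent oracle: exact one-layer small-load impedance solution."""
    w = 2 * np.pi * n * f0
    g_star = mu1 + 1j * w * eta1
    z_film = np.sqrt(rho1 * g_star)
    gamma = 1j * w * np.sqrt(rho1 / g_star)
    z_liq = np.sqrt(1j * w * liquid.density * liquid.viscosity)
    h = h_nm * 1e-9
    z_load = z_film * (z_liq * np.cosh(gamma * h) + z_film * np.sinh(gamma * h)) \
        / (z_film * np.cosh(gamma * h) + z_liq * np.sinh(gamma * h))
    shift = 1j * f0 / (np.pi * zq) * (z_load - z_liq)
    return shift.real, 2 * shift.imag / (n * f0)


class TestVoinova:
    liquid = LiquidParams()

    def test_vanishing_film_gives_zero_response(self):
        df, dd = voinova_series(0.0, self.liquid, 9)
        assert (df, dd) == (0.0, 0.0)

    def test_rigid_thin_film_matches_sauerbrey_with_negligible_dissipation(self):
        film = FilmParams(thickness=2.0, density=1100.0,
                          shear_viscosity=1e-5, shear_modulus=1e9)
        truth = 2e-9 * 1100.0 * 1e8  # ng/cm^2
        for n in (3, 9, 13):
            df, dd = voinova_response(film, self.liquid, n)
            assert sauerbrey_mass(df, n) == pytest.approx(truth, rel=0.01)
            assert dd < 1e-7

    def test_rigid_film_frequency_scales_with_overtone(self):
        film = FilmParams(thickness=2.0, shear_viscosity=1e-5, shear_modulus=1e9)
        reduced = []
        for n in (3, 5, 7, 9, 11, 13):
            df, _ = voinova_response(film, self.liquid, n)
            reduced.append(df / n)
        assert np.ptp(reduced) / abs(np.mean(reduced)) < 0.01

    @pytest.mark.parametrize("mu,eta", [(1e9, 1e-5), (1e5, 2e-3)])
    def test_thin_film_agrees_with_exact_impedance_oracle(self, mu, eta):
        # first-order model vs exact transfer-matrix small-load solution
        for n in (3, 9, 13):
            df, dd = voinova_series(1.0, self.liquid, n,
                                    shear_viscosity=eta, shear_modulus=mu)
            ef, ed = _sla_exact(1.0, 1100.0, eta, mu, self.liquid, n)
            assert df == pytest.approx(ef, rel=0.01)
            assert dd == pytest.approx(ed, rel=0.10, abs=1e-10)

    def test_bulk_term_reproduces_kanazawa_water_loading(self):
        # 5 MHz fundamental in water-like liquid: df ~ -700 Hz, dD ~ 2.8e-4
        df, dd = voinova_series(1e-9, self.liquid, 1, include_bulk=True)
        assert df == pytest.approx(-676.0, abs=2.0)
        assert dd == pytest.approx(2.70e-4, rel=0.01)


class TestVoigtInversion:
    def test_noiseless_round_trip_recovers_density_series(self):
        scenario = QcmScenario(stage_times=(600.0, 7800.0, 9600.0),
                               sample_interval=60.0, rate_constant=5e-4,
                               noise_f=0.0, noise_d=0.0, seed=1)
        trace, truth = simulate_qcm_adsorption(scenario)
        model = VoigtFilmModel().fit(trace)
        grown = truth["gamma"] > 50.0
        rel = np.abs(model.areal_density_[grown] - truth["gamma"][grown]) \
            / truth["gamma"][grown]
        assert rel.max() < 0.02
        assert not model.flags_.any()

    def test_zero_trace_gives_zero_density(self):
        scenario = QcmScenario(gamma_max=1e-9, stage_times=(300.0, 900.0, 1200.0),
                               sample_interval=30.0, noise_f=0.0, noise_d=0.0, seed=1)
        trace, _ = simulate_qcm_adsorption(scenario)
        model = VoigtFilmModel().fit(trace)
        assert np.max(np.abs(model.areal_density_)) < 0.1

    def test_single_overtone_dissipation_rejected(self):
        time = np.arange(0, 400.0, 10.0)
        trace = QcmTrace(time, {9: np.zeros_like(time)}, {},
                         StageBoundaries(100.0, 200.0, 390.0))
        with pytest.raises(ValueError, match="2 overtones"):
            VoigtFilmModel().fit(trace)


class TestStageAccounting:
    def test_single_stage_delta_is_end_minus_start(self):
        time = np.arange(0.0, 1001.0, 1.0)
        density = np.where(time > 300, 500.0, 0.0)
        density = np.where(time > 700, 400.0, density)
        stages = StageBoundaries(200.0, 600.0, 1000.0)
        deltas = stage_mass_sum(time, density, stages)
        assert deltas["adsorption"] == pytest.approx(500.0)
        assert deltas["wash"] == pytest.approx(-100.0)
        assert deltas["total"] == pytest.approx(400.0)

    def test_boundary_spike_artifact_excluded_from_both_stages(self):
        time = np.arange(0.0, 1001.0, 1.0)
        density = np.where(time > 300, 500.0, 0.0)
        density = np.where(time > 700, 400.0, density)
        spiked = density.copy()
        spiked[(time >= 598) & (time <= 604)] += 800.0  # bulk-shift artifact
        stages = StageBoundaries(200.0, 600.0, 1000.0)
        clean = stage_mass_sum(time, density, stages)
        with_spike = stage_mass_sum(time, spiked, stages)
        assert with_spike == pytest.approx(clean)

    def test_total_is_sum_of_stage_deltas(self, rng):
        time = np.arange(0.0, 1001.0, 1.0)
        density = np.cumsum(rng.normal(0.3, 1.0, time.size))
        deltas = stage_mass_sum(time, density, StageBoundaries(200.0, 600.0, 1000.0))
        assert deltas["total"] == pytest.approx(deltas["adsorption"] + deltas["wash"])


class TestSurfaceConcentration:
    def test_native_scale_conversion(self):
        assert surface_concentration(1366.0, 1241.5) == pytest.approx(1.10, abs=0.01)

    def test_zero_density_zero_concentration(self):
        assert surface_concentration(0.0, 1241.5) == 0.0

    def test_halving_mass_doubles_concentration(self):
        assert surface_concentration(100.0, 500.0) == 2 * surface_concentration(100.0, 1000.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            surface_concentration(100.0, 0.0)


class TestQcmIO:
    def test_write_read_round_trip(self, tmp_path):
        scenario = QcmScenario(stage_times=(300.0, 900.0, 1200.0),
                               sample_interval=30.0, seed=4)
        trace, _ = simulate_qcm_adsorption(scenario)
        path = tmp_path / "trace.tsv"
        write_qcm_trace(trace, path)
        back = read_qcm_trace(path)
        assert back.overtones == trace.overtones
        np.testing.assert_array_equal(back.time, trace.time)
        for n in trace.overtones:
            np.testing.assert_array_equal(back.delta_f[n], trace.delta_f[n])
            np.testing.assert_array_equal(back.delta_d[n], trace.delta_d[n])
        assert back.stages == trace.stages
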