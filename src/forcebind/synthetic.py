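"""Synthetic AFM and QCM-D data with the statistical structure the analysis assumes.

Three generators:

* :func:`sample_rupture_forces` — rupture forces from the Bell-Evans
  first-passage distribution under constant loading rate, via the closed-form
  inverse CDF.  Survival function
  ``S(F) = exp[-(k_off kBT/(chi r)) (exp(chi F/kBT) - 1)]``; the mode of the
  density is exactly the Bell-Evans force law.
* :func:`simulate_force_curve` / :func:`simulate_dfs_experiment` — retract
  curves over a 500 nm span: compressive contact branch, optional
  non-specific near-contact adhesion (exponential-decay contact peak that
  releases within ~10 nm), with configurable probability a WLC tether stretch
  through a 5 kDa PEG linker terminating in a sampled rupture, Gaussian
  instrument noise.  Ground truth is returned alongside every curve.
* :func:`simulate_qcm_adsorption` — Langmuir-type film growth (partial
  first-order desorption during wash) rendered into multi-overtone df/dD
  traces through the Voinova forward model, with optional bulk-shift
  artifacts at stage boundaries.

All generators are deterministic under a fixed seed.  Defaults emulate the
study conditions: at least 4000 curves per experiment at 8% specific
probability (native peptide), 200 pN contact force, 500 nm retract span, 18 h
adsorption followed by a buffer wash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import T_DEFAULT, thermal_energy
from .kinetics import BellEvansParams, bell_evans_force
from .qcmd import (
    DEFAULT_OVERTONES,
    FilmParams,
    LiquidParams,
    QcmTrace,
    StageBoundaries,
    voinova_series,
)
from .smfs import ForceCurve
from .wlc import wlc_extension, wlc_force, wlc_stiffness

__all__ = [
    "SmfsScenario",
    "QcmScenario",
    "sample_rupture_forces",
    "simulate_force_curve",
    "simulate_dfs_experiment",
    "simulate_qcm_adsorption",
]

_NG_CM2_TO_KG_M2 = 1.0e-8


def _default_kinetics() -> BellEvansParams:
    # native-peptide-like kinetics: chi = 0.38 nm, k_off = 0.0433 1/s
    return BellEvansParams(chi=0.38, k_off=0.0433, temperature=T_DEFAULT)


@dataclass
class SmfsScenario:
    """Study conditions for the SMFS simulation harness."""

    kinetics: BellEvansParams = field(default_factory=_default_kinetics)
    linker_contour: float = 35.0        # nm, 5 kDa PEG
    linker_persistence: float = 0.38    # nm
    retraction_speeds: tuple = (100.0, 300.0, 1000.0, 3000.0, 10000.0)  # nm/s
    curves_per_speed: int = 4000
    specific_probability: float = 0.08
    nonspecific_probability: float = 0.3
    nonspecific_amplitude: float = 150.0  # pN
    nonspecific_range: float = 5.0        # nm decay length; release within 10 nm
    noise_sigma: float = 5.0              # pN
    sampling_rate: float = 5000.0         # Hz
    span: float = 500.0                   # nm retract distance
    spring_constant: float = 50.0         # pN/nm (0.05 N/m, mid-range cantilever)
    applied_force: float = 200.0          # pN contact force before retract
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.specific_probability <= 1.0:
            raise ValueError("specific_probability must lie in [0, 1]")
        for name in ("linker_contour", "linker_persistence", "noise_sigma",
                     "sampling_rate", "span", "spring_constant", "applied_force"):
            if getattr(self, name) < 0 or (name != "noise_sigma" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class QcmScenario:
    """Study conditions for the QCM-D simulation: Langmuir growth + wash."""

    gamma_max: float = 550.0            # ng/cm^2 (~5 nm film at 1100 kg/m^3)
    rate_constant: float = 3.0e-4       # 1/s; most growth within the first 2 h
    desorbed_fraction: float = 0.2      # fraction lost during wash
    wash_rate_constant: float = 1.0 / 600.0  # 1/s
    film: FilmParams = field(default_factory=lambda: FilmParams(thickness=1.0))
    liquid: LiquidParams = field(default_factory=LiquidParams)
    stage_times: tuple = (1800.0, 1800.0 + 18 * 3600.0, 1800.0 + 18 * 3600.0 + 3600.0)
    sample_interval: float = 60.0       # s
    overtones: tuple = DEFAULT_OVERTONES
    noise_f: float = 0.5                # Hz
    noise_d: float = 3.0e-8             # dissipation units (post-averaging scatter)
    boundary_artifact: float = 0.0      # Hz spike amplitude at stage changes
    artifact_duration: float = 10.0     # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_max < 0 or self.rate_constant <= 0:
            raise ValueError("gamma_max must be >= 0 and rate_constant > 0")
        if not self.stage_times[0] < self.stage_times[1] < self.stage_times[2]:
            raise ValueError("stage_times must be strictly ordered")


def sample_rupture_forces(params: BellEvansParams, loading_rate: float, n: int,
                          seed=None) -> np.ndarray:
    """Draw rupture forces (pN) from the Bell-Evans first-passage distribution.

    Inverse-CDF sampling: with U ~ Uniform(0, 1),
    ``F = (kBT/chi) ln(1 - (chi r/(k_off kBT)) ln U)``.
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kbt = thermal_energy(params.temperature)
    u = rng.uniform(size=n)
    scale = params.chi * loading_rate / (params.k_off * kbt)
    return (kbt / params.chi) * np.log1p(-scale * np.log(u))


def _effective_loading_rate(scenario: SmfsScenario, speed: float, force: float) -> float:
    """Instantaneous loading rate at a given tether force: speed times the
    series stiffness of cantilever and WLC tether."""
    x = wlc_extension(force, scenario.linker_persistence, scenario.linker_contour,
                      scenario.kinetics.temperature)
    k_wlc = wlc_stiffness(x, scenario.linker_persistence, scenario.linker_contour,
                          scenario.kinetics.temperature)
    k_series = 1.0 / (1.0 / scenario.spring_constant + 1.0 / k_wlc)
    return speed * k_series


def _nominal_rate(scenario: SmfsScenario, speed: float) -> float:
    """Fixed-point shortcut: loading rate at the distribution mode, iterated
    twice from a cantilever-stiffness start."""
    r = speed * scenario.spring_constant
    for _ in range(2):
        try:
            f_mode = bell_evans_force(scenario.kinetics, r)
        except ValueError:
            f_mode = 1.0
        f_mode = min(max(f_mode, 1.0), _max_tether_force(scenario))
        r = _effective_loading_rate(scenario, speed, f_mode)
    return r


def _max_tether_force(scenario: SmfsScenario) -> float:
    # cap forces so the rupture extension stays on the grid (x < 0.99 Lc)
    return wlc_force(0.99 * scenario.linker_contour, scenario.linker_persistence,
                     scenario.linker_contour, scenario.kinetics.temperature)


def simulate_force_curve(scenario: SmfsScenario, speed: float, seed=None,
                         contact_offset: "float | None" = None,
                         tilt: "tuple | None" = None):
    """One retract curve at the given speed, plus its ground-truth record.

    The piezo ramps at constant speed; the tether branch is generated on a
    fine separation grid, mapped through ``z = s + F(s)/k`` (cantilever
    compliance), and interpolated onto the uniform piezo grid, so curve shape
    and sampled rupture force are mutually consistent.  ``tilt = (a, b)``
    adds a linear baseline ``a + b z`` (pN) for testing baseline correction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = scenario.spring_constant
    z_c = scenario.applied_force / k if contact_offset is None else float(contact_offset)
    # acquisition rate scales with retract speed (instrument practice), so the
    # spatial sampling stays within [0.1, 0.2] nm regardless of speed
    dz = float(np.clip(speed / scenario.sampling_rate, 0.1, 0.2))
    n = int(np.ceil(scenario.span / dz)) + 1
    z = np.arange(n) * dz
    force = np.zeros(n)

    # compressive contact branch (tip pressed into the surface)
    contact = z < z_c
    force[contact] = -k * (z_c - z[contact])

    truth = {
        "specific": False,
        "rupture_force": np.nan,
        "rupture_separation": np.nan,
        "rupture_piezo": np.nan,
        "loading_rate": np.nan,
        "contact": z_c,
        "nonspecific": False,
        "speed": speed,
    }

    # non-specific near-contact adhesion: exponential contact peak released
    # at a random distance within ~10 nm of the surface
    if rng.uniform() < scenario.nonspecific_probability:
        d_ns = rng.uniform(1.0, 8.0)
        zeta = z - z_c
        ns = (zeta >= 0) & (zeta < d_ns)
        force[ns] += scenario.nonspecific_amplitude * np.exp(
            -zeta[ns] / scenario.nonspecific_range
        )
        truth["nonspecific"] = True

    if rng.uniform() < scenario.specific_probability:
        r_nom = _nominal_rate(scenario, speed)
        f_cap = _max_tether_force(scenario)
        f_rup = float(np.clip(
            sample_rupture_forces(scenario.kinetics, r_nom, 1, rng)[0], 0.5, f_cap
        ))
        s_rup = wlc_extension(f_rup, scenario.linker_persistence,
                              scenario.linker_contour, scenario.kinetics.temperature)
        # tether branch on a fine separation grid, mapped to piezo coordinates
        s_grid = np.linspace(0.0, s_rup, 2048)
        f_grid = wlc_force(s_grid, scenario.linker_persistence,
                           scenario.linker_contour, scenario.kinetics.temperature)
        z_grid = s_grid + f_grid / k + z_c
        tether = (z >= z_c) & (z <= z_grid[-1])
        force[tether] += np.interp(z[tether], z_grid, f_grid)
        truth.update(
            specific=True,
            rupture_force=f_rup,
            rupture_separation=float(s_rup),
            rupture_piezo=float(z_grid[-1]),
            loading_rate=_effective_loading_rate(scenario, speed, max(f_rup, 1.0)),
        )

    if tilt is not None:
        force += tilt[0] + tilt[1] * z
    if scenario.noise_sigma > 0:
        force += rng.normal(0.0, scenario.noise_sigma, size=n)

    curve = ForceCurve(
        time=z / speed,
        piezo_position=z,
        force=force,
        spring_constant=k,
        retraction_speed=speed,
        curve_id=f"sim_v{speed:g}",
    )
    return curve, truth


def simulate_dfs_experiment(scenario: SmfsScenario):
    """Curves grouped by retraction speed, with per-curve ground truth.

    Returns ``{speed: (curves, truths)}``; child seeds are spawned from the
    scenario seed so the whole experiment is reproducible.
    """
    out = {}
    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(len(scenario.retraction_speeds))
    for speed, child in zip(scenario.retraction_speeds, children):
        rng = np.random.default_rng(child)
        curves, truths = [], []
        for i in range(scenario.curves_per_speed):
            curve, truth = simulate_force_curve(scenario, speed, rng)
            curve.curve_id = f"v{speed:g}_{i:05d}"
            curves.append(curve)
            truths.append(truth)
        out[speed] = (curves, truths)
    return out


def simulate_qcm_adsorption(scenario: QcmScenario):
    """A multi-overtone QCM-D trace of Langmuir film growth, plus ground truth.

    Areal density grows as ``Gamma_max (1 - exp(-k t))`` during adsorption
    and partially desorbs (first order) during wash; the density is rendered
    into df/dD per overtone through the Voinova forward model at the
    scenario's film viscoelasticity and fixed density.
    """
    rng = np.random.default_rng(scenario.seed)
    t0, t1, t2 = scenario.stage_times
    time = np.arange(0.0, t2 + scenario.sample_interval / 2, scenario.sample_interval)
    gamma = np.zeros_like(time)

    ads = (time >= t0) & (time <= t1)
    gamma[ads] = scenario.gamma_max * (1.0 - np.exp(-scenario.rate_constant * (time[ads] - t0)))
    g_wash_start = scenario.gamma_max * (1.0 - np.exp(-scenario.rate_constant * (t1 - t0)))
    g_end = g_wash_start * (1.0 - scenario.desorbed_fraction)
    wash = time > t1
    gamma[wash] = g_end + (g_wash_start - g_end) * np.exp(
        -scenario.wash_rate_constant * (time[wash] - t1)
    )

    thickness_nm = gamma * _NG_CM2_TO_KG_M2 / scenario.film.density * 1e9
    delta_f, delta_d = {}, {}
    for n_ot in scenario.overtones:
        df, dd = voinova_series(
            np.maximum(thickness_nm, 0.0), scenario.liquid, n_ot,
            film_density=scenario.film.density,
            shear_viscosity=scenario.film.shear_viscosity,
            shear_modulus=scenario.film.shear_modulus,
        )
        delta_f[n_ot] = np.asarray(df)
        delta_d[n_ot] = np.asarray(dd)

    if scenario.boundary_artifact != 0.0:
        for tb in (t0, t1):
            spike = (time >= tb) & (time < tb + scenario.artifact_duration)
            for n_ot in scenario.overtones:
                delta_f[n_ot][spike] += scenario.boundary_artifact
                delta_d[n_ot][spike] += scenario.boundary_artifact * 1e-8

    for n_ot in scenario.overtones:
        if scenario.noise_f > 0:
            delta_f[n_ot] = delta_f[n_ot] + rng.normal(0.0, scenario.noise_f, time.size)
        if scenario.noise_d > 0:
            delta_d[n_ot] = delta_d[n_ot] + rng.normal(0.0, scenario.noise_d, time.size)

    stages = StageBoundaries(baseline_end=t0, adsorption_end=t1, end=t2)
    trace = QcmTrace(time=time, delta_f=delta_f, delta_d=delta_d, stages=stages)
    truth = {
        "gamma": gamma,
        "adsorption_delta": g_wash_start,
        "wash_delta": g_end - g_wash_start,
        "total": g_end,
    }
    return trace, truth
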