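"""Synthetic ergometer, spirometry and marker data with known ground truth.

The generator emulates the three lab instruments so every downstream stage
can be verified against construction:

* **Ergometer** — each side exerts half-sine torque pulses (peak
  ``peak_torque_true / r_wheel`` N at the roller, duration set by the true
  contact angle at the commanded speed) at the configured push frequency;
  the wheel speed integrates ``m dv/dt = F_push_total - mu*m*g``. When
  ``peak_torque_true`` is None the pulses are sized so the cycle-mean push
  force balances rolling friction, which holds the long-run speed at the
  commanded value. Gaussian noise is added to the recorded force only; the
  true push onsets/offsets are returned for oracle tests.
* **Spirometry** — breaths arrive as a Poisson process (mean inter-breath
  interval ``breath_interval``); breath VO2 is set so energy expenditure
  averages ``max(power / gme_true * 100, resting floor)`` with
  ``VCO2 = rer_true * VO2`` and multiplicative per-breath noise. Heart rate
  is an affine function of power plus noise.
* **Hand marker (M2)** — the push phase follows the rim circle over the true
  contact angle; the recovery phase loops above the rim (SLOP), below it
  (SC), above-then-below (DLOP), or hugs the rim (ARC).

``simulate_study`` strings these together into a full practice study whose
per-session learning trajectories default to the bundled reference tables.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import reference
from .config import EnergeticsSettings, SimulationConfig, StudyConfig
from .errors import ConfigError, DataError
from .kinetics import ErgometerSignal
from .patterns import PATTERNS, MarkerTrajectory
from .physiology import SpiroSeries


def _rng(cfg_seed, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg_seed)


def friction_force(config: SimulationConfig, g: float = 9.81) -> float:
    """Total rolling-friction force, N."""
    return config.mu * config.mass * g


def balanced_peak_torque(config: SimulationConfig, g: float = 9.81) -> float:
    """Per-side half-sine peak torque that balances rolling friction.

    A half-sine pulse of duration ``t_p`` repeated every cycle ``T`` has a
    cycle-mean amplitude of ``(2/pi) * peak * t_p / T``; setting the summed
    left+right cycle-mean force equal to ``mu*m*g`` keeps the long-run speed
    at the commanded value.
    """
    mean_force_per_side = friction_force(config, g) / 2.0
    peak_force = (math.pi / 2.0) * mean_force_per_side \
        * (config.cycle_time / config.push_time)
    return peak_force * config.wheel_radius


# ---------------------------------------------------------------------------
# ergometer


def simulate_ergometer_block(config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             duration: float | None = None,
                             g: float = 9.81
                             ) -> tuple[ErgometerSignal, ErgometerSignal, list[dict]]:
    """One practice block of per-side ergometer signals plus ground truth.

    Returns ``(left, right, truth)`` where ``truth`` holds one record per
    push with the true onset/offset, contact angle and torque amplitudes.
    Raises :class:`ConfigError` if the configuration lets the wheel speed
    collapse to zero within the block.
    """
    config.validate()
    rng = _rng(config.seed, rng)
    T = config.block_duration if duration is None else float(duration)
    fs = config.sample_rate
    n = int(round(T * fs)) + 1
    t = np.arange(n) / fs
    r = config.wheel_radius
    cycle = config.cycle_time
    t_push = config.push_time
    n_push = int(math.floor(config.push_frequency * T))

    tau_peak = (config.peak_torque_true if config.peak_torque_true is not None
                else balanced_peak_torque(config, g))
    peak_force = tau_peak / r
    a_left = 2.0 * peak_force / (1.0 + config.asymmetry)
    a_right = a_left * config.asymmetry

    phase = np.mod(t, cycle)
    idx = np.floor(t / cycle).astype(int)
    active = (phase <= t_push) & (idx < n_push)
    profile = np.where(active, np.sin(np.pi * np.clip(phase, 0, t_push) / t_push), 0.0)
    force_left_true = a_left * profile
    force_right_true = a_right * profile

    # wheel dynamics: m dv/dt = F_total - mu*m*g; the force profile is
    # prescribed, so the integral is a cumulative trapezoid sum
    f_fric = friction_force(config, g)
    total = force_left_true + force_right_true
    dt = 1.0 / fs
    accel = (total - f_fric) / config.mass
    v0 = config.target_speed if config.v0 is None else config.v0
    v = v0 + dt * np.concatenate(
        ([0.0], np.cumsum(0.5 * (accel[:-1] + accel[1:]))))
    if config.v0 is None:
        # anchor the long-run mean (over complete cycles) at the commanded
        # speed; a uniform shift of v still satisfies the dynamics
        m_cyc = t < n_push * cycle
        if np.any(m_cyc):
            v = v + (config.target_speed - float(np.mean(v[m_cyc])))
    if np.min(v) <= 0.0:
        i_bad = int(np.argmax(v <= 0.0))
        raise ConfigError(
            "wheel speed collapsed to zero at "
            f"t={t[i_bad]:.2f} s; push amplitude (peak_torque_true="
            f"{tau_peak:.2f} N*m) cannot sustain friction mu="
            f"{config.mu} at mass={config.mass} kg"
        )

    noise_l = rng.normal(0.0, config.noise_sd_force, n) \
        if config.noise_sd_force > 0 else 0.0
    noise_r = rng.normal(0.0, config.noise_sd_force, n) \
        if config.noise_sd_force > 0 else 0.0

    left = ErgometerSignal(t, force_left_true + noise_l, v, side="left",
                           wheel_radius=r)
    right = ErgometerSignal(t, force_right_true + noise_r, v, side="right",
                            wheel_radius=r)

    truth: list[dict] = []
    for k in range(n_push):
        s, e = k * cycle, k * cycle + t_push
        i0 = int(np.searchsorted(t, s - 1e-12))
        i1 = int(np.searchsorted(t, e + 1e-12, side="right"))
        contact = math.degrees(float(np.trapezoid(v[i0:i1] / r, t[i0:i1])))
        truth.append({
            "start": s,
            "end": e,
            "push_time": t_push,
            "contact_angle": contact,
            "peak_torque": tau_peak,
            "mean_torque": 2.0 / math.pi * tau_peak,
        })
    return left, right, truth


# ---------------------------------------------------------------------------
# spirometry


def simulate_spirometry(config: SimulationConfig,
                        power_output: float,
                        rng: np.random.Generator | None = None,
                        duration: float | None = None,
                        t0: float = 0.0,
                        energetics: EnergeticsSettings | None = None
                        ) -> SpiroSeries:
    """Breath-by-breath gas exchange consistent with a prescribed efficiency.

    Mean energy expenditure is ``max(power_output / gme_true * 100,
    resting floor)``; the resting floor keeps simulated efficiency finite
    and below 100% at vanishing loads.
    """
    if power_output < 0:
        raise DataError("power_output must be non-negative")
    if config.gme_true <= 0:
        raise ConfigError("gme_true must be strictly positive")
    rng = _rng(config.seed + 1, rng)
    ecfg = energetics or EnergeticsSettings()
    T = config.block_duration if duration is None else float(duration)

    ee = max(power_output / config.gme_true * 100.0, ecfg.resting_ee_w)
    e_kj_per_l = ecfg.o2_equiv_slope * config.rer_true + ecfg.o2_equiv_intercept
    vo2_lmin = ee * 60.0 / (e_kj_per_l * 1000.0)

    # Poisson breath arrivals around the mean inter-breath interval
    n_max = max(8, int(3 * T / config.breath_interval))
    gaps = rng.exponential(config.breath_interval, n_max)
    times = np.cumsum(gaps)
    times = times[times < T]
    while times.size < 3:  # pathologically sparse draw: densify
        extra = times[-1] + np.cumsum(
            rng.exponential(config.breath_interval, 8)) if times.size else \
            np.cumsum(rng.exponential(config.breath_interval, 8))
        times = np.concatenate([times, extra[extra < T]])
        if times.size >= 3 or extra[-1] >= T:
            break
    times = np.sort(times)

    nb = times.size
    sd = config.noise_sd_breath
    vo2 = vo2_lmin * np.clip(1.0 + rng.normal(0.0, sd, nb), 0.1, None)
    vco2 = config.rer_true * vo2_lmin * np.clip(
        1.0 + rng.normal(0.0, sd, nb), 0.1, None)
    hr = config.hr_rest + config.hr_slope * power_output \
        + rng.normal(0.0, config.hr_noise_sd, nb)
    return SpiroSeries(t0 + times, vo2, vco2, hr)


# ---------------------------------------------------------------------------
# hand marker


_RECOVERY_AMPLITUDE_FRAC = 0.30  # loop amplitude, fraction of rim radius
_ARC_WIGGLE_FRAC = 0.30          # ARC radial wiggle, fraction of the band


def simulate_hand_trajectory(pattern, config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             duration: float = 16.0,
                             band_frac: float = 0.05) -> MarkerTrajectory:
    """Sagittal-plane M2 marker path for one of the four Boninger patterns.

    The push arc is centred on top-dead centre and spans the true contact
    angle at the rim; the recovery retraces the angle with a radial offset
    profile characteristic of the pattern. ``band_frac`` must match the
    classifier's rim tolerance band so ARC paths stay inside it and loop
    amplitudes clear it.
    """
    label = pattern.label if hasattr(pattern, "label") else str(pattern)
    if label not in PATTERNS:
        raise DataError(f"unknown pattern {label!r}; expected one of {PATTERNS}")
    if duration < 15.0:
        raise DataError("trajectory must span at least 15 s")
    rng = _rng(config.seed + 2, rng)

    fs = config.sample_rate
    r_rim = config.rim_radius
    cycle = config.cycle_time
    t_push = config.push_time
    theta = math.radians(config.contact_angle_true)
    phi0, phi1 = -theta / 2.0, theta / 2.0
    eps = band_frac * r_rim
    amp = _RECOVERY_AMPLITUDE_FRAC * r_rim

    n_push = max(2, int(round(t_push * fs)))
    n_rec = max(6, int(round((cycle - t_push) * fs)))
    n_cycles = int(math.ceil(duration / cycle))

    # one template cycle: push along the rim, then recovery back over the top
    phi_push = np.linspace(phi0, phi1, n_push, endpoint=False)
    s = np.linspace(0.0, 1.0, n_rec, endpoint=False)
    phi_rec = phi1 - (phi1 - phi0) * s
    if label == "ARC":
        d = _ARC_WIGGLE_FRAC * eps * np.sin(np.pi * s)
    elif label == "SLOP":
        d = amp * np.sin(np.pi * s)
    elif label == "SC":
        d = -amp * np.sin(np.pi * s)
    else:  # DLOP: over the rim first, then under
        d = amp * np.sin(2.0 * np.pi * s)
    radius = np.concatenate([np.full(n_push, r_rim), r_rim + d])
    phi = np.concatenate([phi_push, phi_rec])

    radius_all = np.tile(radius, n_cycles)
    phi_all = np.tile(phi, n_cycles)
    n_total = radius_all.size
    t = np.arange(n_total) * (cycle / (n_push + n_rec))
    x = radius_all * np.sin(phi_all)
    y = radius_all * np.cos(phi_all)
    if config.marker_noise_sd > 0:
        x = x + rng.normal(0.0, config.marker_noise_sd, n_total)
        y = y + rng.normal(0.0, config.marker_noise_sd, n_total)

    dt = cycle / (n_push + n_rec)
    push_intervals = [(k * cycle, k * cycle + n_push * dt)
                      for k in range(n_cycles)]
    return MarkerTrajectory(t, x, y, rim_radius=r_rim,
                            push_intervals=push_intervals)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class SessionSim:
    """All simulated inputs for one subject-session."""

    subject: int
    session: int
    blocks: list = field(default_factory=list)   # (left, right, truth) triples
    spiro: SpiroSeries | None = None
    block_windows: list = field(default_factory=list)  # (start, end) in spiro time
    rpe: float = math.nan
    markers: list = field(default_factory=list)  # MarkerTrajectory per block
    pattern: str | None = None
    truth: dict = field(default_factory=dict)


def _subject_traits(rng: np.random.Generator) -> dict:
    """Persistent between-subject offsets (z-scores) for each trajectory."""
    return {k: float(rng.normal()) for k in
            ("speed", "cycle_time", "contact_angle", "gme", "rer", "rpe",
             "mass")}


#: shrinkage of the printed between-subject SDs used for subject offsets;
#: keeps the joint draws physically consistent (push shorter than cycle)
_TRAIT_SHRINK = 0.8


def _session_params(session: int, traits: dict) -> dict:
    i = session - 1
    m, s = reference.NOVICE_MEANS, reference.NOVICE_SDS
    speed = m["speed"][i] + _TRAIT_SHRINK * s["speed"][i] * traits["speed"]
    cycle = m["cycle_time"][i] + _TRAIT_SHRINK * s["cycle_time"][i] * traits["cycle_time"]
    theta = m["contact_angle"][i] + _TRAIT_SHRINK * s["contact_angle"][i] * traits["contact_angle"]
    gme = m["gme"][i] + _TRAIT_SHRINK * s["gme"][i] * traits["gme"]
    rer = reference.RER_SCHEDULE[i] + reference.RER_SUBJECT_SD * traits["rer"]
    rpe = m["rpe"][i] + s["rpe"][i] * traits["rpe"]
    speed = float(np.clip(speed, 1.5, 3.5))
    cycle = float(np.clip(cycle, 0.45, 2.5))
    theta = float(np.clip(theta, 40.0, 170.0))
    # keep the push comfortably shorter than the cycle
    omega = speed / 0.355
    t_push = math.radians(theta) / omega
    cycle = max(cycle, 1.6 * t_push)
    mass = reference.MASS_MEAN \
        + _TRAIT_SHRINK * reference.MASS_SD * traits["mass"]
    return {
        "speed": speed,
        "cycle_time": cycle,
        "contact_angle": theta,
        "gme": float(np.clip(gme, 2.0, 9.5)),
        "rer": float(np.clip(rer, 0.75, 1.15)),
        "rpe": float(np.clip(round(rpe), 6, 20)),
        "mass": float(np.clip(mass, 45.0, 100.0)),
    }


def simulate_session(base: SimulationConfig, subject: int, session: int,
                     params: dict, rng: np.random.Generator,
                     pattern: str | None = None,
                     energetics: EnergeticsSettings | None = None) -> SessionSim:
    """Simulate one subject-session: 3 blocks of signals, spirometry, RPE
    and (when ``pattern`` is given) per-block marker trajectories."""
    cfg = SimulationConfig(**{**base.__dict__,
                              "target_speed": params["speed"],
                              "push_frequency": 1.0 / params["cycle_time"],
                              "contact_angle_true": params["contact_angle"],
                              "peak_torque_true": None,
                              "gme_true": params["gme"],
                              "rer_true": params["rer"],
                              "mass": params.get("mass", base.mass)})
    cfg.validate()
    sim = SessionSim(subject=subject, session=session,
                     rpe=params["rpe"], pattern=pattern,
                     truth=dict(params))
    po_theory = cfg.mu * cfg.mass * 9.81 * cfg.target_speed
    spiro_parts = []
    for b in range(cfg.blocks_per_session):
        left, right, truth = simulate_ergometer_block(cfg, rng=rng)
        sim.blocks.append((left, right, truth))
        t0 = b * (cfg.block_duration + cfg.rest_between_blocks)
        sim.block_windows.append((t0, t0 + cfg.block_duration))
        spiro_parts.append(simulate_spirometry(
            cfg, po_theory, rng=rng, t0=t0, energetics=energetics))
        if pattern is not None:
            sim.markers.append(simulate_hand_trajectory(pattern, cfg, rng=rng))
    sim.spiro = SpiroSeries(
        np.concatenate([s.time for s in spiro_parts]),
        np.concatenate([s.vo2 for s in spiro_parts]),
        np.concatenate([s.vco2 for s in spiro_parts]),
        np.concatenate([s.hr for s in spiro_parts]),
    )
    sim.truth["po_theory"] = po_theory
    return sim


def simulate_study(config: StudyConfig | None = None, seed: int = 0,
                   kinematic_sessions: tuple[int, ...] | None = None):
    """Generate a full practice study, yielding one :class:`SessionSim` per
    subject-session.

    Learning trajectories (speed, cycle time, contact angle, efficiency,
    RER, RPE) follow the bundled per-session reference means with persistent
    subject offsets drawn from the printed between-subject SDs. Marker data
    are produced for the first and last session only, with per-subject
    pre/post techniques matching the reference transition counts.
    """
    cfg = (config or StudyConfig()).validate()
    if kinematic_sessions is None:
        kinematic_sessions = (1, cfg.sim.sessions)
    assignments = reference.technique_assignments()
    for subject in range(1, cfg.subjects + 1):
        trait_rng = np.random.default_rng([seed, subject, 0])
        traits = _subject_traits(trait_rng)
        pre, post = assignments[(subject - 1) % len(assignments)]
        for session in range(1, cfg.sim.sessions + 1):
            rng = np.random.default_rng([seed, subject, session])
            params = _session_params(session, traits)
            pattern = None
            if session in kinematic_sessions:
                pattern = pre if session == min(kinematic_sessions) else post
            yield simulate_session(cfg.sim, subject, session, params, rng,
                                   pattern=pattern,
                                   energetics=cfg.energetics)
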