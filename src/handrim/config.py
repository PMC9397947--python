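"""Configuration objects for simulation, analysis and protocol physics.

Every tunable constant used anywhere in the package lives in exactly one of
the dataclasses below, and :class:`StudyConfig` bundles them into a single
flat, human-editable YAML mapping (dotted keys, e.g. ``filter.cutoff_hz``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: standard gravity, m/s^2
G = 9.81


@dataclass
class FilterSettings:
    """Low-pass filter applied to raw ergometer force before segmentation.

    A 4th-order Butterworth design applied forward-backward (zero phase,
    effectively 8th-order magnitude response).
    """

    cutoff_hz: float = 15.0
    order: int = 4


@dataclass
class DetectionSettings:
    """Hysteresis push segmentation on filtered wheel torque.

    A push starts where torque exceeds ``max(min_torque_nm,
    rel_peak * median block peak)`` and extends outward to where torque drops
    below ``off_frac`` times that onset threshold; edges are then refined to
    the nearest zero crossing of the filtered torque so that threshold height
    does not bias contact-angle estimates.
    """

    min_torque_nm: float = 1.0
    rel_peak: float = 0.10
    off_frac: float = 0.5
    min_duration_s: float = 0.05
    merge_gap_s: float = 0.05
    refine_to_zero: bool = True


@dataclass
class ClassifierSettings:
    """Recovery-path pattern classifier constants.

    ``band_frac`` sets the rim tolerance band as a fraction of rim radius;
    an excursion counts only if at least ``min_excursion_samples`` consecutive
    samples lie beyond the band.
    """

    band_frac: float = 0.05
    min_excursion_samples: int = 5


@dataclass
class EnergeticsSettings:
    """Oxygen energetic equivalent and resting-metabolism floor.

    The energy value of oxygen is modelled as ``e (kJ/L O2) =
    o2_equiv_slope * RER + o2_equiv_intercept`` (Garby & Astrup form).
    ``resting_ee_w`` is the floor used by the spirometry simulator so that
    simulated efficiency stays below 100% at vanishing external load.
    """

    o2_equiv_slope: float = 4.940
    o2_equiv_intercept: float = 16.040
    resting_ee_w: float = 100.0


@dataclass
class ProtocolConfig:
    """Protocol-level physics and statistical conventions."""

    mu: float = 0.011            # rolling-friction coefficient
    mass: float = 69.3           # system mass in the friction model, kg
    g: float = G                 # m/s^2
    target_speed: float = 2.78   # m/s (10 km/h)
    tolerance: float = 0.05      # speed-compliance band, fraction of target
    alpha: float = 0.05

    def validate(self) -> "ProtocolConfig":
        if not 0.0 < self.mu < 0.1:
            raise ConfigError(f"mu must lie in (0, 0.1), got {self.mu}")
        if not 0.0 < self.tolerance < 0.5:
            raise ConfigError(
                f"tolerance must lie in (0, 0.5), got {self.tolerance}"
            )
        for name in ("mass", "g", "target_speed"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        return self


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic instrument signals.

    Defaults reproduce the study conditions: 9 sessions of 3 x 4-min blocks
    at a commanded 2.78 m/s against rolling friction mu = 0.011 on 0.71 m
    wheels with 0.38 m handrims, sampled at 100 Hz.
    """

    seed: int = 0
    sample_rate: float = 100.0       # Hz
    block_duration: float = 240.0    # s
    blocks_per_session: int = 3
    sessions: int = 9
    target_speed: float = 2.78       # m/s
    mu: float = 0.011
    mass: float = 69.3               # kg, lumped system mass
    wheel_diameter: float = 0.71     # m
    rim_diameter: float = 0.38       # m
    push_frequency: float = 1.0      # Hz
    contact_angle_true: float = 90.0  # degrees of wheel rotation per push
    peak_torque_true: float | None = None  # N*m; None -> friction-balanced
    gme_true: float = 5.0            # percent
    rer_true: float = 0.90           # VCO2/VO2
    noise_sd_force: float = 1.0      # N, additive on recorded force
    noise_sd_breath: float = 0.05    # multiplicative, per breath
    marker_noise_sd: float = 0.001   # m, additive on marker coordinates
    v0: float | None = None          # initial wheel speed; None -> target
    asymmetry: float = 1.0           # right/left push-amplitude ratio
    hr_rest: float = 80.0            # bpm at zero external power
    hr_slope: float = 2.5            # bpm per watt
    hr_noise_sd: float = 3.0         # bpm
    breath_interval: float = 4.0     # s, mean inter-breath interval
    rest_between_blocks: float = 120.0  # s

    @property
    def wheel_radius(self) -> float:
        return self.wheel_diameter / 2.0

    @property
    def rim_radius(self) -> float:
        return self.rim_diameter / 2.0

    @property
    def cycle_time(self) -> float:
        """Push-onset-to-next-onset time, s."""
        return 1.0 / self.push_frequency

    @property
    def push_time(self) -> float:
        """Hand-rim contact duration at the commanded speed, s."""
        omega = self.target_speed / self.wheel_radius
        return math.radians(self.contact_angle_true) / omega

    def validate(self) -> "SimulationConfig":
        positive = (
            "sample_rate", "block_duration", "target_speed", "mu", "mass",
            "wheel_diameter", "rim_diameter", "push_frequency",
            "contact_angle_true", "gme_true", "breath_interval", "asymmetry",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.rim_diameter >= self.wheel_diameter:
            raise ConfigError(
                "rim_diameter must be smaller than wheel_diameter "
                f"({self.rim_diameter} >= {self.wheel_diameter})"
            )
        if math.floor(self.push_frequency * self.block_duration) < 1:
            raise ConfigError(
                "push_frequency * block_duration must allow at least one push"
            )
        if not 0.0 < self.gme_true < 100.0:
            raise ConfigError(f"gme_true must lie in (0, 100), got {self.gme_true}")
        if not 0.7 <= self.rer_true <= 1.3:
            raise ConfigError(f"rer_true must lie in [0.7, 1.3], got {self.rer_true}")
        if self.peak_torque_true is not None and self.peak_torque_true <= 0:
            raise ConfigError("peak_torque_true must be strictly positive")
        if self.push_time >= self.cycle_time:
            raise ConfigError(
                "contact_angle_true and push_frequency imply a push longer "
                f"than the cycle ({self.push_time:.3f} s >= "
                f"{self.cycle_time:.3f} s)"
            )
        return self


@dataclass
class StudyConfig:
    """Everything needed to simulate and analyse a complete practice study."""

    subjects: int = 15
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    filter: FilterSettings = field(default_factory=FilterSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    energetics: EnergeticsSettings = field(default_factory=EnergeticsSettings)

    _SECTIONS = ("sim", "protocol", "filter", "detection", "classifier",
                 "energetics")

    def validate(self) -> "StudyConfig":
        if self.subjects < 1:
            raise ConfigError("subjects must be >= 1")
        self.sim.validate()
        self.protocol.validate()
        return self

    # -- flat serialization ------------------------------------------------

    def to_flat_dict(self) -> dict:
        out: dict = {"subjects": self.subjects}
        for section in self._SECTIONS:
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                out[f"{section}.{f.name}"] = getattr(obj, f.name)
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "StudyConfig":
        cfg = cls()
        known = set(cfg.to_flat_dict())
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "subjects" in flat:
            cfg.subjects = int(flat["subjects"])
        for key, value in flat.items():
            if key == "subjects":
                continue
            section, name = key.split(".", 1)
            setattr(getattr(cfg, section), name, value)
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_flat_dict(), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        flat = yaml.safe_load(Path(path).read_text())
        if not isinstance(flat, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_flat_dict(flat)
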