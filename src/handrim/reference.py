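"""Bundled reference data from a three-week racing-wheelchair practice study.

Fifteen able-bodied novices practised 9 sessions (3 x 4 min each) on a
wheelchair roller ergometer at a commanded 2.78 m/s against rolling friction
mu = 0.011; one experienced T54 athlete completed a single block at 28.4 W
for comparison. The per-session group means and standard deviations below
(last minute of each block, averaged over the three blocks and over the
left/right sides) serve two roles in this package:

* defaults for the synthetic study generator's learning trajectories, and
* reference inputs for the athlete-comparison t-tests and the worked
  examples.

Units: speed m/s, power W, RPE on the Borg 6-20 scale, HR bpm, EE W,
GME percent, contact angle degrees, push/cycle time s, torque N*m, work J.
"""

from __future__ import annotations

import numpy as np

#: session indices of the practice protocol
SESSIONS = tuple(range(1, 10))

#: number of novice participants
NOVICE_N = 15

#: novice body mass, kg (mean and between-subject SD)
MASS_MEAN = 69.3
MASS_SD = 9.87

#: per-session group means for the novice cohort (index 0 = session 1)
NOVICE_MEANS: dict[str, tuple[float, ...]] = {
    "speed": (2.34, 2.53, 2.68, 2.76, 2.78, 2.79, 2.81, 2.79, 2.84),
    "power": (19.7, 21.6, 22.7, 23.6, 23.6, 23.7, 23.8, 23.7, 24.1),
    "rpe": (15.2, 14.3, 13.6, 13.2, 12.4, 12.2, 11.8, 11.6, 11.4),
    "hr": (141.0, 142.0, 132.0, 130.0, 126.0, 124.0, 119.0, 120.0, 120.0),
    "ee": (552.0, 543.0, 544.0, 522.0, 510.0, 482.0, 451.0, 445.0, 450.0),
    "gme": (3.88, 4.06, 4.37, 4.68, 4.75, 4.96, 5.36, 5.40, 5.39),
    "contact_angle": (70.0, 78.2, 86.8, 91.3, 96.2, 98.7, 103.0, 106.0, 108.0),
    "push_time": (0.17, 0.17, 0.18, 0.19, 0.19, 0.20, 0.21, 0.21, 0.21),
    "cycle_time": (0.75, 0.88, 0.94, 1.02, 1.10, 1.18, 1.18, 1.20, 1.26),
    "mean_torque": (6.76, 7.10, 7.15, 7.56, 7.79, 8.07, 7.55, 7.69, 7.73),
    "peak_torque": (12.4, 12.9, 13.2, 13.9, 14.4, 15.1, 14.6, 15.0, 15.0),
    "work": (8.59, 10.2, 11.3, 12.7, 13.7, 14.5, 14.2, 14.9, 15.3),
    "mean_power": (51.0, 57.2, 60.3, 65.5, 68.0, 70.5, 66.5, 67.2, 68.6),
    "peak_power": (93.0, 104.0, 111.0, 120.0, 126.0, 132.0, 128.0, 131.0, 133.0),
}

#: per-session between-subject standard deviations for the novice cohort
NOVICE_SDS: dict[str, tuple[float, ...]] = {
    "speed": (0.39, 0.27, 0.15, 0.08, 0.08, 0.09, 0.08, 0.14, 0.08),
    "power": (4.49, 3.55, 3.15, 3.20, 3.04, 3.03, 2.97, 3.20, 2.97),
    "rpe": (1.80, 2.14, 1.85, 2.09, 2.03, 1.98, 2.23, 1.77, 1.60),
    "hr": (19.5, 20.7, 20.2, 20.5, 19.8, 12.9, 14.3, 14.1, 12.8),
    "ee": (152.0, 115.0, 134.0, 123.0, 105.0, 72.7, 71.1, 61.4, 58.2),
    "gme": (0.78, 0.76, 0.94, 0.93, 0.81, 0.63, 0.77, 0.94, 0.60),
    "contact_angle": (20.4, 15.0, 13.5, 17.7, 15.7, 14.6, 18.8, 19.3, 20.7),
    "push_time": (0.04, 0.03, 0.03, 0.04, 0.03, 0.03, 0.04, 0.04, 0.04),
    "cycle_time": (0.23, 0.22, 0.21, 0.26, 0.25, 0.32, 0.34, 0.32, 0.39),
    "mean_torque": (2.31, 2.39, 2.08, 2.44, 2.48, 2.92, 1.75, 1.85, 1.87),
    "peak_torque": (3.85, 3.97, 3.92, 4.24, 4.58, 4.93, 3.76, 4.44, 4.10),
    "work": (3.73, 3.85, 3.68, 5.21, 5.00, 5.80, 4.71, 4.87, 5.41),
    "mean_power": (23.7, 22.8, 19.1, 22.1, 22.8, 26.0, 16.0, 17.2, 17.2),
    "peak_power": (40.0, 38.4, 36.3, 38.5, 42.1, 44.3, 34.0, 40.7, 37.7),
}

#: single-session values of the experienced T54 reference athlete
ATHLETE: dict[str, float] = {
    "speed": 2.78,
    "power": 28.4,
    "rpe": 8.0,
    "hr": 101.0,
    "ee": 426.0,
    "gme": 6.66,
    "contact_angle": 165.0,
    "push_time": 0.37,
    "cycle_time": 1.26,
    "mean_torque": 6.17,
    "peak_torque": 13.0,
    "work": 18.3,
    "mean_power": 48.1,
    "peak_power": 102.0,
}

#: first-session -> last-session propulsion-technique transition counts
#: (pre pattern, post pattern) -> number of participants
TECHNIQUE_TRANSITIONS: dict[tuple[str, str], int] = {
    ("ARC", "DLOP"): 3,
    ("DLOP", "DLOP"): 2,
    ("SC", "SC"): 2,
    ("SLOP", "DLOP"): 6,
    ("SLOP", "SLOP"): 2,
}


def technique_assignments() -> list[tuple[str, str]]:
    """Per-subject (pre, post) technique pairs consistent with the observed
    transition counts, in a fixed deterministic order."""
    out: list[tuple[str, str]] = []
    for (pre, post), n in TECHNIQUE_TRANSITIONS.items():
        out.extend([(pre, post)] * n)
    return out


#: mean session-mean respiratory exchange ratio assumed for the generator's
#: learning trajectory (anaerobic contribution fades with practice; with a
#: between-subject SD of ~0.03 the early sessions occasionally exceed 1.0,
#: matching the observed handful of discarded efficiency values)
RER_SCHEDULE = (0.97, 0.95, 0.93, 0.91, 0.90, 0.89, 0.88, 0.88, 0.87)
RER_SUBJECT_SD = 0.03


def session_schedule(variable: str) -> np.ndarray:
    """Group-mean learning trajectory for ``variable`` across the 9 sessions."""
    return np.asarray(NOVICE_MEANS[variable], dtype=float)
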