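"""Breath-by-breath gas exchange, energy expenditure and gross efficiency.

Energy expenditure (EE, W) is derived from oxygen uptake and the respiratory
exchange ratio (RER = VCO2/VO2) through an oxygen energetic equivalent
``e (kJ/L O2) = 4.940 * RER + 16.040`` (Garby & Astrup), so

    EE = VO2[L/s] * e * 1000.

Gross mechanical efficiency is the external power output over the metabolic
rate, GME(%) = PO / EE * 100. Sessions whose mean RER exceeds 1.0 indicate a
substantial anaerobic contribution, invalidating the steady-state efficiency
estimate; their GME is discarded (reported as null, never zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import EnergeticsSettings
from .errors import DataError


@dataclass
class SpiroSeries:
    """Breath-by-breath VO2/VCO2 (L/min) and optional heart rate (bpm)."""

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    hr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if self.hr is not None:
            self.hr = np.asarray(self.hr, dtype=float)
            if self.hr.size != self.time.size:
                raise DataError("hr must match time length")
        n = self.time.size
        if self.vo2.size != n or self.vco2.size != n:
            raise DataError("time, vo2 and vco2 must have equal length")
        if n and np.any(np.diff(self.time) <= 0):
            raise DataError("breath times must be strictly increasing")
        if n and (np.any(self.vo2 <= 0) or np.any(self.vco2 <= 0)):
            raise DataError("vo2 and vco2 must be strictly positive")

    def window(self, start: float, end: float) -> "SpiroSeries":
        m = (self.time >= start) & (self.time <= end)
        return SpiroSeries(self.time[m], self.vo2[m], self.vco2[m],
                           None if self.hr is None else self.hr[m])


@dataclass
class GmeRecord:
    """Gross mechanical efficiency with its screening provenance."""

    ee: float                 # W
    po: float                 # W
    rer: float
    gme: float | None         # percent; None when discarded
    discarded: bool


def energy_expenditure(series: SpiroSeries,
                       window: tuple[float, float],
                       settings: EnergeticsSettings | None = None,
                       vo2_in_l_per_s: bool = False) -> float:
    """Mean metabolic rate (W) over ``window`` from breath records.

    Requires at least three breaths with midpoint inside the window. VO2 is
    in L/min by convention; pass ``vo2_in_l_per_s=True`` if the series is
    already in L/s (the result is identical up to the factor 60 handled
    here).
    """
    cfg = settings or EnergeticsSettings()
    sub = series.window(*window)
    if sub.time.size < 3:
        raise DataError(
            f"window ({window[0]:.1f}, {window[1]:.1f}) s holds only "
            f"{sub.time.size} breaths (need >= 3)"
        )
    vo2 = float(np.mean(sub.vo2))
    rer = float(np.mean(sub.vco2)) / vo2
    e_kj_per_l = cfg.o2_equiv_slope * rer + cfg.o2_equiv_intercept
    vo2_l_per_s = vo2 if vo2_in_l_per_s else vo2 / 60.0
    return vo2_l_per_s * e_kj_per_l * 1000.0


def mean_rer(series: SpiroSeries, window: tuple[float, float]) -> float:
    sub = series.window(*window)
    if sub.time.size == 0:
        raise DataError("window holds no breaths")
    return float(np.mean(sub.vco2)) / float(np.mean(sub.vo2))


def gross_mechanical_efficiency(ee: float, po: float, rer: float) -> GmeRecord:
    """GME(%) = PO / EE * 100, discarded (null) when ``rer > 1.0``."""
    if ee <= 0:
        raise DataError(f"energy expenditure must be positive, got {ee}")
    if po < 0:
        raise DataError(f"power output must be non-negative, got {po}")
    discarded = rer > 1.0
    gme: float | None
    if discarded:
        gme = None
    else:
        gme = po / ee * 100.0
        if gme >= 100.0:
            raise DataError(
                f"GME {gme:.1f}% >= 100% is non-physiological; check units"
            )
    return GmeRecord(ee=ee, po=po, rer=rer, gme=gme, discarded=discarded)


def session_physiology(series: SpiroSeries,
                       blocks: list[tuple[float, float]],
                       block_powers: list[float],
                       settings: EnergeticsSettings | None = None,
                       window_s: float = 60.0) -> dict:
    """Session-level physiological means from one spirometry recording.

    For each block the last ``window_s`` seconds are used; block means are
    then averaged across blocks. The RER screen is applied once, to the
    session-mean RER. Missing heart rate leaves ``hr`` as NaN while the
    other quantities are still computed.
    """
    if len(blocks) != len(block_powers):
        raise DataError("blocks and block_powers must have equal length")
    ee_b, rer_b, hr_b = [], [], []
    for start, end in blocks:
        win = (end - window_s, end)
        ee_b.append(energy_expenditure(series, win, settings))
        rer_b.append(mean_rer(series, win))
        if series.hr is None:
            hr_b.append(math.nan)
        else:
            sub = series.window(*win)
            hr_b.append(float(np.mean(sub.hr)))
    ee = float(np.mean(ee_b))
    rer = float(np.mean(rer_b))
    po = float(np.mean(block_powers))
    rec = gross_mechanical_efficiency(ee, po, rer)
    return {
        "ee": ee,
        "rer": rer,
        "hr": float(np.mean(hr_b)),
        "po": po,
        "gme": rec.gme,
        "discarded": rec.discarded,
    }
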