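"""Ergometer kinetics: filtering, push segmentation and per-push variables.

The raw signal is the force each hand exerts on the instrumented roller plus
the wheel's linear velocity, per side, at a fixed sample rate. Force is
low-pass filtered (zero-phase Butterworth), pushes are segmented by
hysteresis thresholding on wheel torque, and per-push propulsion-technique
variables (contact angle, push/cycle time, mean/peak torque and power, work)
are integrated on the sampled grid. Session values are the means over pushes
fully inside the last minute of each block, averaged over the left and right
side and then over the three blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import signal as sps

from .config import DetectionSettings, FilterSettings
from .errors import DataError


@dataclass
class ErgometerSignal:
    """Per-side ergometer time series.

    ``force`` is the hand force on the roller (N), ``velocity`` the wheel
    linear speed (m/s). The time base must be uniform; velocity must be
    non-negative (the roller cannot spin backward in this protocol).
    """

    time: np.ndarray
    force: np.ndarray
    velocity: np.ndarray
    side: str = "left"
    wheel_radius: float = 0.355

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.time.size
        if n < 2:
            raise DataError("signal needs at least two samples")
        if self.force.size != n or self.velocity.size != n:
            raise DataError("time, force and velocity must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise DataError(
                "time base must be uniform within 1e-6 s "
                f"(spread {np.ptp(dt):.2e} s)"
            )
        if np.min(self.velocity) < -1e-9:
            raise DataError("velocity must be non-negative throughout")
        if self.wheel_radius <= 0:
            raise DataError("wheel_radius must be strictly positive")
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def torque(self) -> np.ndarray:
        """Wheel torque, N*m (force referred to the wheel radius)."""
        return self.force * self.wheel_radius

    def replace(self, **kw) -> "ErgometerSignal":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(kw)
        return ErgometerSignal(**data)


@dataclass
class Push:
    """One detected propulsion cycle with its kinetic metrics."""

    start: float
    end: float
    push_time: float
    contact_angle: float     # degrees of wheel rotation during contact
    mean_torque: float       # N*m, time average over the push
    peak_torque: float       # N*m
    mean_power: float        # W, time average over the push
    peak_power: float        # W
    work: float              # J
    side: str = "left"
    cycle_time: float | None = None  # onset-to-next-onset; None for last push


@dataclass
class SessionSummary:
    """Per-session means (the long-format row fed to the statistics)."""

    session: int
    speed: float = math.nan
    power: float = math.nan
    rpe: float = math.nan
    hr: float = math.nan
    ee: float = math.nan
    rer: float = math.nan
    gme: float | None = None
    contact_angle: float = math.nan
    push_time: float = math.nan
    cycle_time: float = math.nan
    mean_torque: float = math.nan
    peak_torque: float = math.nan
    work: float = math.nan
    mean_power: float = math.nan
    peak_power: float = math.nan
    missing: tuple = ()
    block_powers: tuple = ()

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)
               if f.name not in ("missing", "block_powers")}
        out["gme"] = math.nan if self.gme is None else self.gme
        return out


# ---------------------------------------------------------------------------
# filtering


def filter_signal(signal: ErgometerSignal,
                  cutoff: float = 15.0,
                  order: int = 4) -> ErgometerSignal:
    """Zero-phase low-pass Butterworth filter of the force channel.

    The stated order is the design order; applying it forward-backward
    doubles the effective magnitude order and cancels the phase. Velocity is
    passed through unchanged. Raises for a cutoff at or above Nyquist or a
    signal too short for stable padding.
    """
    fs = signal.sample_rate
    if cutoff >= fs / 2.0:
        raise DataError(
            f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2.0} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if signal.time.size <= 3 * padlen:
        raise DataError(
            f"signal too short to filter ({signal.time.size} samples, "
            f"need > {3 * padlen})"
        )
    force = sps.sosfiltfilt(sos, signal.force)
    return signal.replace(force=force)


# ---------------------------------------------------------------------------
# segmentation


def _mask_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index intervals [i0, i1] (inclusive) of True runs in ``mask``."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[k]), int(idx[k + 1] - 1)) for k in range(0, idx.size, 2)]


def detect_pushes(signal: ErgometerSignal,
                  settings: DetectionSettings | None = None,
                  threshold: float | None = None) -> list[tuple[float, float]]:
    """Segment pushes from a (filtered) ergometer signal.

    Returns non-overlapping ``(start, end)`` time intervals, time-ordered.
    ``threshold`` overrides the automatic onset threshold (N*m); otherwise
    the onset threshold is ``max(min_torque_nm, rel_peak * median peak)``
    over the block. An empty or all-zero signal yields an empty list.
    """
    cfg = settings or DetectionSettings()
    tau = signal.torque
    t = signal.time
    dt = signal.dt

    if threshold is None:
        coarse = [seg for seg in _mask_segments(tau > cfg.min_torque_nm)]
        if not coarse:
            return []
        peaks = [float(np.max(tau[i0:i1 + 1])) for i0, i1 in coarse]
        thr_on = max(cfg.min_torque_nm, cfg.rel_peak * float(np.median(peaks)))
    else:
        thr_on = float(threshold)
    thr_off = cfg.off_frac * thr_on

    segs = [seg for seg in _mask_segments(tau > thr_off)
            if np.max(tau[seg[0]:seg[1] + 1]) > thr_on]
    if not segs:
        return []

    # merge segments separated by less than merge_gap_s
    merged: list[list[int]] = [list(segs[0])]
    for i0, i1 in segs[1:]:
        if (i0 - merged[-1][1]) * dt < cfg.merge_gap_s:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    # refine edges toward the zero crossing of the torque so threshold
    # height does not clip the push; the walk requires torque to keep
    # falling outward and stops at the gap noise level (zero for clean
    # signals, so noise-free edges are recovered exactly)
    if cfg.refine_to_zero:
        in_seg = np.zeros(tau.size, dtype=bool)
        for i0, i1 in merged:
            in_seg[i0:i1 + 1] = True
        gap = tau[~in_seg]
        if gap.size:
            med = np.median(gap)
            sigma = 1.4826 * float(np.median(np.abs(gap - med)))
        else:
            sigma = 0.0
        stop = 2.0 * sigma
        prev_end = -1
        for k, (i0, i1) in enumerate(merged):
            while i0 - 1 > prev_end and stop < tau[i0 - 1] < tau[i0]:
                i0 -= 1
            nxt = merged[k + 1][0] if k + 1 < len(merged) else tau.size
            while i1 + 1 < nxt and stop < tau[i1 + 1] < tau[i1]:
                i1 += 1
            merged[k] = [i0, i1]
            prev_end = i1

    out = [(float(t[i0]), float(t[i1])) for i0, i1 in merged
           if (i1 - i0) * dt >= cfg.min_duration_s]
    return out


# ---------------------------------------------------------------------------
# per-push metrics


def compute_push_metrics(signal: ErgometerSignal,
                         interval: tuple[float, float]) -> Push:
    """Integrate the propulsion-technique variables over one push.

    Torque is force times wheel radius; instantaneous power is force times
    velocity; work is the trapezoidal integral of power; contact angle is the
    integral of wheel angular velocity over the push, in degrees. Mean torque
    and power are trapezoidal time averages over the contact interval.
    """
    start, end = interval
    if not (signal.time[0] - 1e-9 <= start < end <= signal.time[-1] + 1e-9):
        raise DataError(f"interval ({start}, {end}) outside signal extent")
    i0 = int(np.searchsorted(signal.time, start - 1e-9, side="left"))
    i1 = int(np.searchsorted(signal.time, end + 1e-9, side="right"))
    if i1 - i0 < 2:
        raise DataError(
            f"interval ({start}, {end}) spans fewer than 2 samples"
        )
    t = signal.time[i0:i1]
    f = signal.force[i0:i1]
    v = signal.velocity[i0:i1]
    r = signal.wheel_radius
    tau = f * r
    power = f * v
    duration = float(t[-1] - t[0])
    work = float(np.trapezoid(power, t))
    contact = math.degrees(float(np.trapezoid(v / r, t)))
    return Push(
        start=float(t[0]),
        end=float(t[-1]),
        push_time=duration,
        contact_angle=contact,
        mean_torque=float(np.trapezoid(tau, t)) / duration,
        peak_torque=float(np.max(tau)),
        mean_power=float(np.trapezoid(power, t)) / duration,
        peak_power=float(np.max(power)),
        work=work,
        side=signal.side,
    )


def extract_pushes(signal: ErgometerSignal,
                   detection: DetectionSettings | None = None,
                   filter_settings: FilterSettings | None = None,
                   prefiltered: bool = False,
                   window: tuple[float, float] | None = None) -> list[Push]:
    """Filter, segment and measure every push in a signal.

    ``cycle_time`` is assigned as onset-to-next-onset; the final detected
    push has ``cycle_time=None``. With ``window`` set, metrics are computed
    only for pushes fully inside it (detection still sees the whole signal,
    so the cycle time of the last windowed push remains defined).
    """
    fcfg = filter_settings or FilterSettings()
    sig = signal if prefiltered else filter_signal(
        signal, cutoff=fcfg.cutoff_hz, order=fcfg.order)
    intervals = detect_pushes(sig, detection)
    onsets = [s for s, _ in intervals]
    pushes: list[Push] = []
    for k, iv in enumerate(intervals):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else None
        if window is not None and not (window[0] <= iv[0] and iv[1] <= window[1]):
            continue
        p = compute_push_metrics(sig, iv)
        p.cycle_time = None if nxt is None else nxt - iv[0]
        pushes.append(p)
    return pushes


# ---------------------------------------------------------------------------
# session aggregation

_PUSH_VARS = ("contact_angle", "push_time", "cycle_time", "mean_torque",
              "peak_torque", "work", "mean_power", "peak_power")


def _side_means(pushes: list[Push]) -> dict[str, float]:
    out: dict[str, float] = {}
    for var in _PUSH_VARS:
        vals = [getattr(p, var) for p in pushes
                if getattr(p, var) is not None]
        out[var] = float(np.mean(vals)) if vals else math.nan
    return out


def aggregate_session(blocks: list[tuple[ErgometerSignal, ErgometerSignal]],
                      session: int = 1,
                      window_s: float = 60.0,
                      detection: DetectionSettings | None = None,
                      filter_settings: FilterSettings | None = None) -> SessionSummary:
    """Aggregate per-push metrics to one steady-state session row.

    For each block the last ``window_s`` seconds are used (steady state
    assumed); per-push variables are averaged over pushes fully inside the
    window, per side, then side-averaged, then block-averaged. ``speed`` is
    the side-mean wheel velocity over the window and ``power`` the mean total
    instantaneous push power (left + right) over the window. A block whose
    window holds no detected pushes contributes missing values, not zeros,
    and is recorded in ``missing``.
    """
    if not blocks:
        raise DataError("aggregate_session needs at least one block")
    block_rows: list[dict[str, float]] = []
    block_speed: list[float] = []
    block_power: list[float] = []
    missing: list[str] = []
    for b, sides in enumerate(blocks):
        left, right = sides
        w1 = float(left.time[-1])
        w0 = w1 - window_s
        side_stats = []
        for sig in (left, right):
            fcfg = filter_settings or FilterSettings()
            filt = filter_signal(sig, cutoff=fcfg.cutoff_hz, order=fcfg.order)
            pushes = extract_pushes(filt, detection, prefiltered=True,
                                    window=(w0, w1))
            if not pushes:
                missing.append(f"block{b + 1}:{sig.side}:no pushes in window")
                side_stats.append({var: math.nan for var in _PUSH_VARS})
            else:
                side_stats.append(_side_means(pushes))
        row = {var: float(np.mean([s[var] for s in side_stats]))
               for var in _PUSH_VARS}
        block_rows.append(row)
        m = (left.time >= w0) & (left.time <= w1)
        v_mean = 0.5 * (left.velocity[m].mean() + right.velocity[m].mean())
        p_tot = (left.force[m] * left.velocity[m]
                 + right.force[m] * right.velocity[m])
        block_speed.append(float(v_mean))
        block_power.append(float(p_tot.mean()))

    summary = SessionSummary(
        session=session,
        speed=float(np.mean(block_speed)),
        power=float(np.mean(block_power)),
        missing=tuple(missing),
        block_powers=tuple(block_power),
    )
    for var in _PUSH_VARS:
        vals = [row[var] for row in block_rows]
        setattr(summary, var, float(np.nanmean(vals))
                if not all(math.isnan(v) for v in vals) else math.nan)
    return summary
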