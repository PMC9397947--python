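"""CSV schemas, study directory layout and ground-truth sidecars.

All files are comma-separated UTF-8 with a header row; time is in seconds
and SI units are spelled in the column names:

* ``signals.csv`` — ``time_s, side, force_N, velocity_ms`` (both sides in
  one file, one block per file);
* ``breaths.csv`` — ``time_s, vo2_Lmin, vco2_Lmin, hr_bpm`` (hr optional);
* ``markers.csv`` — ``time_s, x_m, y_m``;
* ``summary.csv`` — one long-format row per subject-session.

A simulated study on disk is laid out as
``<root>/subject01/session1/{block1_signals.csv, ..., breaths.csv,
markers_block1.csv, meta.yaml, truth.json}``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import StudyConfig
from .errors import DataError
from .kinetics import ErgometerSignal
from .patterns import MarkerTrajectory
from .physiology import SpiroSeries

log = logging.getLogger("handrim")

SIGNALS_COLUMNS = ("time_s", "side", "force_N", "velocity_ms")
BREATHS_COLUMNS = ("time_s", "vo2_Lmin", "vco2_Lmin")
MARKERS_COLUMNS = ("time_s", "x_m", "y_m")

#: a time step larger than this many nominal steps is reported as a gap
GAP_FACTOR = 5


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: no data") from None
    if df.empty:
        raise DataError(f"{path}: no data")
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(
            f"{path}: missing columns {sorted(missing)}; "
            f"expected header with {required} (units in names)"
        )
    for col in required:
        if col == "side":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DataError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{int(bad[0]) + 2}"
            )
        df[col] = vals
    return df


def _check_time(path, time: np.ndarray, check_gaps: bool = True) -> None:
    """Monotonicity always; gap reporting only for uniformly sampled
    instrument streams (breath records are event-based, so block pauses are
    expected there, not gaps)."""
    if np.any(np.diff(time) <= 0):
        i = int(np.argmax(np.diff(time) <= 0))
        raise DataError(
            f"{path}: time not strictly increasing at line {i + 2}"
        )
    dt = np.diff(time)
    if check_gaps and dt.size:
        nominal = float(np.median(dt))
        gaps = np.flatnonzero(dt > GAP_FACTOR * nominal)
        for i in gaps:
            msg = (f"{path}: gap of {dt[i]:.3f} s (> {GAP_FACTOR} samples) "
                   f"after line {int(i) + 2}; gap interpolation refused")
            log.warning(msg)
            warnings.warn(msg, stacklevel=3)


# ---------------------------------------------------------------------------
# signals


def write_signals(path: str | Path, left: ErgometerSignal,
                  right: ErgometerSignal) -> None:
    frames = []
    for sig in (left, right):
        frames.append(pd.DataFrame({
            "time_s": sig.time, "side": sig.side,
            "force_N": sig.force, "velocity_ms": sig.velocity,
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_signals(path: str | Path, wheel_radius: float = 0.355
                 ) -> dict[str, ErgometerSignal]:
    """Read a per-block signals file into per-side typed series."""
    df = _read_csv(path, SIGNALS_COLUMNS)
    out: dict[str, ErgometerSignal] = {}
    for side, grp in df.groupby("side"):
        if side not in ("left", "right"):
            raise DataError(f"{path}: unknown side {side!r}")
        time = grp["time_s"].to_numpy()
        _check_time(path, time)
        try:
            out[str(side)] = ErgometerSignal(
                time, grp["force_N"].to_numpy(),
                grp["velocity_ms"].to_numpy(),
                side=str(side), wheel_radius=wheel_radius)
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from None
    if not out:
        raise DataError(f"{path}: no data")
    return out


# ---------------------------------------------------------------------------
# breaths


def write_breaths(path: str | Path, series: SpiroSeries) -> None:
    df = pd.DataFrame({"time_s": series.time, "vo2_Lmin": series.vo2,
                       "vco2_Lmin": series.vco2})
    if series.hr is not None:
        df["hr_bpm"] = series.hr
    df.to_csv(path, index=False)


def read_breaths(path: str | Path) -> SpiroSeries:
    df = _read_csv(path, BREATHS_COLUMNS)
    time = df["time_s"].to_numpy()
    _check_time(path, time, check_gaps=False)
    hr = None
    if "hr_bpm" in df.columns:
        hr = pd.to_numeric(df["hr_bpm"], errors="coerce").to_numpy()
    try:
        return SpiroSeries(time, df["vo2_Lmin"].to_numpy(),
                           df["vco2_Lmin"].to_numpy(), hr)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# markers


def write_markers(path: str | Path, traj: MarkerTrajectory) -> None:
    pd.DataFrame({"time_s": traj.time, "x_m": traj.x,
                  "y_m": traj.y}).to_csv(path, index=False)


def read_markers(path: str | Path, rim_radius: float = 0.19,
                 push_intervals: list | None = None) -> MarkerTrajectory:
    df = _read_csv(path, MARKERS_COLUMNS)
    time = df["time_s"].to_numpy()
    _check_time(path, time)
    try:
        return MarkerTrajectory(time, df["x_m"].to_numpy(),
                                df["y_m"].to_numpy(), rim_radius=rim_radius,
                                push_intervals=push_intervals or [])
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# study directory layout


def session_dir(root: str | Path, subject: int, session: int) -> Path:
    return Path(root) / f"subject{subject:02d}" / f"session{session}"


def write_session(sim, root: str | Path) -> Path:
    """Write one simulated subject-session in the study layout, including a
    ground-truth JSON sidecar for oracle tests."""
    d = session_dir(root, sim.subject, sim.session)
    d.mkdir(parents=True, exist_ok=True)
    truth = {"params": sim.truth, "rpe": sim.rpe, "pattern": sim.pattern,
             "pushes": []}
    for b, (left, right, block_truth) in enumerate(sim.blocks, start=1):
        write_signals(d / f"block{b}_signals.csv", left, right)
        truth["pushes"].append(block_truth)
    if sim.spiro is not None:
        write_breaths(d / "breaths.csv", sim.spiro)
    for b, traj in enumerate(sim.markers, start=1):
        write_markers(d / f"markers_block{b}.csv", traj)
    meta = {"subject": sim.subject, "session": sim.session,
            "rpe": float(sim.rpe),
            "block_windows": [[float(a), float(b)]
                              for a, b in sim.block_windows]}
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))
    (d / "truth.json").write_text(json.dumps(truth, indent=1))
    return d


def read_session(d: str | Path, wheel_radius: float = 0.355,
                 rim_radius: float = 0.19):
    """Read one session directory back into a SessionSim-shaped object."""
    from .synthetic import SessionSim  # deferred: io must not require synthesis

    d = Path(d)
    meta_path = d / "meta.yaml"
    if not meta_path.exists():
        raise DataError(f"{d}: missing meta.yaml")
    meta = yaml.safe_load(meta_path.read_text())
    sim = SessionSim(subject=int(meta["subject"]),
                     session=int(meta["session"]))
    sim.rpe = float(meta.get("rpe", float("nan")))
    sim.block_windows = [tuple(w) for w in meta.get("block_windows", [])]
    for f in sorted(d.glob("block*_signals.csv")):
        sides = read_signals(f, wheel_radius=wheel_radius)
        if set(sides) != {"left", "right"}:
            raise DataError(f"{f}: needs both left and right side rows")
        sim.blocks.append((sides["left"], sides["right"], None))
    if not sim.blocks:
        raise DataError(f"{d}: no block signal files")
    breaths = d / "breaths.csv"
    if breaths.exists():
        sim.spiro = read_breaths(breaths)
    for f in sorted(d.glob("markers_block*.csv")):
        sim.markers.append(read_markers(f, rim_radius=rim_radius))
    return sim


def write_study_config(config: StudyConfig, root: str | Path) -> Path:
    path = Path(root) / "config.yaml"
    config.to_yaml(path)
    return path
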