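"""End-to-end orchestration: signals -> session rows -> statistics report.

``analyze_session`` turns one subject-session's raw inputs into a
long-format summary row (plus per-block technique labels when marker data
are present). ``analyze_study`` maps that over a simulated or on-disk study
and ``run_stats`` fits the learning model and the expert-comparison t-test
for each outcome, mirroring the session-by-session summary table of the
underlying protocol.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import reference
from .config import StudyConfig
from .errors import DataError
from .kinetics import aggregate_session
from .patterns import classify_pattern, session_label
from .physiology import session_physiology
from .stats import athlete_comparison, fit_learning_model
from .synthetic import simulate_study

log = logging.getLogger("handrim")

#: outcomes carried in the long-format summary table
SUMMARY_OUTCOMES = ("speed", "power", "rpe", "hr", "ee", "gme",
                    "contact_angle", "push_time", "cycle_time",
                    "mean_torque", "peak_torque", "work",
                    "mean_power", "peak_power")


def analyze_session(sim, config: StudyConfig | None = None
                    ) -> tuple[dict, list[dict]]:
    """One subject-session: kinetic aggregation, physiology and labels.

    Returns ``(summary_row, label_rows)``; ``label_rows`` has one entry per
    block with marker data plus one session-level consensus entry.
    """
    cfg = config or StudyConfig()
    summary = aggregate_session(
        [(left, right) for left, right, _ in sim.blocks],
        session=sim.session,
        detection=cfg.detection, filter_settings=cfg.filter)
    row = summary.to_dict()
    row["subject"] = sim.subject
    row["rpe"] = sim.rpe
    for item in summary.missing:
        log.warning("subject %s session %s: missing %s",
                    sim.subject, sim.session, item)

    if sim.spiro is not None and sim.block_windows:
        phys = session_physiology(sim.spiro, list(sim.block_windows),
                                  list(summary.block_powers),
                                  settings=cfg.energetics)
        row["hr"] = phys["hr"]
        row["rer"] = phys["rer"]
        row["ee"] = phys["ee"]
        row["gme"] = math.nan if phys["gme"] is None else phys["gme"]
        if phys["discarded"]:
            log.info("subject %s session %s: GME discarded (mean RER %.3f "
                     "> 1.0)", sim.subject, sim.session, phys["rer"])

    labels: list[dict] = []
    if sim.markers:
        block_labels = []
        for b, traj in enumerate(sim.markers, start=1):
            lab = classify_pattern(traj, cfg.classifier, block=b,
                                   session=sim.session)
            block_labels.append(lab)
            labels.append({"subject": sim.subject, "session": sim.session,
                           "block": b, "source": "auto", "label": lab.label})
        sess = session_label(block_labels)
        labels.append({"subject": sim.subject, "session": sim.session,
                       "block": None, "source": "auto", "label": sess.label})
    return row, labels


def _collect(sessions, config: StudyConfig | None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, label_rows = [], []
    for sim in sessions:
        row, labels = analyze_session(sim, config)
        rows.append(row)
        label_rows.extend(labels)
    summary = pd.DataFrame(rows).sort_values(["subject", "session"])
    cols = ["subject", "session"] + [c for c in summary.columns
                                     if c not in ("subject", "session")]
    labels_df = pd.DataFrame(
        label_rows, columns=["subject", "session", "block", "source", "label"])
    return summary[cols].reset_index(drop=True), labels_df


def analyze_study(config: StudyConfig | None = None, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse a complete practice study in memory.

    Returns the long-format session summary (one row per subject-session)
    and the technique-label table for the kinematic sessions.
    """
    cfg = config or StudyConfig()
    return _collect(simulate_study(cfg, seed=seed), cfg)


def analyze_directory(input_dir: str | Path,
                      config: StudyConfig | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse an on-disk study laid out as written by :func:`handrim.io.write_session`."""
    cfg = config or StudyConfig()
    root = Path(input_dir)
    session_dirs = sorted(root.glob("subject*/session*"))
    if not session_dirs:
        raise DataError(f"{root}: no subject*/session* directories found")
    sims = (hio.read_session(d, wheel_radius=cfg.sim.wheel_radius,
                             rim_radius=cfg.sim.rim_radius)
            for d in session_dirs)
    return _collect(sims, cfg)


def run_stats(summary: pd.DataFrame,
              outcomes: tuple[str, ...] | None = None,
              athlete: dict | None = None,
              sided: str = "one") -> pd.DataFrame:
    """Learning-model LRT and expert-comparison t-test per outcome.

    The mixed model controls for speed, so ``speed`` itself is reported
    with the t-test only. GME rows discarded by the RER screen enter as
    missing and reduce the t-test n for that outcome.
    """
    ref = athlete or reference.ATHLETE
    outs = outcomes or [o for o in SUMMARY_OUTCOMES if o in summary.columns]
    last = summary["session"].max()
    records = []
    for outcome in outs:
        rec: dict = {"outcome": outcome}
        if outcome != "speed":
            try:
                lmm = fit_learning_model(summary, outcome)
                rec.update(slope_session=lmm.slope_session,
                           se_session=lmm.se_session,
                           slope_speed=lmm.slope_speed,
                           chi2=lmm.chi2, p_lrt=lmm.p,
                           converged=lmm.converged, singular=lmm.singular)
            except DataError as exc:
                log.warning("learning model for %s failed: %s", outcome, exc)
        if outcome in ref:
            vals = summary.loc[summary["session"] == last, outcome]
            tt = athlete_comparison(vals.to_numpy(), ref=ref[outcome],
                                    sided=sided)
            rec.update(t=tt.t, p_t=tt.p, n_t=tt.n, athlete=ref[outcome])
        records.append(rec)
    return pd.DataFrame(records)


def run_pipeline(input_dir: str | Path, output_dir: str | Path,
                 config: StudyConfig | None = None) -> dict[str, Path]:
    """Disk-to-disk pipeline: read a study tree, write summary, labels and
    statistics CSVs plus a missing-data manifest. Returns the output paths."""
    cfg = config or StudyConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary, labels = analyze_directory(input_dir, cfg)
    paths = {"summary": out / "summary.csv", "labels": out / "labels.csv",
             "stats": out / "stats.csv", "manifest": out / "manifest.txt"}
    summary.to_csv(paths["summary"], index=False, float_format="%.6g")
    labels.to_csv(paths["labels"], index=False)
    manifest = []
    n_missing = int(summary[list(SUMMARY_OUTCOMES)].isna().sum().sum())
    manifest.append(f"rows: {len(summary)}")
    manifest.append(f"missing values in summary: {n_missing}")
    for col in SUMMARY_OUTCOMES:
        miss = summary[summary[col].isna()]
        for _, r in miss.iterrows():
            manifest.append(
                f"missing {col}: subject {int(r['subject'])} "
                f"session {int(r['session'])}")
    try:
        stats = run_stats(summary)
        stats.to_csv(paths["stats"], index=False, float_format="%.6g")
    except DataError as exc:
        manifest.append(f"statistics skipped: {exc}")
        paths.pop("stats")
    paths["manifest"].write_text("\n".join(manifest) + "\n")
    return paths
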