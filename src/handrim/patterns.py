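"""Propulsion-pattern classification and inter-rater agreement.

The four Boninger propulsion patterns are judged from the sagittal-plane
path of the second-metacarpal (M2) marker relative to the handrim circle
during the recovery phase:

* **ARC** — the hand hugs the rim closely on the way back;
* **SLOP** — the hand passes *over* the rim during recovery;
* **SC** — the hand dips *under* the rim in a circular/elliptic motion;
* **DLOP** — the hand goes over, crosses, and then under the rim.

The automated rule operationalizes this visual judgment: recovery samples
are scored against the rim circle with a tolerance band of ``band_frac``
times the rim radius; an above/below excursion counts when at least
``min_excursion_samples`` consecutive samples lie beyond the band. Presence
of an above-excursion (A) and below-excursion (B) maps to
(A and B) -> DLOP, (A only) -> SLOP, (B only) -> SC, (neither) -> ARC.

Session labels follow the block-majority rule with ties broken by the last
block; rater agreement is quantified with Fleiss' kappa and interpreted on
the Landis-Koch scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .config import ClassifierSettings
from .errors import DataError

PATTERNS = ("ARC", "DLOP", "SC", "SLOP")


@dataclass
class PatternLabel:
    """Categorical propulsion technique with provenance."""

    label: str
    source: str = "auto"          # "auto" or "rater"
    block: int | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        if self.label not in PATTERNS:
            raise DataError(
                f"unknown pattern {self.label!r}; expected one of {PATTERNS}"
            )


@dataclass
class MarkerTrajectory:
    """2-D hand-marker path in the wheel plane, hub origin.

    ``x`` is horizontal (forward positive), ``y`` vertical (up positive),
    both in metres. ``push_intervals`` give hand-rim contact times; when
    empty, contact is inferred from rim proximity.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rim_radius: float
    push_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.time.size or self.y.size != self.time.size:
            raise DataError("time, x and y must have equal length")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if self.rim_radius <= 0:
            raise DataError("rim_radius must be strictly positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


# ---------------------------------------------------------------------------
# recovery-phase geometry


def rim_deviation(x: np.ndarray, y: np.ndarray, rim_radius: float) -> np.ndarray:
    """Signed above(+)/below(-) deviation of points from the rim circle.

    Inside the wheel silhouette (|x| < rim radius, y > 0) the deviation is
    vertical distance from the upper rim arc; elsewhere it falls back to the
    radial distance from the circle (outside positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    radial = np.hypot(x, y) - rim_radius
    dev = radial.copy()
    m = (np.abs(x) < rim_radius) & (y > 0)
    dev[m] = y[m] - np.sqrt(rim_radius ** 2 - x[m] ** 2)
    return dev


def recovery_intervals(traj: MarkerTrajectory,
                       settings: ClassifierSettings | None = None
                       ) -> list[tuple[float, float]]:
    """Recovery phases as the complement of the push intervals.

    Marker-only input (no push intervals) infers contact from rim proximity:
    samples within the tolerance band of the rim circle count as contact.
    """
    cfg = settings or ClassifierSettings()
    t0, t1 = float(traj.time[0]), float(traj.time[-1])
    if traj.push_intervals:
        pushes = sorted((float(a), float(b)) for a, b in traj.push_intervals)
    else:
        eps = cfg.band_frac * traj.rim_radius
        contact = np.abs(rim_deviation(traj.x, traj.y, traj.rim_radius)) < eps
        idx = np.flatnonzero(np.diff(np.concatenate(
            ([0], contact.view(np.int8), [0]))))
        pushes = [(float(traj.time[idx[k]]),
                   float(traj.time[min(idx[k + 1] - 1, traj.time.size - 1)]))
                  for k in range(0, idx.size, 2)]
    out: list[tuple[float, float]] = []
    prev = t0
    for a, b in pushes:
        if a > prev:
            out.append((prev, a))
        prev = max(prev, b)
    if t1 > prev:
        out.append((prev, t1))
    min_span = 3.0 / _sample_rate(traj)
    return [(a, b) for a, b in out if b - a >= min_span]


def _sample_rate(traj: MarkerTrajectory) -> float:
    return 1.0 / float(np.median(np.diff(traj.time)))


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    run = 0
    for v in mask:
        run = run + 1 if v else 0
        if run >= min_len:
            return True
    return False


def _modal_last(labels: list[str]) -> str:
    """Most frequent label; ties broken by the label observed last."""
    counts = Counter(labels)
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    for lab in reversed(labels):
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def classify_recovery(traj: MarkerTrajectory,
                      interval: tuple[float, float],
                      settings: ClassifierSettings | None = None) -> str:
    cfg = settings or ClassifierSettings()
    eps = cfg.band_frac * traj.rim_radius
    m = (traj.time >= interval[0]) & (traj.time <= interval[1])
    dev = rim_deviation(traj.x[m], traj.y[m], traj.rim_radius)
    above = _has_run(dev > eps, cfg.min_excursion_samples)
    below = _has_run(dev < -eps, cfg.min_excursion_samples)
    if above and below:
        return "DLOP"
    if above:
        return "SLOP"
    if below:
        return "SC"
    return "ARC"


def classify_pattern(traj: MarkerTrajectory,
                     settings: ClassifierSettings | None = None,
                     block: int | None = None,
                     session: int | None = None) -> PatternLabel:
    """Classify the propulsion technique of one trajectory window.

    Each recovery phase is scored independently; the trajectory label is the
    majority over recoveries (ties broken by the most recent recovery).
    """
    cfg = settings or ClassifierSettings()
    recs = recovery_intervals(traj, cfg)
    if not recs:
        if not traj.push_intervals:
            dev = rim_deviation(traj.x, traj.y, traj.rim_radius)
            if np.max(np.abs(dev)) < cfg.band_frac * traj.rim_radius:
                # marker-only input whose path never leaves the rim band:
                # that is the arcing pattern by definition
                return PatternLabel("ARC", source="auto", block=block,
                                    session=session)
        raise DataError("trajectory holds no recovery phase")
    labels = [classify_recovery(traj, iv, cfg) for iv in recs]
    return PatternLabel(_modal_last(labels), source="auto",
                        block=block, session=session)


# ---------------------------------------------------------------------------
# label aggregation


def _as_str(label) -> str:
    return label.label if isinstance(label, PatternLabel) else str(label)


def session_label(block_labels: list) -> PatternLabel:
    """Session technique: modal label over blocks, ties -> last block."""
    if not block_labels:
        raise DataError("session_label needs at least one block label")
    labels = [_as_str(lab) for lab in block_labels]
    sess = next((lab.session for lab in block_labels
                 if isinstance(lab, PatternLabel)), None)
    return PatternLabel(_modal_last(labels), source="auto", session=sess)


def consensus_label(rater_labels: list) -> PatternLabel:
    """Consensus over raters' session labels (modal, ties -> last rater)."""
    if not rater_labels:
        raise DataError("consensus_label needs at least one rater label")
    return PatternLabel(_modal_last([_as_str(lab) for lab in rater_labels]),
                        source="rater")


# ---------------------------------------------------------------------------
# agreement


@dataclass
class KappaResult:
    kappa: float
    band: str
    n_subjects: int
    n_raters: int
    degenerate: bool = False
    note: str = ""


def landis_koch_band(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def ratings_to_counts(table) -> np.ndarray:
    """Subjects x raters label matrix -> subjects x categories count matrix."""
    arr = np.asarray(table, dtype=object)
    if arr.ndim != 2:
        raise DataError("rating table must be 2-D (subjects x raters)")
    if any(v is None or (isinstance(v, float) and np.isnan(v))
           for v in arr.ravel()):
        raise DataError("rating table must be complete (no missing cells)")
    cats = sorted({str(v) for v in arr.ravel()})
    counts = np.zeros((arr.shape[0], len(cats)), dtype=int)
    for i, row in enumerate(arr):
        for v in row:
            counts[i, cats.index(str(v))] += 1
    return counts


def fleiss_kappa(table=None, counts=None) -> KappaResult:
    """Fleiss' kappa for a complete subjects x raters table.

    Accepts either a label matrix (``table``) or a pre-tabulated subjects x
    categories count matrix (``counts``). When every rating falls in a
    single category the expected agreement is 1 and kappa is undefined; the
    result is flagged degenerate rather than raising.
    """
    if (table is None) == (counts is None):
        raise DataError("provide exactly one of table or counts")
    c = ratings_to_counts(table) if counts is None else np.asarray(counts, int)
    if c.ndim != 2 or c.shape[0] < 2:
        raise DataError("kappa needs at least 2 subjects")
    n_raters = int(c[0].sum())
    if n_raters < 2 or np.any(c.sum(axis=1) != n_raters):
        raise DataError("every subject needs the same >= 2 raters")
    used = int(np.count_nonzero(c.sum(axis=0)))
    if used < 2:
        return KappaResult(
            kappa=float("nan"), band="undefined",
            n_subjects=c.shape[0], n_raters=n_raters, degenerate=True,
            note="all ratings fall in a single category; expected agreement "
                 "is 1 so kappa is undefined",
        )
    kappa = float(_sm_fleiss(c, method="fleiss"))
    return KappaResult(kappa=kappa, band=landis_koch_band(kappa),
                       n_subjects=c.shape[0], n_raters=n_raters)


# ---------------------------------------------------------------------------
# pre/post contingency


def technique_contingency(pre_labels: list, post_labels: list
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """4x4 pre/post technique contingency with totals and percentages.

    Rows are the post-test (last session) technique, columns the pre-test
    (first session) technique. Returns ``(counts, percent)`` DataFrames,
    both carrying a ``Total`` row and column; percentages are of the total
    number of paired subjects.
    """
    if len(pre_labels) != len(post_labels):
        raise DataError(
            f"pre ({len(pre_labels)}) and post ({len(post_labels)}) label "
            "lists differ in length"
        )
    if not pre_labels:
        raise DataError("empty label lists")
    pre = pd.Categorical([_as_str(v) for v in pre_labels], categories=PATTERNS)
    post = pd.Categorical([_as_str(v) for v in post_labels], categories=PATTERNS)
    counts = pd.crosstab(post, pre, dropna=False)
    counts = counts.reindex(index=PATTERNS, columns=PATTERNS, fill_value=0)
    counts.index.name = "post"
    counts.columns.name = "pre"
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    pct = counts / len(pre_labels) * 100.0
    return counts, pct


def format_contingency(counts: pd.DataFrame, pct: pd.DataFrame) -> pd.DataFrame:
    """Render a counts/percent pair as ``n (p%)`` strings."""
    out = pd.DataFrame(index=counts.index, columns=counts.columns,
                       dtype=object)
    for i in counts.index:
        for j in counts.columns:
            out.loc[i, j] = f"{int(counts.loc[i, j])} " \
                            f"({round(pct.loc[i, j]):.0f}%)"
    return out


def plot_trajectory(traj: MarkerTrajectory, ax=None, label: str | None = None):
    """Plot the marker path against the rim circle (sagittal view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(traj.rim_radius * np.sin(theta), traj.rim_radius * np.cos(theta),
            color="0.6", lw=1, label="handrim")
    ax.plot(traj.x, traj.y, lw=0.8, label=label or "M2 path")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m, forward)")
    ax.set_ylabel("y (m, up)")
    ax.legend(loc="lower right", fontsize="small")
    return ax
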