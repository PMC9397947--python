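"""Protocol physics and the study's statistical machinery.

Physics: the ergometer brakes the wheelchair with rolling friction
``F = mu * m * g``, so the external power needed to hold speed ``v`` is
``P = mu * m * g * v``; a free coast-down decelerates at ``mu * g``, which
is how ``mu`` is estimated in the first place.

Statistics: motor learning over the nine practice sessions is modelled with
a linear mixed-effects regression

    outcome ~ session + speed + (1 + session | subject)

fitted by maximum likelihood; the practice effect is tested with a
likelihood-ratio test against the model without the session fixed effect
(chi-square, 1 df). Final-session group values are compared with the single
expert reference via a one-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as spstats

from .config import ProtocolConfig
from .errors import DataError


def theoretical_power(mu: float, mass: float, speed: float,
                      g: float = 9.81) -> float:
    """External power (W) to overcome rolling friction at constant speed."""
    if min(mu, mass, speed, g) < 0:
        raise DataError("arguments must be non-negative")
    return mu * mass * g * speed


def coast_down_mu(time, velocity, g: float = 9.81) -> float:
    """Rolling-friction coefficient from a free-deceleration trace.

    Fits ``v(t)`` by least squares over a monotonically decreasing segment
    of at least one second; ``mu = |slope| / g``.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if t.size != v.size or t.size < 3:
        raise DataError("need >= 3 matching samples")
    if t[-1] - t[0] < 1.0:
        raise DataError("coast-down segment must span at least 1 s")
    if v[-1] >= v[0]:
        raise DataError("velocity trace is not decreasing")
    slope = np.polyfit(t, v, 1)[0]
    if slope >= 0:
        raise DataError("fitted slope is non-negative; not a coast-down")
    return float(-slope / g)


def speed_compliance(speed: float, config: ProtocolConfig | None = None) -> bool:
    """Whether a session mean speed lies within the target tolerance band."""
    cfg = config or ProtocolConfig()
    if speed < 0:
        raise DataError("speed must be non-negative")
    return abs(speed - cfg.target_speed) <= cfg.tolerance * cfg.target_speed


# ---------------------------------------------------------------------------
# mixed-effects learning model


@dataclass
class LmmResult:
    outcome: str
    slope_session: float
    se_session: float
    slope_speed: float
    se_speed: float
    intercept: float
    re_var_intercept: float
    re_var_session: float
    resid_var: float
    chi2: float
    p: float
    converged: bool
    singular: bool = False
    degenerate: bool = False
    n_obs: int = 0
    n_subjects: int = 0


def _fit_ml(formula: str, data: pd.DataFrame, subject_col: str):
    model = smf.mixedlm(formula, data, groups=data[subject_col],
                        re_formula="~session")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=200)
    singular = any("singular" in str(w.message).lower()
                   or "boundary" in str(w.message).lower() for w in caught)
    return res, singular


def fit_learning_model(data: pd.DataFrame, outcome: str, *,
                       session_col: str = "session",
                       speed_col: str = "speed",
                       subject_col: str = "subject") -> LmmResult:
    """Fit the learning model and test the practice effect by LRT.

    Both the full model (``outcome ~ session + speed``) and the reduced
    model without the session fixed effect are fitted by maximum likelihood
    with random intercepts and session slopes per subject; the
    likelihood-ratio chi-square has 1 df. Convergence and boundary
    (singular) fits are flagged honestly rather than hidden. Rows with
    missing outcome or speed are dropped (e.g. efficiency values discarded
    by the RER screen).
    """
    cols = {outcome, session_col, speed_col, subject_col}
    missing_cols = cols - set(data.columns)
    if missing_cols:
        raise DataError(f"missing columns: {sorted(missing_cols)}")
    df = data[[outcome, session_col, speed_col, subject_col]].dropna().copy()
    df = df.rename(columns={outcome: "_y", session_col: "session",
                            speed_col: "speed", subject_col: "_subject"})
    n_subj = df["_subject"].nunique()
    n_sess = df["session"].nunique()
    if n_subj < 2 or n_sess < 3:
        raise DataError(
            f"need >= 2 subjects and >= 3 sessions, got {n_subj} x {n_sess}"
        )

    # A perfect affine dependence on the fixed effects leaves no residual
    # variance; the variance components are then unidentifiable and the
    # mixed-model likelihood degenerates, so return the exact least-squares
    # solution instead.
    X = sm.add_constant(df[["session", "speed"]].to_numpy())
    beta, _, _, _ = np.linalg.lstsq(X, df["_y"].to_numpy(), rcond=None)
    resid = df["_y"].to_numpy() - X @ beta
    scale = max(float(np.std(df["_y"])), 1.0)
    if float(np.max(np.abs(resid))) < 1e-10 * scale:
        return LmmResult(
            outcome=outcome, slope_session=float(beta[1]), se_session=0.0,
            slope_speed=float(beta[2]), se_speed=0.0,
            intercept=float(beta[0]), re_var_intercept=0.0,
            re_var_session=0.0, resid_var=0.0,
            chi2=math.inf if abs(beta[1]) > 0 else 0.0,
            p=0.0 if abs(beta[1]) > 0 else 1.0,
            converged=True, degenerate=True,
            n_obs=len(df), n_subjects=n_subj,
        )

    full, sing_f = _fit_ml("_y ~ session + speed", df, "_subject")
    reduced, sing_r = _fit_ml("_y ~ speed", df, "_subject")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(spstats.chi2.sf(chi2, df=1))
    cov_re = np.asarray(full.cov_re)
    return LmmResult(
        outcome=outcome,
        slope_session=float(full.params["session"]),
        se_session=float(full.bse["session"]),
        slope_speed=float(full.params["speed"]),
        se_speed=float(full.bse["speed"]),
        intercept=float(full.params["Intercept"]),
        re_var_intercept=float(cov_re[0, 0]),
        re_var_session=float(cov_re[1, 1]),
        resid_var=float(full.scale),
        chi2=float(chi2),
        p=p,
        converged=bool(full.converged and reduced.converged),
        singular=bool(sing_f or sing_r),
        n_obs=len(df),
        n_subjects=n_subj,
    )


# ---------------------------------------------------------------------------
# one-sample comparison with the expert reference


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    n: int
    mean: float
    sd: float
    ref: float
    sided: str = "one"


def athlete_comparison(values=None, *, mean: float | None = None,
                       sd: float | None = None, n: int | None = None,
                       ref: float, sided: str = "one") -> TTestResult:
    """One-sample t-test of final-session values against an expert reference.

    Accepts either raw ``values`` or summary statistics ``(mean, sd, n)``;
    the two paths agree exactly. ``sided='one'`` reports the one-sided
    p-value in the direction of the observed difference (so ``t = 0`` gives
    ``p = 0.5``); ``sided='two'`` doubles it. A zero SD with a nonzero
    difference yields an infinite t (p = 0), reported as such.
    """
    if sided not in ("one", "two"):
        raise DataError("sided must be 'one' or 'two'")
    if values is not None:
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        n = arr.size
        if n < 2:
            raise DataError(f"need >= 2 observations, got {n}")
        mean = float(np.mean(arr))
        sd = float(np.std(arr, ddof=1))
    else:
        if mean is None or sd is None or n is None:
            raise DataError("provide values or all of mean, sd, n")
        if n < 2:
            raise DataError(f"need n >= 2, got {n}")
        if sd < 0:
            raise DataError("sd must be non-negative")
    dof = n - 1
    if sd == 0.0:
        t = 0.0 if mean == ref else math.copysign(math.inf, mean - ref)
    else:
        t = (mean - ref) / (sd / math.sqrt(n))
    p_one = float(spstats.t.sf(abs(t), dof)) if math.isfinite(t) else 0.0
    p = p_one if sided == "one" else min(1.0, 2.0 * p_one)
    return TTestResult(t=float(t), df=dof, p=p, n=int(n), mean=float(mean),
                       sd=float(sd), ref=float(ref), sided=sided)
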