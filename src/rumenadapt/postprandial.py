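"""Step 1 — summarise post-prandial acid-status kinetics.

Each animal-day curve of hydrogen-ion concentration versus time after
feed delivery, sampled at 0, 1, 2, 4 and 6 h, is described by a
quadratic

    [H+](t) = a t^2 + b t + c,

fitted by ordinary least squares (the quadratic is linear in its
coefficients, so the OLS optimum coincides with any nonlinear
re-parametrised fit).  The coefficients are then re-expressed as
biologically meaningful synthetic variables:

* ``v0``     — fitted [H+] at t = 0, the pre-feeding baseline;
* ``A``      — amplitude: maximum fitted [H+] over the sampling window
               minus ``v0`` (the post-prandial deviation);
* ``R``      — recovery descriptor at the end of the window,
               (max - v0) / (max - v_last) x 100;
* ``v_last`` — fitted [H+] at t = 6 h;

plus two threshold-dependent descriptors for an acidosis threshold
theta given in pH units (default 5.5):

* ``dur``    — time within the window during which the fitted curve
               exceeds 10**(-theta);
* ``amp_ac`` — peak exceedance of the fitted curve above 10**(-theta)
               (negative when the curve never reaches the threshold).

On the pH scale the post-prandial deviation points downwards, so in
``scale="ph"`` mode the amplitude is ``v0 - min(curve)``, ``dur`` is
the time the fitted pH sits below theta, and ``amp_ac`` is
``theta - min(curve)``; the recovery descriptor mirrors accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InfeasibleParametersError,
    InsufficientDataError,
    SingularFitError,
)
from .measurements import ph_to_h

__all__ = [
    "QuadraticFit",
    "SyntheticVariables",
    "ThresholdVariables",
    "fit_quadratic",
    "evaluate_quadratic",
    "reparametrise",
    "inverse_reparametrise",
    "derive_threshold_vars",
    "fit_all",
    "spearman_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW: tuple[float, float] = (0.0, 6.0)

Direction = Literal["up", "down"]
RecoveryDefinition = Literal["standard", "complement"]


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic fit of one post-prandial curve."""

    a: float
    b: float
    c: float
    rss: float
    n_points: int
    converged: bool = True

    def __call__(self, t):
        return evaluate_quadratic(self.a, self.b, self.c, t)


@dataclass(frozen=True)
class SyntheticVariables:
    """Re-parametrised descriptors of one post-prandial curve.

    ``direction`` records whether the deviation is upward (``"up"``,
    the [H+] scale) or downward (``"down"``, the pH scale); ``t_peak``
    is the within-window location of the extremum in either case.
    ``R`` is NaN when undefined (no deviation, or extremum at the end
    of the window).
    """

    v0: float
    A: float
    R: float
    v_last: float
    t_peak: float
    window: tuple[float, float] = DEFAULT_WINDOW
    direction: Direction = "up"
    recovery_definition: RecoveryDefinition = "standard"


@dataclass(frozen=True)
class ThresholdVariables:
    """Threshold-dependent descriptors for an acidosis threshold theta."""

    theta_ph: float
    theta_h: float
    dur: float
    amp_ac: float
    window: tuple[float, float] = DEFAULT_WINDOW
    direction: Direction = "up"


def evaluate_quadratic(a: float, b: float, c: float, t):
    """Evaluate a t^2 + b t + c (vectorised)."""
    t = np.asarray(t, dtype=float)
    out = (a * t + b) * t + c
    return float(out) if out.ndim == 0 else out


def fit_quadratic(times: Sequence[float], conc: Sequence[float]) -> QuadraticFit:
    """Ordinary least-squares quadratic fit to one curve.

    Requires at least three distinct time points; with exactly three,
    the fit interpolates (rss = 0 to rounding).

    Raises
    ------
    InsufficientDataError
        Fewer than three distinct time points.
    SingularFitError
        Rank-deficient design (cannot happen with >=3 distinct times
        for a quadratic, but guarded for safety).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(conc, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InsufficientDataError("times and conc must be 1-D of equal length")
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            f"need >=3 distinct time points, got {np.unique(t).size}"
        )
    X = np.column_stack([t**2, t, np.ones_like(t)])
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return QuadraticFit(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        rss=float(resid @ resid), n_points=int(t.size),
    )


def _extremum(a: float, b: float, c: float,
              window: tuple[float, float], direction: Direction) -> tuple[float, float]:
    """Location and value of the window max (direction 'up') or min ('down')."""
    t0, t1 = float(window[0]), float(window[1])
    cand = [t0, t1]
    if a != 0.0:
        vtx = -b / (2.0 * a)
        # the vertex is a max if a < 0, a min if a > 0
        vertex_is_wanted = (a < 0) if direction == "up" else (a > 0)
        if vertex_is_wanted and t0 < vtx < t1:
            cand.append(vtx)
    vals = [evaluate_quadratic(a, b, c, t) for t in cand]
    if direction == "up":
        i = int(np.argmax(vals))
    else:
        i = int(np.argmin(vals))
    return cand[i], vals[i]


def reparametrise(
    fit: QuadraticFit,
    window: tuple[float, float] = DEFAULT_WINDOW,
    direction: Direction = "up",
    recovery_definition: RecoveryDefinition = "standard",
) -> SyntheticVariables:
    """Convert quadratic coefficients into the synthetic variables.

    The amplitude is measured against the extremum of the fitted curve
    over the *closed* sampling window (the vertex when it lies inside
    the window and has the right curvature, otherwise the more extreme
    endpoint), which keeps ``A >= 0`` for any fit.

    Two recovery conventions are exposed:

    * ``"standard"`` (default): R = (ext - v0) / (ext - v_last) x 100 —
      100 when the curve returns exactly to baseline, above 100 when it
      overshoots, divergent as v_last approaches the extremum;
    * ``"complement"``: R = (ext - v_last) / (ext - v0) x 100 — the
      fraction of the excursion recovered by the end of the window.

    (Differences written for the upward direction; on the pH scale all
    differences flip sign so both conventions stay positive.)
    ``R`` is NaN, with a warning, when its denominator vanishes or when
    ``A == 0``.
    """
    a, b, c = fit.a, fit.b, fit.c
    t0, t1 = float(window[0]), float(window[1])
    v0 = evaluate_quadratic(a, b, c, t0)
    v_last = evaluate_quadratic(a, b, c, t1)
    t_peak, v_peak = _extremum(a, b, c, window, direction)

    sign = 1.0 if direction == "up" else -1.0
    A = sign * (v_peak - v0)
    excursion = sign * (v_peak - v0)      # == A
    unrecovered = sign * (v_peak - v_last)

    if A == 0.0:
        warnings.warn("flat or monotone-adverse curve: A == 0, R undefined")
        R = float("nan")
    elif recovery_definition == "standard":
        if unrecovered == 0.0:
            warnings.warn("extremum equals end value: R (standard) undefined")
            R = float("nan")
        else:
            R = 100.0 * excursion / unrecovered
    elif recovery_definition == "complement":
        R = 100.0 * unrecovered / excursion
    else:
        raise ValueError(f"unknown recovery_definition {recovery_definition!r}")

    return SyntheticVariables(
        v0=float(v0), A=float(A), R=float(R), v_last=float(v_last),
        t_peak=float(t_peak), window=(t0, t1), direction=direction,
        recovery_definition=recovery_definition,
    )


def inverse_reparametrise(
    v0: float, A: float, R: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[float, float, float]:
    """Recover quadratic coefficients from (v0, A, R) — upward direction.

    For a concave quadratic with its peak strictly inside the window
    ``[t0, t1]`` of width ``W``, writing u = t - t0:

        c = v0,   A = -b^2 / (4a),   v_last - v0 = a W^2 + b W,

    and the table-1 recovery definition R = 100 A / (A - (v_last - v0))
    gives the quadratic  b^2 W^2 - 4 A b W + 4 A^2 (1 - 100/R) = 0 in b,
    whose positive root with an interior vertex is

        b = 2 A (1 + 10 / sqrt(R)) / W,   a = -b^2 / (4 A).

    Any v0 > 0, A > 0, R > 0 is feasible; the round trip through
    :func:`reparametrise` is the validation of this algebra.

    Raises
    ------
    InfeasibleParametersError
        For non-positive v0, A or R (no concave interior-peak quadratic
        exists).
    """
    if not (np.isfinite(v0) and np.isfinite(A) and np.isfinite(R)):
        raise InfeasibleParametersError("v0, A, R must be finite")
    if v0 <= 0 or A <= 0 or R <= 0:
        raise InfeasibleParametersError(
            f"need v0 > 0, A > 0, R > 0, got v0={v0}, A={A}, R={R}"
        )
    t0, t1 = float(window[0]), float(window[1])
    W = t1 - t0
    if W <= 0:
        raise InfeasibleParametersError("window must have positive width")
    b_u = 2.0 * A * (1.0 + 10.0 / np.sqrt(R)) / W
    a = -b_u * b_u / (4.0 * A)
    # expand q(t) = a (t - t0)^2 + b_u (t - t0) + v0 into a t^2 + b t + c
    b = b_u - 2.0 * a * t0
    c = v0 + a * t0 * t0 - b_u * t0
    return float(a), float(b), float(c)


def derive_threshold_vars(
    fit: QuadraticFit,
    theta_ph: float = 5.5,
    window: tuple[float, float] = DEFAULT_WINDOW,
    direction: Direction = "up",
) -> ThresholdVariables:
    """Duration and amplitude of acidosis relative to a pH threshold.

    ``dur`` is the Lebesgue measure of the within-window set where the
    fitted curve is on the acidotic side of the threshold ([H+] above
    10**(-theta), equivalently pH below theta), computed analytically
    from the quadratic's roots.  ``amp_ac`` is the peak exceedance
    (negative when the curve never crosses the threshold).
    """
    if not np.isfinite(theta_ph):
        raise ValueError("theta_ph must be finite")
    theta_h = ph_to_h(theta_ph)
    thr = theta_h if direction == "up" else theta_ph
    t0, t1 = float(window[0]), float(window[1])

    # g(t) = +-(q(t) - thr): positive exactly where the curve is acidotic
    sign = 1.0 if direction == "up" else -1.0
    ga, gb, gc = sign * fit.a, sign * fit.b, sign * (fit.c - thr)
    dur = _measure_positive(ga, gb, gc, t0, t1)

    _, v_ext = _extremum(fit.a, fit.b, fit.c, window, direction)
    amp_ac = sign * (v_ext - thr)
    return ThresholdVariables(
        theta_ph=float(theta_ph), theta_h=float(theta_h),
        dur=float(dur), amp_ac=float(amp_ac), window=(t0, t1),
        direction=direction,
    )


def _measure_positive(a: float, b: float, c: float, t0: float, t1: float) -> float:
    """Measure of {t in [t0, t1] : a t^2 + b t + c > 0}."""
    if a == 0.0:
        if b == 0.0:
            return (t1 - t0) if c > 0 else 0.0
        r = -c / b
        if b > 0:      # positive for t > r
            return max(0.0, t1 - max(t0, r))
        return max(0.0, min(t1, r) - t0)
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        # no sign change: sign everywhere that of a (disc<0) or touching zero
        return (t1 - t0) if a > 0 else 0.0
    sq = np.sqrt(disc)
    r1 = (-b - sq) / (2.0 * a)
    r2 = (-b + sq) / (2.0 * a)
    lo, hi = min(r1, r2), max(r1, r2)
    inside = max(0.0, min(t1, hi) - max(t0, lo))
    if a < 0:          # positive between the roots
        return inside
    return (t1 - t0) - inside  # positive outside the roots


def fit_all(
    records: pd.DataFrame,
    scale: Literal["h_conc", "ph"] = "h_conc",
    theta_ph: float = 5.5,
    window: tuple[float, float] = DEFAULT_WINDOW,
    recovery_definition: RecoveryDefinition = "standard",
    min_points: int = 4,
) -> pd.DataFrame:
    """Fit every animal-day curve and tabulate the synthetic variables.

    Parameters
    ----------
    records
        Annotated measurement table (see
        :func:`rumenadapt.schedule.annotate_schedule`).
    scale
        ``"h_conc"`` fits hydrogen-ion concentration (deviation
        upward); ``"ph"`` fits pH directly (deviation downward).
    theta_ph
        Acidosis threshold in pH units for the threshold-dependent
        descriptors.
    min_points
        Animal-days with fewer sampled time points are excluded with a
        logged warning (never below the 3 needed by the quadratic).

    Returns
    -------
    pandas.DataFrame
        One row per animal-day: coefficients (a, b, c), rss, v0, A, R,
        v_last, t_peak, dur, amp_ac plus the schedule metadata and the
        configuration columns (scale, theta_ph, recovery_definition).
    """
    if scale not in ("h_conc", "ph"):
        raise ValueError(f"scale must be 'h_conc' or 'ph', got {scale!r}")
    direction: Direction = "up" if scale == "h_conc" else "down"
    min_points = max(int(min_points), 3)

    rows = []
    for (animal, day), grp in records.groupby(["animal_id", "day_label"], sort=True):
        grp = grp.sort_values("time_h")
        if grp["time_h"].nunique() < min_points:
            logger.warning(
                "excluding animal %s day %s: %d points < minimum %d",
                animal, day, grp["time_h"].nunique(), min_points,
            )
            continue
        fit = fit_quadratic(grp["time_h"].to_numpy(), grp[scale].to_numpy())
        sv = reparametrise(fit, window, direction, recovery_definition)
        tv = derive_threshold_vars(fit, theta_ph, window, direction)
        row = {
            "animal_id": animal, "day_label": int(day),
            "a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss,
            "n_points": fit.n_points,
            "v0": sv.v0, "A": sv.A, "R": sv.R, "v_last": sv.v_last,
            "t_peak": sv.t_peak, "dur": tv.dur, "amp_ac": tv.amp_ac,
        }
        for meta in ("week", "days_since_change", "day_offset"):
            if meta in grp.columns:
                row[meta] = grp[meta].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    out["scale"] = scale
    out["theta_ph"] = theta_ph
    out["recovery_definition"] = recovery_definition
    return out


def spearman_matrix(
    var_table: pd.DataFrame,
    variables: Sequence[str] = ("a", "b", "c", "v0", "A", "R", "dur", "amp_ac"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation screen among candidate descriptors.

    Pairwise-complete observations; constant columns yield NaN for
    their pairs.  Returns the (rho, p-value) matrices as symmetric
    DataFrames with unit diagonal.
    """
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], pval[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = var_table[[variables[i], variables[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # constant column: undefined
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = list(variables)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
    )
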