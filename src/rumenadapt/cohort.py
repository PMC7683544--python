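"""Synthetic measurement cohorts with known ground truth.

The generator inverts the whole analysis chain so that every pipeline
stage can be tested against known generating values without any
external data.  For each animal and sampling day it:

1. draws the power-transformed baseline v0**lambda1 and amplitude
   A**lambda2 from the random-intercept longitudinal model (week means,
   per-animal intercept, optional short-term day slope, residual
   noise);
2. back-transforms to the molar [H+] scale and draws the recovery
   descriptor R from a truncated normal on (5, 100];
3. builds the unique concave quadratic with these (v0, A, R) via the
   inverse re-parametrisation and evaluates it at the post-prandial
   sampling hours 0, 1, 2, 4, 6;
4. applies multiplicative lognormal measurement noise to the
   concentrations (equivalently, additive noise on pH — pH electrodes
   err on the log scale) and emits measurement records on both scales.

Default parameters emulate the reference study conditions: 8 animals,
the 9-day irregular schedule, transformed-scale week means that dip
after the diet change and rise in the final week, and variance
components that put ~56% of the baseline's variance and ~17% of the
amplitude's variance between animals.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InfeasibleParametersError, ParameterError
from .measurements import POSTPRANDIAL_HOURS, validate_measurements
from .postprandial import evaluate_quadratic, inverse_reparametrise
from .schedule import SamplingSchedule, default_schedule

__all__ = ["GeneratorParams", "default_params", "generate_cohort"]

_R_RETRY_CAP = 100


@dataclass(frozen=True)
class GeneratorParams:
    """Generating parameters for a synthetic diet-challenge cohort.

    Week means and variance components are on the power-transformed
    scales (v0**lambda_v0, A**lambda_A); R is drawn per animal-day from
    a normal truncated to (r_lo, 100].
    """

    n_animals: int = 8
    schedule: SamplingSchedule = field(default_factory=default_schedule)
    alpha_v0: tuple[float, ...] = (0.052, 0.046, 0.049, 0.047, 0.054)
    alpha_A: tuple[float, ...] = (0.016, 0.017, 0.018, 0.020, 0.023)
    lambda_v0: float = 0.20
    lambda_A: float = 0.28
    beta_v0: float = 0.0
    beta_A: float = 0.0
    sigma_A2_v0: float = 2.46e-6     # between-animal variance, transformed v0
    sigma2_v0: float = 1.51e-6       # residual variance, transformed v0
    sigma_A2_A: float = 0.68e-6      # between-animal variance, transformed A
    sigma2_A: float = 3.32e-6        # residual variance, transformed A
    R_mean: float = 85.0
    R_sd: float = 15.0
    R_lo: float = 5.0
    meas_noise_cv: float = 0.03      # CV of lognormal noise on [H+]
    min_conc_frac: float = 0.25      # curve must stay above this fraction of v0
    dropout_fraction: float = 0.0    # fraction of records dropped at random
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 2:
            raise ParameterError("n_animals must be >= 2")
        for name in ("sigma_A2_v0", "sigma2_v0", "sigma_A2_A", "sigma2_A"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.meas_noise_cv < 0:
            raise ParameterError("meas_noise_cv must be >= 0")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ParameterError("dropout_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "schedule"
        }
        d["schedule"] = self.schedule.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        sched = d.pop("schedule", None)
        kwargs = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()
        }
        if sched is not None:
            kwargs["schedule"] = SamplingSchedule.from_dict(sched)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_params(**overrides) -> GeneratorParams:
    """Reference-condition generator parameters, optionally overridden."""
    return replace(GeneratorParams(), **overrides) if overrides else GeneratorParams()


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        if not lo < mean <= hi:
            raise ParameterError("degenerate R distribution outside bounds")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return x
    raise ParameterError("truncated-normal rejection sampling failed")


def generate_cohort(
    params: GeneratorParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (measurements, ground_truth).

    The measurement table is in the canonical long format (one row per
    animal, day and post-prandial hour, both pH and [H+] populated);
    the ground-truth table has one row per animal-day with the
    generating quadratic coefficients, the true (v0, A, R) and the
    transformed-scale values and random intercepts.

    (v0, A, R) triples whose quadratic would cross zero inside the
    sampling window are infeasible as concentrations; R is re-drawn up
    to a retry cap for such animal-days, and an
    :class:`InfeasibleParametersError` is raised if the cap is hit.
    """
    p = params or default_params()
    rng = np.random.default_rng(p.seed)
    sched = p.schedule
    weeks = sorted({sched.week_of(d) for d in sched.day_labels})
    if len(p.alpha_v0) < len(weeks) or len(p.alpha_A) < len(weeks):
        raise ParameterError("alpha_v0 / alpha_A must cover every week")
    a_v0 = {wk: p.alpha_v0[k] for k, wk in enumerate(weeks)}
    a_A = {wk: p.alpha_A[k] for k, wk in enumerate(weeks)}

    hours = np.asarray(POSTPRANDIAL_HOURS)
    sd_ln = np.sqrt(np.log1p(p.meas_noise_cv**2))  # lognormal sigma for given CV

    meas_rows, truth_rows = [], []
    for i in range(p.n_animals):
        animal = f"goat{i + 1}"
        g_v0 = rng.normal(0.0, np.sqrt(p.sigma_A2_v0))
        g_A = rng.normal(0.0, np.sqrt(p.sigma_A2_A))
        for day in sched.day_labels:
            wk = sched.week_of(day)
            days_k = sched.days_since_change(day)
            t_v0 = (
                a_v0[wk] + g_v0 + p.beta_v0 * days_k
                + rng.normal(0.0, np.sqrt(p.sigma2_v0))
            )
            t_A = (
                a_A[wk] + g_A + p.beta_A * days_k
                + rng.normal(0.0, np.sqrt(p.sigma2_A))
            )
            if t_v0 <= 0 or t_A <= 0:
                raise ParameterError(
                    "transformed value went non-positive; variance too large "
                    "relative to the week means"
                )
            v0 = t_v0 ** (1.0 / p.lambda_v0)
            A = t_A ** (1.0 / p.lambda_A)

            # draw R until the quadratic stays well above zero over the
            # window (a curve plunging toward zero concentration would be
            # an implausibly alkaline end-of-window pH)
            floor = p.min_conc_frac * v0
            for attempt in range(_R_RETRY_CAP):
                R = _truncnorm(rng, p.R_mean, p.R_sd, p.R_lo, 100.0)
                a, b, c = inverse_reparametrise(v0, A, R)
                conc = evaluate_quadratic(a, b, c, hours)
                if np.all(conc > floor) and np.all(conc > 0):
                    break
            else:
                raise InfeasibleParametersError(
                    f"no feasible R for {animal} day {day} "
                    f"(v0={v0:.3g}, A={A:.3g}) after {_R_RETRY_CAP} draws"
                )

            noise = (
                np.exp(rng.normal(0.0, sd_ln, hours.size))
                if p.meas_noise_cv > 0 else np.ones(hours.size)
            )
            obs = conc * noise
            for t, h in zip(hours, obs):
                meas_rows.append(
                    {
                        "animal_id": animal, "day_label": day,
                        "day_offset": sched.offset_of(day),
                        "time_h": float(t),
                        "ph": float(-np.log10(h)), "h_conc": float(h),
                    }
                )
            truth_rows.append(
                {
                    "animal_id": animal, "day_label": day,
                    "day_offset": sched.offset_of(day),
                    "week": wk, "days_since_change": days_k,
                    "v0": v0, "A": A, "R": R,
                    "a": a, "b": b, "c": c,
                    "t_v0": t_v0, "t_A": t_A,
                    "G_v0": g_v0, "G_A": g_A,
                }
            )

    meas = pd.DataFrame(meas_rows)
    if p.dropout_fraction > 0:
        keep = rng.random(len(meas)) >= p.dropout_fraction
        meas = meas.loc[keep].reset_index(drop=True)
    meas = validate_measurements(meas)
    return meas, pd.DataFrame(truth_rows)
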