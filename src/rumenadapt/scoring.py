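"""Step 3 — phase-plane trajectory scoring and the global adaptive index.

Each animal traces a trajectory through the (v0, A) phase plane across
the nine sampling days.  Every step between consecutive sampling days
receives a quadrant score s in {-2, -1, 1, 2} from the signs of the
changes: a decrease in both coordinates (acid baseline and
post-prandial amplitude both improving) scores +2, an increase in both
scores -2, and mixed steps score +1 when the amplitude improves despite
a rising baseline (the animal's effort to adapt) or -1 when the
amplitude worsens despite a falling baseline.

Each score is weighted by the relative Euclidean distance

    omega = ||p_(i+1) - p_i|| / (calendar days between the samplings),

so that larger excursions per day weigh more, and irregular sampling
gaps do not bias the index.  The daily index is d = s * omega, and the
global index

    GI = sum of d over the steps d2->d3 .. d8->d9

(the baseline-to-baseline step d1->d2, entirely on the standard diet,
is excluded by default).  Higher (less negative) GI means better
adaptive capacity.  Because [H+] values are tiny, scores are also
reported rescaled by 1e7 for display; the rescaling is a joint positive
scaling of both coordinates and therefore never changes ranks.

The quadrant rule generalises to n coordinates (one baseline-like, the
rest amplitude-like): +2 when all decrease, -2 when all increase,
otherwise +-1 by majority; a tied majority is decided by the
amplitude-like coordinates alone, which reproduces the 2-D quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ScheduleError, ValidationError

__all__ = [
    "PhaseTrajectory",
    "StepScore",
    "GlobalIndex",
    "score_step",
    "score_step_nd",
    "step_weight",
    "daily_scores",
    "global_index",
    "unweighted_global_index",
    "rank_animals",
    "trajectories_from_table",
    "DISPLAY_RESCALE",
]

#: Display rescaling applied to scores built from molar [H+] values.
DISPLAY_RESCALE = 1e7

ZeroRule = Literal["decrease", "increase"]


@dataclass(frozen=True)
class PhaseTrajectory:
    """One animal's ordered path through the phase plane.

    ``points`` holds one (day_label, day_offset, coordinates...) tuple
    per sampling day, sorted by day_offset with unique day labels.
    """

    animal_id: str
    points: tuple[tuple, ...]  # (day_label, day_offset, v0, A, ...)

    def __post_init__(self):
        offs = [p[1] for p in self.points]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValidationError(
                f"trajectory for {self.animal_id}: points must be sorted by "
                "day_offset with no duplicates"
            )
        labels = [p[0] for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"trajectory for {self.animal_id}: duplicate day labels"
            )


@dataclass(frozen=True)
class StepScore:
    """Score of one step between consecutive sampling days."""

    from_day: int
    to_day: int
    s: int                      # quadrant score in {-2, -1, 1, 2}
    omega: float                # relative Euclidean distance per day
    d: float                    # daily index s * omega

    def __post_init__(self):
        if self.omega < 0:
            raise ValidationError("omega must be >= 0")


@dataclass(frozen=True)
class GlobalIndex:
    """Per-animal global adaptive-capacity index."""

    animal_id: str
    gi: float                   # raw scale (same units as the coordinates)
    steps: tuple[StepScore, ...]
    include_first_step: bool = False

    @property
    def gi_display(self) -> float:
        """Global index rescaled by 1e7 for readability."""
        return self.gi * DISPLAY_RESCALE


def _sign_class(delta: float, zero_rule: ZeroRule) -> int:
    """-1 for a decrease, +1 for an increase, with the zero convention."""
    if delta < 0:
        return -1
    if delta > 0:
        return 1
    return -1 if zero_rule == "decrease" else 1


def score_step(
    delta_v0: float, delta_A: float, zero_rule: ZeroRule = "decrease"
) -> int:
    """Quadrant score of one phase-plane step.

    Both down -> +2; both up -> -2; baseline up but amplitude down ->
    +1; baseline down but amplitude up -> -1.  A zero change counts as
    a decrease by default (non-deterioration is credited); when both
    changes are zero the weight is zero anyway, so the convention never
    affects the index there.
    """
    return score_step_nd((delta_v0, delta_A), zero_rule=zero_rule)


def score_step_nd(
    deltas: Sequence[float], zero_rule: ZeroRule = "decrease"
) -> int:
    """Generalised quadrant score for an n-coordinate phase space.

    The first coordinate is baseline-like (v0), the rest
    amplitude-like.  All decreasing -> +2, all increasing -> -2,
    otherwise +-1 by the majority of signs; a tied majority is decided
    by the amplitude-like coordinates alone (in two dimensions this is
    exactly the published quadrant assignment), and if those are also
    tied, by the baseline coordinate.
    """
    deltas = list(deltas)
    if len(deltas) < 2:
        raise ValidationError("need at least 2 phase-space coordinates")
    signs = [_sign_class(d, zero_rule) for d in deltas]
    if all(s < 0 for s in signs):
        return 2
    if all(s > 0 for s in signs):
        return -2
    total = sum(signs)
    if total < 0:
        return 1
    if total > 0:
        return -1
    amp = sum(signs[1:])
    if amp < 0:
        return 1
    if amp > 0:
        return -1
    return 1 if signs[0] < 0 else -1


def step_weight(
    p_i: Sequence[float], p_j: Sequence[float], gap_days: float
) -> float:
    """Relative Euclidean distance between two phase-space points.

    Euclidean distance divided by the number of calendar days between
    the two samplings.
    """
    if gap_days <= 0:
        raise ScheduleError(f"gap_days must be positive, got {gap_days}")
    a = np.asarray(p_i, dtype=float)
    b = np.asarray(p_j, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("phase-space points must have equal dimension")
    return float(np.linalg.norm(b - a) / gap_days)


def daily_scores(
    traj: PhaseTrajectory, zero_rule: ZeroRule = "decrease"
) -> list[StepScore]:
    """Score every consecutive-day step of a trajectory.

    Calendar gaps come from the day_offset differences, so the
    irregular spacing of the sampling days is respected.
    """
    if len(traj.points) < 2:
        raise ValidationError("trajectory needs >= 2 points")
    out = []
    for p, q in zip(traj.points, traj.points[1:]):
        coords_p = np.asarray(p[2:], dtype=float)
        coords_q = np.asarray(q[2:], dtype=float)
        s = score_step_nd(coords_q - coords_p, zero_rule=zero_rule)
        omega = step_weight(coords_p, coords_q, q[1] - p[1])
        out.append(
            StepScore(from_day=int(p[0]), to_day=int(q[0]), s=s,
                      omega=omega, d=s * omega)
        )
    return out


def global_index(
    steps: Sequence[StepScore],
    animal_id: str = "",
    include_first_step: bool = False,
) -> GlobalIndex:
    """Sum the daily indices into the global adaptive-capacity index.

    By default the first step (between the two pre-change baseline
    days) is excluded; set ``include_first_step`` to sum every step.
    """
    steps = tuple(steps)
    included = steps if include_first_step else steps[1:]
    gi = float(sum(st.d for st in included))
    return GlobalIndex(
        animal_id=animal_id, gi=gi, steps=steps,
        include_first_step=include_first_step,
    )


def unweighted_global_index(
    traj: PhaseTrajectory,
    include_first_step: bool = False,
    zero_rule: ZeroRule = "decrease",
) -> GlobalIndex:
    """Global index with every step weight set to 1 (raw quadrant sum)."""
    steps = [
        StepScore(from_day=st.from_day, to_day=st.to_day, s=st.s,
                  omega=1.0, d=float(st.s))
        for st in daily_scores(traj, zero_rule=zero_rule)
    ]
    return global_index(steps, traj.animal_id, include_first_step)


def rank_animals(indices: Sequence[GlobalIndex]) -> pd.DataFrame:
    """Rank animals by global index, best (highest GI) first.

    Ties share the same rank value and are flagged; ordering within a
    tie falls back to animal_id.
    """
    if not indices:
        raise ValidationError("need at least one global index to rank")
    df = pd.DataFrame(
        {
            "animal_id": [g.animal_id for g in indices],
            "gi": [g.gi for g in indices],
            "gi_display": [g.gi_display for g in indices],
        }
    )
    df = df.sort_values(["gi", "animal_id"], ascending=[False, True])
    df["rank"] = df["gi"].rank(method="min", ascending=False).astype(int)
    df["tied"] = df.duplicated("gi", keep=False)
    return df.reset_index(drop=True)


def trajectories_from_table(
    var_table: pd.DataFrame, coords: Sequence[str] = ("v0", "A")
) -> list[PhaseTrajectory]:
    """Build per-animal phase trajectories from a synthetic-variable table."""
    need = {"animal_id", "day_label", "day_offset", *coords}
    missing = need - set(var_table.columns)
    if missing:
        raise ValidationError(f"variable table lacks columns {sorted(missing)}")
    out = []
    for animal, grp in var_table.groupby("animal_id", sort=True):
        grp = grp.sort_values("day_offset")
        pts = tuple(
            (int(r.day_label), float(r.day_offset),
             *(float(getattr(r, c)) for c in coords))
            for r in grp.itertuples()
        )
        out.append(PhaseTrajectory(animal_id=str(animal), points=pts))
    return out
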