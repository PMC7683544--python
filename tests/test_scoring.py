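import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rumenadapt as ra
from rumenadapt.datasets import STEP_COLUMNS, load_reference_daily_scores
from rumenadapt.errors import ScheduleError, ValidationError
from rumenadapt.scoring import score_step_nd

nonzero = st.floats(min_value=1e-9, max_value=1e-5)


class TestScoreStep:
    @pytest.mark.parametrize(
        "dv0, dA, expected",
        [
            (-1e-7, -1e-7, 2),   # both improve
            (+1e-7, +1e-7, -2),  # both worsen
            (+1e-7, -1e-7, 1),   # effort: amplitude improves despite baseline
            (-1e-7, +1e-7, -1),  # amplitude worsens despite baseline
        ],
    )
    def test_quadrants(self, dv0, dA, expected):
        assert ra.score_step(dv0, dA) == expected

    @settings(deadline=None, derandomize=True)
    @given(x=nonzero, y=nonzero, sx=st.sampled_from([-1, 1]),
           sy=st.sampled_from([-1, 1]))
    def test_antisymmetry(self, x, y, sx, sy):
        assert ra.score_step(-sx * x, -sy * y) == -ra.score_step(sx * x, sy * y)

    def test_zero_rule(self):
        assert ra.score_step(0.0, -1e-7) == 2           # zero counts as decrease
        assert ra.score_step(0.0, -1e-7, zero_rule="increase") == 1
        assert ra.score_step(0.0, 0.0) == 2

    def test_nd_generalisation(self):
        assert score_step_nd((-1, -1, -1)) == 2
        assert score_step_nd((1, 1, 1)) == -2
        assert score_step_nd((1, -1, -1)) == 1     # majority improves
        assert score_step_nd((-1, 1, 1)) == -1     # majority worsens
        # 2-D ties resolve by the amplitude-like coordinate
        assert score_step_nd((1, -1)) == 1
        assert score_step_nd((-1, 1)) == -1


class TestStepWeight:
    def test_pythagorean_triangle(self):
        assert ra.step_weight((0, 0), (3, 4), 1) == pytest.approx(5)
        assert ra.step_weight((0, 0), (3, 4), 5) == pytest.approx(1)
        assert ra.step_weight((2, 2), (2, 2), 3) == 0

    def test_invalid_gap(self):
        with pytest.raises(ScheduleError):
            ra.step_weight((0, 0), (1, 1), 0)


def random_trajectory(rng, animal="g"):
    sched = ra.default_schedule()
    pts = tuple(
        (d, sched.offset_of(d),
         float(rng.uniform(1e-7, 1e-6)), float(rng.uniform(1e-7, 1e-6)))
        for d in sched.day_labels
    )
    return ra.PhaseTrajectory(animal_id=animal, points=pts)


def brute_force_gi(points, include_first=False):
    """Direct recomputation of the index from its defining formulas."""
    total = 0.0
    steps = list(zip(points, points[1:]))
    if not include_first:
        steps = steps[1:]
    for (d1, o1, v1, a1), (d2, o2, v2, a2) in steps:
        dv, da = v2 - v1, a2 - a1
        if dv <= 0 and da <= 0:
            s = 2
        elif dv > 0 and da > 0:
            s = -2
        elif da <= 0:
            s = 1
        else:
            s = -1
        omega = np.hypot(dv, da) / (o2 - o1)
        total += s * omega
    return total


class TestDailyScores:
    def test_monotone_decrease_scores_plus_two(self):
        pts = tuple((d, d, 1e-6 - d * 1e-8, 5e-7 - d * 1e-8) for d in range(1, 10))
        steps = ra.daily_scores(ra.PhaseTrajectory("g", pts))
        assert all(st.s == 2 and st.d >= 0 for st in steps)

    def test_matches_hand_computation(self, rng):
        traj = random_trajectory(rng)
        steps = ra.daily_scores(traj)
        for (p, q), st_ in zip(zip(traj.points, traj.points[1:]), steps):
            omega = np.hypot(q[2] - p[2], q[3] - p[3]) / (q[1] - p[1])
            assert st_.omega == pytest.approx(omega, rel=1e-12)
            assert st_.d == pytest.approx(st_.s * omega, rel=1e-12)

    def test_reversal_flips_scores(self, rng):
        traj = random_trajectory(rng)
        rev_pts = tuple(
            (p[0], p[1], q[2], q[3])
            for p, q in zip(traj.points, reversed(traj.points))
        )
        fwd = ra.daily_scores(traj)
        rev = ra.daily_scores(ra.PhaseTrajectory("g", rev_pts))
        for f, r in zip(fwd, reversed(rev)):
            assert r.s == -f.s

    def test_brute_force_recomputation(self, rng):
        for _ in range(20):
            traj = random_trajectory(rng)
            gi = ra.global_index(ra.daily_scores(traj), traj.animal_id)
            assert gi.gi == pytest.approx(brute_force_gi(traj.points), rel=1e-12)

    def test_unsorted_trajectory_rejected(self):
        with pytest.raises(ValidationError):
            ra.PhaseTrajectory("g", ((1, 5, 1.0, 1.0), (2, 3, 1.0, 1.0)))


class TestGlobalIndex:
    def test_reference_goats_reproduced(self):
        ref = load_reference_daily_scores(consistent_only=True)
        for _, row in ref.iterrows():
            steps = [
                ra.StepScore(from_day=i + 1, to_day=i + 2,
                             s=int(np.sign(row[col])) or 1,
                             omega=abs(row[col]), d=row[col])
                for i, col in enumerate(STEP_COLUMNS)
            ]
            gi = ra.global_index(steps, str(int(row["goat"])))
            assert gi.gi == pytest.approx(row["reported_index"], abs=0.02)

    def test_first_step_flag(self):
        steps = [
            ra.StepScore(from_day=i, to_day=i + 1, s=1, omega=1.0, d=1.0)
            for i in range(1, 9)
        ]
        assert ra.global_index(steps).gi == 7
        assert ra.global_index(steps, include_first_step=True).gi == 8

    def test_all_zero_steps(self):
        steps = [
            ra.StepScore(from_day=i, to_day=i + 1, s=2, omega=0.0, d=0.0)
            for i in range(1, 9)
        ]
        assert ra.global_index(steps).gi == 0

    def test_joint_rescaling_equivariance(self, rng):
        traj = random_trajectory(rng)
        gi = ra.global_index(ra.daily_scores(traj), "g").gi
        k = 10.0
        scaled_pts = tuple((p[0], p[1], k * p[2], k * p[3]) for p in traj.points)
        gi_k = ra.global_index(
            ra.daily_scores(ra.PhaseTrajectory("g", scaled_pts)), "g"
        ).gi
        assert gi_k == pytest.approx(k * gi, rel=1e-9)

    def test_bounded_by_weights(self, rng):
        traj = random_trajectory(rng)
        steps = ra.daily_scores(traj)
        gi = ra.global_index(steps, "g")
        assert abs(gi.gi) <= 2 * sum(s.omega for s in steps[1:]) + 1e-18


class TestUnweighted:
    def test_all_improving_trajectory(self):
        pts = tuple((d, d, 1e-6 - d * 1e-8, 5e-7 - d * 1e-8) for d in range(1, 10))
        gi = ra.unweighted_global_index(ra.PhaseTrajectory("g", pts))
        assert gi.gi == 14  # 7 included steps x (+2)

    def test_dominant_loser_keeps_last_rank(self, rng):
        # one animal deteriorates monotonically; it must rank last under
        # both the weighted and unweighted metric
        trajs = [random_trajectory(rng, f"g{i}") for i in range(5)]
        bad_pts = tuple((d, d, 1e-6 + d * 2e-7, 5e-7 + d * 2e-7)
                        for d in range(1, 10))
        trajs.append(ra.PhaseTrajectory("loser", bad_pts))
        weighted = ra.rank_animals(
            [ra.global_index(ra.daily_scores(t), t.animal_id) for t in trajs]
        )
        unweighted = ra.rank_animals(
            [ra.unweighted_global_index(t) for t in trajs]
        )
        assert weighted.iloc[-1]["animal_id"] == "loser"
        assert unweighted.iloc[-1]["animal_id"] == "loser"


class TestRanking:
    def test_reference_order(self):
        ref = load_reference_daily_scores()
        gis = [
            ra.GlobalIndex(animal_id=str(int(r.goat)), gi=r.reported_index,
                           steps=())
            for r in ref.itertuples()
        ]
        ranked = ra.rank_animals(gis)
        assert ranked.iloc[0]["animal_id"] == "8"
        assert ranked.iloc[-1]["animal_id"] == "1"

    def test_single_animal(self):
        ranked = ra.rank_animals([ra.GlobalIndex("a", -1.0, ())])
        assert ranked["rank"].tolist() == [1]

    def test_shift_invariance(self, rng):
        gis = [ra.GlobalIndex(f"g{i}", float(rng.normal()), ()) for i in range(6)]
        shifted = [ra.GlobalIndex(g.animal_id, g.gi + 42.0, ()) for g in gis]
        r1 = ra.rank_animals(gis)
        r2 = ra.rank_animals(shifted)
        assert r1["animal_id"].tolist() == r2["animal_id"].tolist()

    def test_ties_flagged(self):
        gis = [ra.GlobalIndex("a", 1.0, ()), ra.GlobalIndex("b", 1.0, ())]
        ranked = ra.rank_animals(gis)
        assert ranked["tied"].all()
        assert ranked["rank"].tolist() == [1, 1]
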