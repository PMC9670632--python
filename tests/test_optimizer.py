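import numpy as np
import pytest

from rehabgym import (
    BruteForceSizeError,
    InfeasibleScheduleError,
    ObjectiveSpec,
    Schedule,
    TrainingBlock,
    best_robot_schedule,
    brute_force_optimal,
    check_disjunctive,
    check_time_indexed,
    decode_disjunctive,
    decode_time_indexed,
    disjunctive_objective,
    encode_disjunctive,
    encode_time_indexed,
    equal_curve_scenario,
    max_individual_gain,
    optimize,
    per_patient_gains,
    repair_schedule,
    switch_halfway_schedule,
    total_gain,
    trajectory,
    upper_bound,
    validate_schedule,
)
from rehabgym.evaluation import GroupSpec, random_group_scenario
from rehabgym.skill_model import EQUAL_CURVE, gain

from conftest import random_blocks, random_feasible_schedule


def switch_layout_12t_exit():
    blocks = []
    for i in range(5):
        blocks.append(TrainingBlock(i + 1, i + 1, 1, 6))
        blocks.append(TrainingBlock(i + 1, (i + 1) % 5 + 1, 8, 12))
    return Schedule(tuple(blocks))


class TestTimeIndexedEncoding:
    def test_single_block_transcription(self, gym_5p5r7t):
        sched = Schedule((TrainingBlock(1, 1, 1, 3),))
        tvars = encode_time_indexed(gym_5p5r7t, sched)
        assert tvars.x[0, 0, 0] == 1 and tvars.x.sum() == 1
        assert tvars.d[0, 0] == 3 and tvars.s[0, 0] == 1
        assert check_time_indexed(gym_5p5r7t, tvars)

    def test_empty_schedule_is_all_zero(self, gym_5p5r7t):
        tvars = encode_time_indexed(gym_5p5r7t, Schedule(()))
        assert tvars.x.sum() == 0 and tvars.d.sum() == 0

    def test_round_trip_on_switch_layout(self, gym_5p5r12t_exit):
        sched = switch_layout_12t_exit()
        assert decode_time_indexed(
            gym_5p5r12t_exit, encode_time_indexed(gym_5p5r12t_exit, sched)
        ) == sched

    def test_infeasible_schedule_rejected(self, gym_5p5r7t):
        bad = Schedule((TrainingBlock(1, 1, 1, 4), TrainingBlock(2, 1, 4, 6)))
        with pytest.raises(InfeasibleScheduleError):
            encode_time_indexed(gym_5p5r7t, bad)
        assert not check_time_indexed(
            gym_5p5r7t, encode_time_indexed(gym_5p5r7t, bad, validate=False)
        )


class TestDisjunctiveEncoding:
    def test_single_block_transcription(self):
        sc = equal_curve_scenario(1, 1, 7)
        sched = Schedule((TrainingBlock(1, 1, 2, 5),))
        dvars = encode_disjunctive(sc, sched)
        assert (dvars.x[0, 0], dvars.y[0, 0], dvars.z[0, 0]) == (2, 5, 1)
        assert dvars.V == sc.G + 1
        assert disjunctive_objective(sc, dvars) == pytest.approx(gain(EQUAL_CURVE, 4))
        assert check_disjunctive(sc, dvars)

    def test_exit_gap_semantics(self):
        sc = equal_curve_scenario(2, 1, 12, exit_time=1)
        ok = Schedule((TrainingBlock(1, 1, 1, 4), TrainingBlock(2, 1, 6, 9)))
        assert check_disjunctive(sc, encode_disjunctive(sc, ok))
        bad = Schedule((TrainingBlock(1, 1, 1, 4), TrainingBlock(2, 1, 5, 9)))
        assert not check_disjunctive(sc, encode_disjunctive(sc, bad, validate=False))

    def test_objective_agrees_with_time_indexed_total(self, gym_5p5r12t_exit):
        sched = switch_layout_12t_exit()
        dvars = encode_disjunctive(gym_5p5r12t_exit, sched)
        assert disjunctive_objective(gym_5p5r12t_exit, dvars) == pytest.approx(
            total_gain(gym_5p5r12t_exit, sched)
        )
        assert decode_disjunctive(gym_5p5r12t_exit, dvars) == sched

    def test_precedence_indicators_consistent(self, gym_5p5r12t_exit):
        dvars = encode_disjunctive(gym_5p5r12t_exit, switch_layout_12t_exit())
        a = dvars.a
        for r in range(5):
            active = [p for p in range(5) if dvars.z[r, p]]
            for i in active:
                for j in active:
                    if i != j:
                        assert a[r, i, j] + a[r, j, i] == 1


class TestFormulationEquivalence:
    @pytest.mark.parametrize("shape", [(2, 2, 5, 0), (3, 2, 4, 1), (2, 3, 6, 1)])
    def test_checkers_accept_exactly_the_feasible_schedules(self, shape, rng):
        m, n, g, e = shape
        sc = equal_curve_scenario(m, n, g, exit_time=e)
        seen_feasible = seen_infeasible = 0
        for _ in range(150):
            sched = random_blocks(sc, rng)
            feasible = validate_schedule(sc, sched).feasible
            ti = check_time_indexed(sc, encode_time_indexed(sc, sched, validate=False))
            dj = check_disjunctive(sc, encode_disjunctive(sc, sched, validate=False))
            assert ti == feasible
            assert dj == feasible
            seen_feasible += feasible
            seen_infeasible += not feasible
        assert seen_feasible > 5 and seen_infeasible > 5


class TestRepair:
    def test_pulls_forward_and_extends(self):
        sc = equal_curve_scenario(1, 1, 5)
        out = repair_schedule(sc, Schedule((TrainingBlock(1, 1, 2, 3),)))
        assert out.blocks == (TrainingBlock(1, 1, 1, 5),)
        assert total_gain(sc, out) == pytest.approx(24.509803921568626)

    def test_full_session_block_unchanged(self):
        sc = equal_curve_scenario(1, 1, 7)
        sched = Schedule((TrainingBlock(1, 1, 1, 7),))
        assert repair_schedule(sc, sched) == sched

    def test_respects_exit_windows(self):
        sc = equal_curve_scenario(2, 1, 12, exit_time=1)
        sched = Schedule((TrainingBlock(1, 1, 1, 4), TrainingBlock(2, 1, 8, 10)))
        out = repair_schedule(sc, sched)
        # second block pulled to step 6 (end 4 + exit 1 + 1) and extended
        assert out.for_patient(2) == (TrainingBlock(2, 1, 6, 12),)
        assert validate_schedule(sc, out).feasible

    def test_infeasible_input_rejected(self, gym_5p5r7t):
        bad = Schedule((TrainingBlock(1, 1, 1, 4), TrainingBlock(2, 1, 4, 6)))
        with pytest.raises(InfeasibleScheduleError):
            repair_schedule(gym_5p5r7t, bad)

    def test_monotone_feasible_and_idempotent_on_random_schedules(self, rng):
        for m, n, g, e in ((3, 3, 6, 0), (3, 2, 5, 1), (2, 3, 7, 2)):
            sc = equal_curve_scenario(m, n, g, exit_time=e)
            for _ in range(25):
                sched = random_feasible_schedule(sc, rng)
                out = repair_schedule(sc, sched)
                assert validate_schedule(sc, out).feasible
                assert total_gain(sc, out) >= total_gain(sc, sched) - 1e-12
                assert repair_schedule(sc, out) == out


class TestSoloOptimumAndBounds:
    def test_solo_values(self):
        assert max_individual_gain(equal_curve_scenario(5, 5, 7), 1) == pytest.approx(
            43.04029304029304
        )
        assert max_individual_gain(
            equal_curve_scenario(5, 5, 12, exit_time=1), 1
        ) == pytest.approx(54.16666666666666)
        assert max_individual_gain(equal_curve_scenario(1, 1, 7), 1) == pytest.approx(
            gain(EQUAL_CURVE, 7)
        )

    def test_solo_agrees_with_brute_force_on_single_patient(self):
        # dual route: subset-enumeration allocator vs exhaustive search
        for n, g, e in ((2, 5, 0), (3, 6, 1), (2, 6, 2)):
            sc = equal_curve_scenario(1, n, g, exit_time=e)
            assert max_individual_gain(sc, 1) == pytest.approx(
                brute_force_optimal(sc).value
            )

    def test_unknown_patient_rejected(self, gym_5p5r7t):
        with pytest.raises(ValueError):
            max_individual_gain(gym_5p5r7t, 6)

    def test_upper_bound_is_tight_for_the_rotation_scenario(self, gym_5p5r7t):
        assert upper_bound(gym_5p5r7t) == pytest.approx(215.2014652014652, abs=1e-4)

    def test_single_patient_bound_equals_solo_optimum(self):
        sc = equal_curve_scenario(1, 5, 12, exit_time=1)
        assert upper_bound(sc) == pytest.approx(max_individual_gain(sc, 1), abs=1e-4)

    def test_bound_dominates_random_feasible_schedules(self, rng):
        for m, n, g, e in ((3, 3, 6, 0), (2, 3, 6, 1)):
            sc = equal_curve_scenario(m, n, g, exit_time=e)
            bound = upper_bound(sc)
            for _ in range(20):
                sched = random_feasible_schedule(sc, rng)
                assert total_gain(sc, sched) <= bound + 1e-9


class TestBruteForce:
    def test_known_optima(self):
        assert brute_force_optimal(equal_curve_scenario(1, 1, 3)).value == pytest.approx(
            16.666666666666664
        )
        res = brute_force_optimal(equal_curve_scenario(2, 1, 3))
        assert res.value == pytest.approx(18.315018315018314)
        # the optimal split trains one patient 2 steps and the other 1
        assert sorted(b.duration for b in res.schedule.blocks) == [1, 2]

    def test_zero_patients(self):
        sc = equal_curve_scenario(0, 1, 3)
        res = brute_force_optimal(sc)
        assert res.value == 0.0 and len(res.schedule.blocks) == 0

    def test_value_equals_bound_field(self):
        res = brute_force_optimal(equal_curve_scenario(2, 2, 4))
        assert res.value == res.bound

    def test_oversized_instance_raises(self, gym_5p5r7t):
        with pytest.raises(BruteForceSizeError, match="optimize"):
            brute_force_optimal(gym_5p5r7t)


class TestOptimize:
    def test_zero_budget_returns_better_baseline(self, gym_5p5r7t):
        res = optimize(gym_5p5r7t, budget=0)
        expected = max(
            total_gain(gym_5p5r7t, best_robot_schedule(gym_5p5r7t)),
            total_gain(gym_5p5r7t, switch_halfway_schedule(gym_5p5r7t)),
        )
        assert res.value == pytest.approx(expected)
        assert res.iterations_used == 0

    @pytest.mark.parametrize("method", ["disjunctive", "time_indexed"])
    def test_matches_oracle_on_tiny_instances(self, method):
        for sc in (
            equal_curve_scenario(1, 1, 3),
            equal_curve_scenario(2, 1, 3),
            equal_curve_scenario(3, 2, 5),
        ):
            res = optimize(sc, method=method, budget=8000, seed=0)
            assert res.value == pytest.approx(brute_force_optimal(sc).value, abs=1e-9)

    def test_value_nondecreasing_in_budget(self, rng):
        sc = random_group_scenario(GroupSpec(seed=4), 4, 3, 8, exit_time=1)
        values = [optimize(sc, budget=b, seed=2).value for b in (0, 200, 1000, 3000)]
        assert values == sorted(values)

    @pytest.mark.parametrize("method", ["disjunctive", "time_indexed"])
    def test_never_worse_than_baselines(self, method):
        sc = random_group_scenario(GroupSpec(seed=9), 5, 5, 12, exit_time=1)
        base = max(
            total_gain(sc, best_robot_schedule(sc)),
            total_gain(sc, switch_halfway_schedule(sc)),
        )
        for budget in (0, 1, 500):
            res = optimize(sc, method=method, budget=budget, seed=0)
            assert res.value >= base - 1e-9

    def test_result_invariants(self):
        sc = random_group_scenario(GroupSpec(seed=6), 4, 4, 10)
        res = optimize(sc, budget=2000, seed=1)
        assert validate_schedule(sc, res.schedule).feasible
        assert res.value <= res.bound + 1e-9
        assert res.value == pytest.approx(total_gain(sc, res.schedule))
        logged = [v for _, v in res.improvement_log]
        assert logged == sorted(logged)
        traj = trajectory(sc, res.schedule)
        assert traj[-1] == pytest.approx(res.value)

    def test_deterministic_given_seed(self):
        sc = random_group_scenario(GroupSpec(seed=8), 4, 3, 9)
        a = optimize(sc, budget=1500, seed=11)
        b = optimize(sc, budget=1500, seed=11)
        assert a.value == b.value and a.schedule == b.schedule

    def test_variance_penalty_spreads_gains(self):
        # one robot, two patients: the total-gain optimum splits 2+1 but a
        # heavy variance penalty prefers the even 1+1 split
        sc = equal_curve_scenario(2, 1, 3)
        res = optimize(sc, ObjectiveSpec(kind="variance_penalized", m=10.0),
                       budget=3000, seed=0)
        gains = per_patient_gains(sc, res.schedule)
        assert gains[0] == pytest.approx(gains[1])

    def test_relative_objective_fills_in_individual_maxima(self):
        sc = equal_curve_scenario(2, 2, 4)
        res = optimize(sc, ObjectiveSpec(kind="relative_to_max", m_p=(1.0, 1.0)),
                       budget=2000, seed=0)
        assert validate_schedule(sc, res.schedule).feasible

    def test_unknown_method_rejected(self, gym_5p5r7t):
        with pytest.raises(ValueError):
            optimize(gym_5p5r7t, method="rank_based")
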