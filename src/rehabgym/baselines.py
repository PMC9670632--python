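"""The two naive comparison schedules: best-robot-only and switch-halfway.

Both resolve contention greedily: repeatedly give the free robot to the
(patient, robot) pair with the largest session gain, so a patient beaten
to their best robot falls back to their next best.  Ties break by lower
patient index, then lower robot index, making both schedules fully
deterministic.
"""

from __future__ import annotations

from .scenario import Scenario, Schedule, TrainingBlock
from .skill_model import gain

__all__ = ["best_robot_schedule", "switch_halfway_schedule"]


def _greedy_assign(scenario: Scenario, patients, robots, duration_of):
    """Greedy max-gain matching of `patients` to `robots`.

    `duration_of(robot)` gives the training duration a patient would get
    on that robot.  Returns {patient: robot} for the pairs assigned;
    patients left without a free robot are omitted.  Pairs whose duration
    would be nonpositive are not assignable.
    """
    free_patients = set(patients)
    free_robots = set(robots)
    assignment: dict[int, int] = {}
    while free_patients and free_robots:
        best = None
        for p in sorted(free_patients):
            for r in sorted(free_robots):
                d = duration_of(r)
                if d < 1:
                    continue
                g = gain(scenario.curve(p, r), d)
                # strict > keeps the lowest (patient, robot) on ties
                if best is None or g > best[0] + 1e-12:
                    best = (g, p, r)
        if best is None:
            break
        _, p, r = best
        assignment[p] = r
        free_patients.discard(p)
        free_robots.discard(r)
    return assignment


def best_robot_schedule(scenario: Scenario) -> Schedule:
    """Each assigned patient holds a single robot for the whole session.

    Exactly min(M, N) patients are assigned; with more patients than
    robots the surplus patients (those losing every greedy round) idle.
    """
    patients = range(1, scenario.n_patients + 1)
    robots = range(1, scenario.n_robots + 1)
    assignment = _greedy_assign(scenario, patients, robots, lambda r: scenario.G)
    blocks = [
        TrainingBlock(patient=p, robot=r, start=1, end=scenario.G)
        for p, r in assignment.items()
    ]
    return Schedule(tuple(blocks))


def switch_halfway_schedule(scenario: Scenario) -> Schedule:
    """Each assigned patient trains on one robot for the first half of the
    session and a second robot for the second half.

    With exit time ``e`` on the first robot the halves are
    ``d1 = ceil((G - e)/2)`` and ``d2 = G - e - d1`` (longer half first;
    12 steps with e=1 splits 6+5, reproducing the reference layout).  The
    same greedy conflict resolution is applied per half; a patient who
    cannot get a second robot keeps their first robot for the whole
    session, and one who gets nothing idles.
    """
    G = scenario.G
    patients = list(range(1, scenario.n_patients + 1))
    robots = list(range(1, scenario.n_robots + 1))

    def d1_of(r: int) -> int:
        e = scenario.exit_time(r)
        return -((G - e) // -2)  # ceil((G - e) / 2)

    first = _greedy_assign(scenario, patients, robots, d1_of)

    blocks: list[TrainingBlock] = []
    second_candidates: list[int] = []
    first_end: dict[int, int] = {}
    for p, r in first.items():
        d1 = d1_of(r)
        d2 = G - scenario.exit_time(r) - d1
        if d2 >= 1:
            blocks.append(TrainingBlock(p, r, 1, d1))
            first_end[p] = d1
            second_candidates.append(p)
        else:  # session too short to switch: keep the robot throughout
            blocks.append(TrainingBlock(p, r, 1, G))

    # Second half: greedily hand out the remaining session time.  A robot
    # is usable by patient p only after both p's own exit window and the
    # robot's first-half occupant's exit window have elapsed.
    free_robots = set(robots)
    free_patients = set(second_candidates)
    n = scenario.n_robots
    while free_patients and free_robots:
        best = None
        for p in sorted(free_patients):
            p_ready = first_end[p] + scenario.exit_time(first[p]) + 1
            # cyclic tie-break: prefer the robot just after the first-half
            # one, so equal-gain groups rotate instead of deadlocking the
            # last patient on their own robot
            ordered = sorted(free_robots, key=lambda r: (r - first[p] - 1) % n)
            for r in ordered:
                if r == first[p]:
                    continue
                r_ready = 1
                occupant = next((q for q, rr in first.items() if rr == r), None)
                if occupant is not None and occupant in first_end:
                    r_ready = first_end[occupant] + scenario.exit_time(r) + 1
                elif occupant is not None:
                    continue  # occupant kept the robot for the whole session
                start = max(p_ready, r_ready)
                if start > min(G, scenario.H):
                    continue
                g = gain(scenario.curve(p, r), G - start + 1)
                if best is None or g > best[0] + 1e-12:
                    best = (g, p, r, start)
        if best is None:
            break
        _, p, r, start = best
        blocks.append(TrainingBlock(p, r, start, G))
        free_patients.discard(p)
        free_robots.discard(r)

    # Patients who could not get any second robot keep their first one for
    # the whole session — unless someone else claimed it for the second half.
    for p in sorted(free_patients):
        r = first[p]
        if any(b.robot == r and b.start > first_end[p] for b in blocks):
            continue
        blocks.remove(TrainingBlock(p, r, 1, first_end[p]))
        blocks.append(TrainingBlock(p, r, 1, G))

    return Schedule(tuple(blocks))
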