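"""Random patient groups, the nine-scenario evaluation suite, and the
scaling experiment.

The equal-curve suite crosses three gym sizes (5P/5R, 6P/5R, 5P/7R) with
three time variants (7 steps, 12 steps, 12 steps with exit time 1).
Random groups emulate heterogeneous patients by drawing a pool of skill
curves with c2 and c3 spread over several decades and dealing them to
patient-robot pairs without replacement.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import best_robot_schedule, switch_halfway_schedule
from .optimizer import max_individual_gain, optimize
from .scenario import (
    ObjectiveSpec,
    Scenario,
    Schedule,
    equal_curve_scenario,
    per_patient_gains,
    total_gain,
    trajectory,
    validate_schedule,
)
from .skill_model import SkillCurve

__all__ = [
    "GroupSpec",
    "SuiteResult",
    "generate_group",
    "random_group_scenario",
    "equal_curve_suite",
    "run_suite",
    "scaling_experiment",
    "SCHEDULE_TYPES",
]

SCHEDULE_TYPES = ("disjunctive", "time_indexed", "best_robot", "switch_halfway")


@dataclass(frozen=True)
class GroupSpec:
    """How to draw a random patient group's skill curves.

    A pool of ``n_curves`` curves is sampled with ``c2`` and ``c3``
    log-uniform over their ranges (both span 3-4 decades, so a uniform
    draw would almost never produce small values; a ``uniform`` flag is
    available), then dealt to the M*N patient-robot pairs without
    replacement.
    """

    n_curves: int = 42
    c2_range: tuple[float, float] = (0.01, 100.0)
    c3_range: tuple[float, float] = (5.0, 1000.0)
    c1: float = 100.0
    c4: float = 1.0
    u: float = 1.0
    seed: int = 0
    log_uniform: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.c2_range, self.c3_range):
            if not (0 < lo < hi):
                raise ValueError("parameter ranges must be positive with low < high")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")


def generate_group(spec: GroupSpec, n_patients: int, n_robots: int):
    """Draw the curve pool and deal an M x N curve matrix, deterministically
    per seed.  Requires ``n_curves >= M*N`` (dealing without replacement)."""
    needed = n_patients * n_robots
    if spec.n_curves < needed:
        raise ValueError(
            f"pool of {spec.n_curves} curves cannot cover {needed} patient-robot pairs"
        )
    rng = np.random.default_rng(spec.seed)

    def draw(lo: float, hi: float, size: int) -> np.ndarray:
        if spec.log_uniform:
            return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size)
        return rng.uniform(lo, hi, size)

    c2 = draw(*spec.c2_range, spec.n_curves)
    c3 = draw(*spec.c3_range, spec.n_curves)
    pool = [
        SkillCurve(c1=spec.c1, c2=float(a), c3=float(b), c4=spec.c4, u=spec.u)
        for a, b in zip(c2, c3)
    ]
    picks = rng.choice(spec.n_curves, size=needed, replace=False)
    it = iter(picks)
    return tuple(
        tuple(pool[int(next(it))] for _ in range(n_robots)) for _ in range(n_patients)
    )


def random_group_scenario(
    spec: GroupSpec, n_patients: int, n_robots: int, G: int, exit_time: int = 0
) -> Scenario:
    """An equal-curve scenario's layout with a random group's curve matrix."""
    base = equal_curve_scenario(n_patients, n_robots, G, exit_time=exit_time)
    return Scenario(n_patients, base.robots, base.G, base.H, generate_group(spec, n_patients, n_robots))


def equal_curve_suite() -> list[tuple[str, Scenario]]:
    """The nine equal-curve evaluation scenarios:
    (5P5R, 6P5R, 5P7R) x (7T, 12T, 12T with exit time 1)."""
    out = []
    for m, n in ((5, 5), (6, 5), (5, 7)):
        for G, e in ((7, 0), (12, 0), (12, 1)):
            tag = f"{m}P {n}R {G} T" + (" with exit time" if e else "")
            out.append((tag, equal_curve_scenario(m, n, G, exit_time=e)))
    return out


def random_group_suite(spec: GroupSpec) -> list[tuple[str, Scenario]]:
    """The same nine scenarios with one random group's curves (pairs beyond
    the 5x5 core reuse the same pool, dealt per scenario shape)."""
    out = []
    for m, n in ((5, 5), (6, 5), (5, 7)):
        for G, e in ((7, 0), (12, 0), (12, 1)):
            tag = f"{m}P {n}R {G} T" + (" with exit time" if e else "")
            out.append((tag, random_group_scenario(spec, m, n, G, exit_time=e)))
    return out


@dataclass
class CellResult:
    """One (scenario, schedule type) evaluation."""

    schedule: Schedule
    total: float
    per_patient: np.ndarray
    trajectory: np.ndarray
    iterations_used: int = 0
    bound: float | None = None


@dataclass
class SuiteResult:
    """Per-scenario, per-schedule-type totals and trajectories."""

    cells: dict = field(default_factory=dict)  # (scenario tag, type) -> CellResult
    scenario_tags: list = field(default_factory=list)
    schedule_types: tuple = SCHEDULE_TYPES
    budget: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Totals as one row per scenario, one column per schedule type."""
        data = {
            t: [self.cells[(tag, t)].total for tag in self.scenario_tags]
            for t in self.schedule_types
        }
        return pd.DataFrame(data, index=pd.Index(self.scenario_tags, name="Scenario (PxRxT)"))

    def to_csv(self, path) -> None:
        self.to_frame().round(1).to_csv(path)


def _build_schedule(scenario: Scenario, schedule_type: str, budget: int, seed: int):
    if schedule_type == "best_robot":
        return best_robot_schedule(scenario), 0, None
    if schedule_type == "switch_halfway":
        return switch_halfway_schedule(scenario), 0, None
    res = optimize(scenario, ObjectiveSpec(), method=schedule_type, budget=budget, seed=seed)
    return res.schedule, res.iterations_used, res.bound


def run_suite(
    scenarios: list[tuple[str, Scenario]],
    schedule_types=SCHEDULE_TYPES,
    budget: int = 20000,
    seed: int = 0,
) -> SuiteResult:
    """Evaluate every (scenario, schedule type) cell.

    Optimized cells are seeded from the baselines, so for a shared seed the
    optimizer columns dominate the baseline columns row by row.
    """
    result = SuiteResult(schedule_types=tuple(schedule_types), budget=budget, seed=seed)
    for tag, scenario in scenarios:
        result.scenario_tags.append(tag)
        for schedule_type in schedule_types:
            schedule, iters, bound = _build_schedule(scenario, schedule_type, budget, seed)
            assert validate_schedule(scenario, schedule).feasible
            result.cells[(tag, schedule_type)] = CellResult(
                schedule=schedule,
                total=total_gain(scenario, schedule),
                per_patient=per_patient_gains(scenario, schedule),
                trajectory=trajectory(scenario, schedule),
                iterations_used=iters,
                bound=bound,
            )
    return result


def scaling_experiment(
    axis: str,
    values,
    method: str = "disjunctive",
    base=(5, 5, 5),
    exit_time: int = 0,
    budget: int = 20000,
    seed: int = 0,
    curve: SkillCurve | None = None,
) -> pd.DataFrame:
    """Re-run the optimizer while growing one problem dimension.

    ``axis`` is one of ``time_steps``, ``patients``, ``robots``; ``base``
    is the (patients, robots, time steps) kept fixed on the other axes.
    Wall-clock durations are recorded for illustration only — they depend
    on the hardware — alongside the achieved gain.
    """
    if axis not in ("time_steps", "patients", "robots"):
        raise ValueError(f"unknown axis {axis!r}")
    rows = []
    m0, n0, g0 = base
    for v in values:
        v = int(v)
        if v < 1:
            raise ValueError("axis values must be positive integers")
        m, n, g = m0, n0, g0
        if axis == "patients":
            m = v
        elif axis == "robots":
            n = v
        else:
            g = v
        kwargs = {} if curve is None else {"curve": curve}
        scenario = equal_curve_scenario(m, n, g, exit_time=exit_time, **kwargs)
        tic = time.perf_counter()
        res = optimize(scenario, method=method, budget=budget, seed=seed)
        wall = time.perf_counter() - tic
        rows.append({axis: v, "wall_time_s": wall, "total_gain": res.value,
                     "bound": res.bound, "iterations": res.iterations_used})
    return pd.DataFrame(rows)


def max_gains_for(scenario: Scenario) -> tuple[float, ...]:
    """Per-patient solo maxima (used by the relative-to-max objective)."""
    return tuple(max_individual_gain(scenario, p) for p in range(1, scenario.n_patients + 1))
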