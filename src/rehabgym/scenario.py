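"""Gym scenarios, training schedules, feasibility checking and objectives.

A scenario is an open-shop-style gym: ``M`` patients, ``N`` single-skill
robots (one robot per skill), a session of ``G`` discrete 1-based time
steps, a last allowed start step ``H <= G``, per-robot exit times and an
``M x N`` matrix of skill curves.  A schedule is a set of inclusive
training blocks ``[start, end]``; whenever a block is followed by another
block of the same patient or on the same robot, the successor must start
at ``end + e + 1`` or later, where ``e`` is the exit time of the robot
being vacated.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .skill_model import EQUAL_CURVE, SkillCurve, gain

__all__ = [
    "RobotSpec",
    "Scenario",
    "TrainingBlock",
    "Schedule",
    "ObjectiveSpec",
    "FeasibilityReport",
    "Violation",
    "StructuralError",
    "InfeasibleScheduleError",
    "validate_schedule",
    "total_gain",
    "per_patient_gains",
    "trajectory",
    "objective_value",
    "equal_curve_scenario",
    "load_scenario",
    "scenario_from_dict",
    "save_schedule_csv",
    "load_schedule_csv",
    "save_schedule_json",
]


class StructuralError(ValueError):
    """A schedule references patients/robots that do not exist (distinct
    from plain infeasibility)."""


class InfeasibleScheduleError(ValueError):
    """An operation requiring a feasible schedule was given an infeasible
    one; carries the offending :class:`FeasibilityReport`."""

    def __init__(self, report: "FeasibilityReport"):
        self.report = report
        tags = ", ".join(sorted({v.tag for v in report.violations}))
        super().__init__(f"schedule is infeasible: {tags}")


@dataclass(frozen=True)
class RobotSpec:
    """One robot: 1-based id, exit time in steps, and the skill it trains
    (defaults to its own id — one robot per skill)."""

    id: int
    exit_time: int = 0
    skill_id: int | None = None

    def __post_init__(self) -> None:
        if self.exit_time < 0 or int(self.exit_time) != self.exit_time:
            raise ValueError(f"exit_time must be a nonnegative integer, got {self.exit_time}")
        if self.skill_id is None:
            object.__setattr__(self, "skill_id", self.id)


@dataclass(frozen=True)
class Scenario:
    """Gym definition: patients, robots, horizon G, last start H, curves."""

    n_patients: int
    robots: tuple[RobotSpec, ...]
    G: int
    H: int
    curves: tuple[tuple[SkillCurve, ...], ...]  # M x N

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not 1 <= self.H <= self.G:
            raise ValueError(f"H must satisfy 1 <= H <= G, got H={self.H}, G={self.G}")
        ids = [r.id for r in self.robots]
        if ids != list(range(1, len(self.robots) + 1)):
            raise ValueError("robot ids must be 1..N in order")
        skills = [r.skill_id for r in self.robots]
        if len(set(skills)) != len(skills):
            raise ValueError("skill_id must be unique across robots (one robot per skill)")
        if len(self.curves) != self.n_patients or any(
            len(row) != len(self.robots) for row in self.curves
        ):
            raise ValueError("curves must be an M x N matrix covering every patient-robot pair")

    @property
    def n_robots(self) -> int:
        return len(self.robots)

    def curve(self, patient: int, robot: int) -> SkillCurve:
        """Skill curve of 1-based (patient, robot)."""
        return self.curves[patient - 1][robot - 1]

    def exit_time(self, robot: int) -> int:
        return self.robots[robot - 1].exit_time


@dataclass(frozen=True, order=True)
class TrainingBlock:
    """One uninterrupted training interval, 1-based inclusive [start, end]."""

    patient: int
    robot: int
    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Schedule:
    """A set of training blocks, canonically ordered by (patient, start)."""

    blocks: tuple[TrainingBlock, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.blocks, key=lambda b: (b.patient, b.start, b.robot)))
        object.__setattr__(self, "blocks", ordered)

    def __len__(self) -> int:
        return len(self.blocks)

    def for_patient(self, patient: int) -> tuple[TrainingBlock, ...]:
        return tuple(b for b in self.blocks if b.patient == patient)

    def for_robot(self, robot: int) -> tuple[TrainingBlock, ...]:
        return tuple(b for b in self.blocks if b.robot == robot)


@dataclass(frozen=True)
class Violation:
    """One violated scheduling constraint and the block(s) involved."""

    tag: str  # bounds | last_start | robot_overlap | patient_overlap |
              # robot_exit_gap | patient_exit_gap | duplicate_pair
    blocks: tuple[TrainingBlock, ...]


@dataclass(frozen=True)
class FeasibilityReport:
    violations: tuple[Violation, ...] = ()

    @property
    def feasible(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which group objective to score a schedule with.

    ``total``: plain total gain.  ``variance_penalized``: total gain minus
    ``m`` times the (population) variance of per-patient gains.
    ``relative_to_max``: per patient j, gain_j - m_j*(1 - gain_j/max_j),
    where max_j is that patient's maximum attainable gain training alone.
    """

    kind: str = "total"
    m: float = 0.0
    m_p: tuple[float, ...] | None = None
    max_gains: tuple[float, ...] | None = None
    variance_ddof: int = 0  # population variance by default

    def __post_init__(self) -> None:
        if self.kind not in ("total", "variance_penalized", "relative_to_max"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.m < 0:
            raise ValueError("penalty coefficient m must be >= 0")
        if self.m_p is not None and any(m < 0 for m in self.m_p):
            raise ValueError("per-patient penalty coefficients must be >= 0")


def validate_schedule(scenario: Scenario, schedule: Schedule) -> FeasibilityReport:
    """Check a schedule against the gym's constraint system.

    Returns a report listing every violated constraint.  Out-of-range
    patient/robot indices raise :class:`StructuralError` instead (they
    are malformed input, not an infeasible schedule).
    """
    for b in schedule.blocks:
        if not 1 <= b.patient <= scenario.n_patients:
            raise StructuralError(f"unknown patient index {b.patient}")
        if not 1 <= b.robot <= scenario.n_robots:
            raise StructuralError(f"unknown robot index {b.robot}")

    violations: list[Violation] = []
    for b in schedule.blocks:
        if not (1 <= b.start <= b.end <= scenario.G):
            violations.append(Violation("bounds", (b,)))
        elif b.start > scenario.H:
            violations.append(Violation("last_start", (b,)))

    seen_pairs: dict[tuple[int, int], TrainingBlock] = {}
    for b in schedule.blocks:
        key = (b.patient, b.robot)
        if key in seen_pairs:
            violations.append(Violation("duplicate_pair", (seen_pairs[key], b)))
        else:
            seen_pairs[key] = b

    def check_chain(blocks: Sequence[TrainingBlock], overlap_tag: str, gap_tag: str) -> None:
        ordered = sorted(blocks, key=lambda b: (b.start, b.end))
        for prev, nxt in zip(ordered, ordered[1:]):
            e = scenario.exit_time(prev.robot)
            if nxt.start <= prev.end:
                violations.append(Violation(overlap_tag, (prev, nxt)))
            elif nxt.start < prev.end + e + 1:
                violations.append(Violation(gap_tag, (prev, nxt)))

    for p in range(1, scenario.n_patients + 1):
        check_chain(schedule.for_patient(p), "patient_overlap", "patient_exit_gap")
    for r in range(1, scenario.n_robots + 1):
        check_chain(schedule.for_robot(r), "robot_overlap", "robot_exit_gap")

    return FeasibilityReport(tuple(violations))


def _require_feasible(scenario: Scenario, schedule: Schedule) -> None:
    report = validate_schedule(scenario, schedule)
    if not report.feasible:
        raise InfeasibleScheduleError(report)


def total_gain(scenario: Scenario, schedule: Schedule) -> float:
    """Total skill gain of a feasible schedule, summed over all blocks."""
    _require_feasible(scenario, schedule)
    return sum(gain(scenario.curve(b.patient, b.robot), b.duration) for b in schedule.blocks)


def per_patient_gains(scenario: Scenario, schedule: Schedule) -> np.ndarray:
    """Length-M vector of each patient's session gain; sums to total_gain."""
    _require_feasible(scenario, schedule)
    out = np.zeros(scenario.n_patients)
    for b in schedule.blocks:
        out[b.patient - 1] += gain(scenario.curve(b.patient, b.robot), b.duration)
    return out


def trajectory(scenario: Scenario, schedule: Schedule) -> np.ndarray:
    """Cumulative group gain after each step t = 1..G (nondecreasing;
    final entry equals total_gain)."""
    _require_feasible(scenario, schedule)
    out = np.zeros(scenario.G)
    for b in schedule.blocks:
        curve = scenario.curve(b.patient, b.robot)
        for t in range(1, scenario.G + 1):
            d = min(max(t - b.start + 1, 0), b.duration)
            out[t - 1] += gain(curve, d)
    return out


def objective_value(scenario: Scenario, schedule: Schedule, spec: ObjectiveSpec) -> float:
    """Score a feasible schedule under a group objective."""
    if spec.kind == "total":
        return total_gain(scenario, schedule)
    gains = per_patient_gains(scenario, schedule)
    if spec.kind == "variance_penalized":
        var = float(np.var(gains, ddof=spec.variance_ddof)) if len(gains) else 0.0
        return float(gains.sum() - spec.m * var)
    # relative_to_max
    if spec.max_gains is None:
        raise ValueError("relative_to_max requires per-patient max_gains "
                         "(see optimizer.max_individual_gain)")
    m_p = spec.m_p if spec.m_p is not None else (0.0,) * scenario.n_patients
    value = 0.0
    for g_j, m_j, max_j in zip(gains, m_p, spec.max_gains):
        if max_j <= 0:
            if m_j > 0:
                raise ValueError("relative_to_max penalty requires max_gain > 0 "
                                 "for every penalized patient")
            value += g_j
        else:
            value += g_j - m_j * (1.0 - g_j / max_j)
    return float(value)


# ---------------------------------------------------------------------------
# Construction helpers and config / schedule serialization
# ---------------------------------------------------------------------------

def equal_curve_scenario(
    n_patients: int,
    n_robots: int,
    G: int,
    exit_time: int = 0,
    H: int | None = None,
    curve: SkillCurve = EQUAL_CURVE,
) -> Scenario:
    """Scenario where every patient-robot pair shares one skill curve
    (the study preset by default) and every robot has the same exit time."""
    robots = tuple(RobotSpec(id=i, exit_time=exit_time) for i in range(1, n_robots + 1))
    curves = tuple(tuple(curve for _ in range(n_robots)) for _ in range(n_patients))
    return Scenario(n_patients, robots, G, G if H is None else H, curves)


def _curve_from_record(rec) -> SkillCurve:
    if isinstance(rec, SkillCurve):
        return rec
    if isinstance(rec, str):
        if rec == "equal":
            return EQUAL_CURVE
        raise ValueError(f"unknown curve preset {rec!r}")
    return SkillCurve(**{k: float(v) for k, v in rec.items()})


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a scenario from a configuration mapping.

    Fields: ``patients`` (int), ``robots`` (int, or list of
    ``{id, exit_time}``), ``G``, optional ``H`` (default G), optional
    ``exit_time`` default for integer ``robots``, and ``curves`` — either
    the string ``"equal"``, an M x N matrix of curve records
    ``{c1, c2, c3, c4, u}``, or ``{random: {...GroupSpec fields...}}``
    for a seeded random group (see :mod:`rehabgym.evaluation`).
    """
    m = int(cfg["patients"])
    robots_cfg = cfg["robots"]
    if isinstance(robots_cfg, int):
        e = int(cfg.get("exit_time", 0))
        robots = tuple(RobotSpec(id=i, exit_time=e) for i in range(1, robots_cfg + 1))
    else:
        robots = tuple(
            RobotSpec(id=int(r["id"]), exit_time=int(r.get("exit_time", 0)))
            for r in robots_cfg
        )
    n = len(robots)
    G = int(cfg["G"])
    H = int(cfg.get("H", G))
    curves_cfg = cfg.get("curves", "equal")
    if curves_cfg == "equal":
        curves = tuple(tuple(EQUAL_CURVE for _ in range(n)) for _ in range(m))
    elif isinstance(curves_cfg, dict) and "random" in curves_cfg:
        from .evaluation import GroupSpec, generate_group

        curves = generate_group(GroupSpec(**curves_cfg["random"]), m, n)
    else:
        curves = tuple(tuple(_curve_from_record(rec) for rec in row) for row in curves_cfg)
    return Scenario(m, robots, G, H, curves)


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML (or JSON) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg)


_CSV_HEADER = ["patient", "robot", "start", "end"]


def save_schedule_csv(schedule: Schedule, path: str | Path) -> None:
    """Write blocks as CSV (columns patient, robot, start, end; 1-based
    inclusive steps, stated in a comment header line)."""
    with open(path, "w", newline="") as fh:
        fh.write("# time steps are 1-based; [start, end] inclusive\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for b in schedule.blocks:
            writer.writerow([b.patient, b.robot, b.start, b.end])


def load_schedule_csv(path: str | Path) -> Schedule:
    with open(path) as fh:
        rows = [r for r in csv.reader(line for line in fh if not line.startswith("#"))]
    if rows and rows[0] == _CSV_HEADER:
        rows = rows[1:]
    return Schedule(tuple(TrainingBlock(*(int(v) for v in row)) for row in rows if row))


def save_schedule_json(scenario: Scenario, schedule: Schedule, path: str | Path) -> None:
    """JSON variant embedding per-patient gains and the group trajectory."""
    payload = {
        "time_convention": "1-based inclusive [start, end]",
        "blocks": [
            {"patient": b.patient, "robot": b.robot, "start": b.start, "end": b.end}
            for b in schedule.blocks
        ],
        "total_gain": total_gain(scenario, schedule),
        "per_patient_gains": per_patient_gains(scenario, schedule).tolist(),
        "trajectory": trajectory(scenario, schedule).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
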