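"""Hyperbolic skill-acquisition curves for patient-robot training.

Skill on one (patient, robot) pair follows a modified hyperbola of
cumulative training time: rapid early gains, then diminishing returns.
With ``d`` integer training steps the skill value is

    S(d) = c1 * (c2 + c4*(d + u)) / (c2 + c4*(d + u) + c3)

and the session *gain* is ``S(d) - S(0)``.  ``c1`` is the ceiling (e.g.
the maximum score of a clinical scale), ``c2``/``c3`` shape the curve
(and set the initial skill), ``c4`` is the advance rate per time step,
and ``u`` calibrates for training done in previous sessions (prior steps
plus one; ``u = 1`` means a naive patient).
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

__all__ = [
    "SkillCurve",
    "EQUAL_CURVE",
    "ParameterError",
    "initial_skill",
    "gain",
    "marginal_gain",
]


class ParameterError(ValueError):
    """A skill-curve parameter violates its domain bound."""


@dataclass(frozen=True)
class SkillCurve:
    """Parameters of one patient-robot learning curve.

    Defaults are the equal-curve study preset: ceiling 100, naive patient,
    one curve unit gained per training step.
    """

    c1: float = 100.0  # maximum attainable skill (skill units)
    c2: float = 1.0    # shape offset, >= 0
    c3: float = 10.0   # shape divisor, > 0
    c4: float = 1.0    # advance rate per time step, >= 0
    u: float = 1.0     # prior training steps + 1, >= 0

    def __post_init__(self) -> None:
        if not self.c1 >= 0:
            raise ParameterError(f"c1 must be >= 0, got {self.c1}")
        if not self.c3 > 0:
            raise ParameterError(f"c3 must be > 0, got {self.c3}")
        if not self.c4 >= 0:
            raise ParameterError(f"c4 must be >= 0, got {self.c4}")
        if not self.u >= 0:
            raise ParameterError(f"u must be >= 0, got {self.u}")
        if not self.c2 + self.c4 * self.u >= 0:
            raise ParameterError(
                f"c2 + c4*u must be >= 0, got {self.c2 + self.c4 * self.u}"
            )


#: The study's equal-curve preset (every patient-robot pair identical).
EQUAL_CURVE = SkillCurve(c1=100.0, c2=1.0, c3=10.0, c4=1.0, u=1.0)


def _skill_at(curve: SkillCurve, d: int) -> float:
    w = curve.c2 + curve.c4 * (d + curve.u)
    return curve.c1 * w / (w + curve.c3)


def _check_steps(d, minimum: int) -> int:
    if isinstance(d, bool) or not isinstance(d, Integral):
        raise ValueError(f"training duration must be an integer, got {d!r}")
    d = int(d)
    if d < minimum:
        raise ValueError(f"training duration must be >= {minimum}, got {d}")
    return d


def initial_skill(curve: SkillCurve) -> float:
    """Skill value before the current session (zero training steps)."""
    return _skill_at(curve, 0)


def gain(curve: SkillCurve, d) -> float:
    """Skill gained by training ``d`` integer steps on this curve.

    Zero at ``d = 0``; strictly increasing and concave in ``d`` when
    ``c4 > 0``, approaching ``c1 - initial_skill`` as ``d`` grows.
    """
    d = _check_steps(d, 0)
    return _skill_at(curve, d) - _skill_at(curve, 0)


def marginal_gain(curve: SkillCurve, d) -> float:
    """Extra gain of the ``d``-th training step: ``gain(d) - gain(d-1)``.

    Strictly positive and strictly decreasing in ``d`` when ``c4 > 0``
    (diminishing returns); used by the optimizer's capacity bound.
    """
    d = _check_steps(d, 1)
    return _skill_at(curve, d) - _skill_at(curve, d - 1)
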