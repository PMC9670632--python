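"""Evaluate a hyperbolic skill curve: initial skill, session gains and
diminishing marginal returns."""

from rehabgym import EQUAL_CURVE, SkillCurve, gain, initial_skill, marginal_gain

print("Study preset curve:", EQUAL_CURVE)
print(f"initial skill          : {initial_skill(EQUAL_CURVE):.4f}")
for d in (1, 4, 7, 12):
    print(f"gain after {d:2d} steps    : {gain(EQUAL_CURVE, d):.4f}")
print("marginal gains (steps 1-5):",
      " ".join(f"{marginal_gain(EQUAL_CURVE, k):.3f}" for k in range(1, 6)))

# a slow-learning, low-start patient: large shape divisor c3
slow = SkillCurve(c2=0.1, c3=500.0)
print(f"\nSlow curve initial skill {initial_skill(slow):.4f}, "
      f"gain after 12 steps {gain(slow, 12):.4f}")
print("Each extra step is worth less than the one before — the scheduler's"
      "\nreason to move patients between robots before returns flatten out.")
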