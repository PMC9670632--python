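"""How optimization cost and achieved gain grow with the session length.

Wall-clock numbers are illustrative only — they depend on the machine."""

from rehabgym.evaluation import scaling_experiment

frame = scaling_experiment("time_steps", [1, 2, 3, 4, 5], base=(5, 5, 5),
                           budget=10000, seed=0)
print(frame.round({"wall_time_s": 2, "total_gain": 1, "bound": 1}).to_string(index=False))
print("\nLonger sessions mean larger search spaces; the achieved gain"
      "\ngrows concavely because every curve has diminishing returns.")
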