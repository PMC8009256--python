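"""Maximal runs of correct and microsaccade-free trials.

Counts maximal streaks (sub-runs are not counted) of trials whose first
saccade landed on the face, and of trials without any microsaccade in the
peri-trial (-200, 800) ms interval.  Streaks do not span block boundaries.
"""

import zapgaze as zg
from zapgaze import metrics, runs

cfg = zg.SimulationConfig(n_blocks=2, trials_per_block=250, rng_seed=4)
session = zg.simulate_session(cfg)
events = zg.detect_session(session.recording, segment_bounds_ms=session.block_bounds_ms)
fs = metrics.first_saccade_after_onset(session.trials, events)

for criterion in ("correct", "microsaccade_free"):
    flags = runs.trial_flags(session.trials, events, criterion, fs)
    table = runs.run_table_per_block(session.trials, flags, criterion)
    frame = table.to_frame()
    print(f"criterion: {criterion}")
    print(f"  criterion-true trials: {int(flags.sum())}/{len(flags)}")
    print(f"  maximal runs: {frame['count'].sum()}, longest: {table.longest} trials")
    print(f"  longest five run lengths: "
          f"{sorted(table.counts, reverse=True)[:5]}")
print()
print("With ~84% targeting accuracy, correct streaks of a dozen or more trials are")
print("common. The microsaccade-free criterion uses the full (-200, 800) ms interval,")
print("which at ~4 faces/s overlaps neighboring trials, so a single microsaccade")
print("disqualifies several trials at once - yet multi-trial microsaccade-free")
print("streaks still occur: continuous search does not require microsaccades.")
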