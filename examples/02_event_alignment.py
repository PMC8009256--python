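"""Align events to trial and saccade anchors; when do microsaccades occur?

Reproduces the core temporal finding of the zapping paradigm on synthetic
data: microsaccades are launched within ~1-25 ms after the targeting
saccade's offset, and essentially never between a trial's onset and its
first saccade.
"""

import zapgaze as zg
from zapgaze import metrics

cfg = zg.SimulationConfig(n_blocks=2, trials_per_block=250, rng_seed=2)
session = zg.simulate_session(cfg)
events = zg.detect_session(session.recording, segment_bounds_ms=session.block_bounds_ms)
fs = metrics.first_saccade_after_onset(session.trials, events)

for label, window, anchor in [
    ("100 ms before trial onset", (-100.0, 0.0), "trial_onset"),
    ("100 ms after trial onset", (0.0, 100.0), "trial_onset"),
    ("100 ms after 1st-saccade offset", (0.0, 100.0), "first_saccade_offset"),
]:
    cd = metrics.microsaccade_count_distribution(
        session.trials, events, window, anchor, first_sacc=fs
    )
    print(f"{label:33s}: 0 micro {cd.pct_0:5.1f}%  1 micro {cd.pct_1:5.1f}%  "
          f">=2 {cd.pct_2plus:4.1f}%")

raster = metrics.align_events(
    session.trials, events, "first_saccade_offset", (0.0, 50.0), fs
)
rel = raster.kind_times("microsaccade_start")["rel_ms"]
print(f"\nmicrosaccade latencies after saccade offset: "
      f"min {rel.min():.1f} ms, median {rel.median():.1f} ms, max {rel.max():.1f} ms")

rates = metrics.subject_rates(session.trials, events, (-200, 800), "microsaccade")
print(f"microsaccade rate in the peri-trial second: {rates['mean_hz']:.2f} Hz")
print()
print("Microsaccades appear almost exclusively in the few tens of ms right after")
print("a targeting saccade lands - i.e. just before the next trial begins - and")
print("are absent from the post-onset fixation period.")
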