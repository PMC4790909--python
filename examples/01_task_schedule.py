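"""Generate one relevance-modulation task session and summarize it.

The schedule is the backbone of every simulation: 8 blocks (B-L-L-B-L-B-B-L)
of 40 alternating butterfly/ladybird stimuli, ~1.93 s onset-to-onset, a 30 s
rest after each block, and rare (p=0.05) targets on relevant trials only.
"""

import numpy as np

from megbeta import task

schedule = task.generate_schedule(seed=0)

n_rel = sum(t.is_relevant for t in schedule.trials)
n_tgt = sum(t.is_target for t in schedule.trials)
isis = []
for b in range(1, 9):
    onsets = sorted(t.onset_ms for t in schedule.trials if t.block_index == b)
    isis.extend(np.diff(onsets))

print(f"trials: {len(schedule.trials)} ({n_rel} relevant, {n_tgt} targets)")
print(f"onset-to-onset interval: {np.mean(isis):.0f} +/- {np.std(isis):.0f} ms")
print(f"rest windows: {len(schedule.rest_windows)} x "
      f"{(schedule.rest_windows[0][1] - schedule.rest_windows[0][0]) / 1000:.0f} s")
print(f"session length: {schedule.duration_ms / 1000:.0f} s")
# Targets are excluded from analysis epochs (they carry button presses):
print(f"analysable relevant epochs: {schedule.onsets_ms('relevant').size}")
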