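"""Recover the power-on offset between the two wristbands.

The two devices are started by hand a few seconds apart, so their sample
indices disagree by a constant lag. This example injects a known offset,
then recovers it by minimizing the mean absolute difference between the two
decimated magnitude series over their overlap.
"""

import numpy as np

from bilacc import (
    ClinicalScores,
    CohortRow,
    SessionParams,
    SynthParams,
    build_session,
    simulate_recording_pair,
)

params = SynthParams(duration_h=0.25, trailing_idle_range_s=60.0, seed=5)
left, right, truth = simulate_recording_pair(
    u=0.6, affected_side="left", params=params, rng=np.random.default_rng(5)
)

meta = CohortRow("demo", "left", "T1", ClinicalScores(5, 1.0, 1.0), "left.csv", "right.csv")
session = build_session(
    left, right, meta,
    session_params=SessionParams(max_lag_s=30.0, trim_min_run_s=30.0, min_overlap_h=0.05),
)

decimated_rate = session.left.rate_hz
print(f"injected offset:  {truth.sync_offset_s:+.2f} s "
      f"({truth.sync_offset_raw_samples / 48:+.2f} decimated samples)")
print(f"recovered lag:    {session.applied_lag_samples:+d} decimated samples "
      f"({session.applied_lag_samples / decimated_rate:+.2f} s)")
print(f"idle tail trimmed (left, right): {session.trimmed_tail_samples} decimated samples")
print(f"common support after sync: {len(session) / decimated_rate:.0f} s")
print()
print("A positive lag means the right band was powered on later than the left;")
print("recovery within one decimated sample (1.5 s) is the pipeline's guarantee.")
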