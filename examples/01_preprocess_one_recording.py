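"""Preprocess a single raw wrist recording into a magnitude series.

Builds a 15-minute synthetic recording for one arm, runs the full
preprocessing chain (count scaling, 3 Hz high-pass, Euclidean norm,
96-sample moving average with 48-sample subsampling) and prints what
comes out the other end.
"""

import numpy as np

from bilacc import SynthParams, preprocess_recording, simulate_recording_pair

params = SynthParams(duration_h=0.25, trailing_idle_range_s=0.0)
left, _, _ = simulate_recording_pair(
    u=0.8, affected_side="right", params=params, rng=np.random.default_rng(1)
)

series = preprocess_recording(left)

print(f"raw:       {len(left)} samples at {left.sample_rate_hz:g} Hz (8-bit counts)")
print(f"decimated: {len(series)} samples at {series.rate_hz:.2f} Hz (m/s^2)")
print(f"mean magnitude: {np.mean(series.values):.3f} m/s^2")
print(f"peak magnitude: {np.max(series.values):.3f} m/s^2")
print(f"transient-flagged leading samples: {series.n_transient}")
print()
print("The 0.67 Hz series is the gravity-free movement intensity of the arm;")
print("rest sits near the sensor noise floor, activity bouts stand out as peaks.")
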