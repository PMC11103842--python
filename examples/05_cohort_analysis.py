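"""Full cohort analysis: descriptives, session deltas, correlation grid.

Simulates an 18-patient cohort in memory (both sessions), runs every
pipeline stage, and prints the three analysis tables: per-session medians
and quartiles, per-patient T2 - T1 changes, and the 3 x 3 Spearman grid of
affected-arm acceleration against M-MAS and the two MAL subscales.
"""

from bilacc import (
    SessionParams,
    SynthParams,
    cohort_descriptives,
    delta_table,
    run_correlation_analysis,
    summarize_simulated_cohort,
)

table, truth = summarize_simulated_cohort(
    SynthParams(n_patients=18, seed=1, duration_h=0.5, trailing_idle_range_s=60.0),
    session_params=SessionParams(max_lag_s=30.0, trim_min_run_s=30.0, min_overlap_h=0.05),
)

print("=== per-session medians (Q1-Q3) ===")
desc = cohort_descriptives(table)
for (var, session), row in desc.iterrows():
    print(f"{var:14s} {session}:  {row['median']:.2f}  ({row['q1']:.2f}-{row['q3']:.2f})")

print("\n=== T2 - T1 deltas (first 5 patients) ===")
print(delta_table(table).head(5).to_string(index=False, float_format=lambda v: f"{v:+.2f}"))

print("\n=== Spearman correlation grid: affected-arm acceleration vs score ===")
grid = run_correlation_analysis(table)
for _, row in grid.iterrows():
    print(f"{row['score']:8s} {row['contrast']:5s}  rho {row['rho']:+.2f}  p {row['p_value']:.3f}")

print("\nStrong positive within-session correlations and a weaker delta row are")
print("the expected signature: scores and acceleration share the latent ability,")
print("while session-to-session changes are noisier.")
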