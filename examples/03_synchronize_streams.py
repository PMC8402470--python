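"""Recovering the clock offset between the cane and reference streams.

Both streams observe the cane's inclination; the simulator records them on
clocks offset by 0.30 s and at different rates (50 vs 100 Hz).  The
synchronizer normalizes, trims to the first/last swing peaks, upsamples the
cane signal and maximizes the Pearson correlation over shifts.
"""

import canegait as cg

injected = 0.30
cfg = cg.GaitSimConfig(injected_lag=injected, seed=12)
recording, kinematics, _ = cg.simulate(cfg)

result = cg.synchronize(
    recording.fsr.timestamps, recording.cane_angle,
    kinematics.timestamps, kinematics.cane_angle,
)
print(f"injected lag : {injected:.4f} s")
print(f"recovered lag: {result.lag:.4f} s "
      f"(error {abs(result.lag - injected) * 1000:.2f} ms)")
print(f"peak Pearson r: {result.peak_correlation:.4f} over "
      f"{result.resampled_length} common-grid samples")

print("\nAdding the recovered lag to every cane-stream timestamp puts grip")
print("events and reference phase onsets on one clock; sub-sample accuracy")
print("comes from parabolic refinement of the correlation peak.")
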