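"""End-to-end gait-event detection with a planted anticipating maximum.

A CoMZ maximum is planted 5% of the gait cycle (55 ms) before every
pre-swing onset, with 10 ms stride-to-stride jitter, on top of a realistic
noisy recording with a 0.3 s inter-stream lag.  The pipeline synchronizes,
smooths, segments, selects the 30 central strides, and reports the events
that recur in at least 25 of them.
"""

import canegait as cg

sim = cg.GaitSimConfig(
    injected_lag=0.3,
    planted_events=(cg.PlantedEvent("CoMZ", "max", 0.45, jitter_sd=0.010),),
    seed=1,
)
report = cg.run_pipeline(cg.PipelineConfig(sim=sim))

print(f"recovered lag {report.sync.lag:.4f} s; "
      f"{report.central_timeline.n_strides} central strides analyzed; "
      f"{len(report.events)} stride-consistent events\n")

planted = [e for e in report.events
           if (e.variable, e.kind, e.phase) == ("CoMZ", "max", "pre_swing")]
ev = planted[0]
print(f"planted event: {ev.variable} {ev.kind} referenced to {ev.phase}")
print(f"  detected in {ev.n_strides_detected}/{ev.total_strides} strides")
print(f"  median offset {ev.median_offset * 1000:+.1f} ms (planted -55 ms), "
      f"IQR {ev.iqr * 1000:.1f} ms")

print("\nThe negative offset means the grip maximum consistently precedes the")
print("pre-swing onset: it can pre-trigger an assistive device before the")
print("phase begins, compensating actuation delays.")
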