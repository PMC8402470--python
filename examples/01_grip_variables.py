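"""Grip-pressure variables from the 16-sensor handle.

Loads the bundled handle geometry, builds a tiny FSR series by hand, and
computes the six derived variables.  With only sensor 3 loaded the centre of
pressure sits exactly at that sensor's coordinates; with every sensor loaded
equally it sits at the unweighted mean of the coordinates.
"""

import numpy as np

import canegait as cg

layout = cg.load_default_layout()
print(f"handle: {layout.n_sensors} sensors "
      f"({int(layout.top_mask.sum())} top, {int(layout.bottom_mask.sum())} bottom)")

only_sensor_3 = np.zeros(16)
only_sensor_3[2] = 2.0          # sensor ids are 1-based
uniform = np.full(16, 1.0)
series = cg.FSRSeries(timestamps=[0.0, 0.02], forces=[only_sensor_3, uniform])

derived = cg.compute_derived(series, layout)
for name in ("CoMX", "CoMZ", "MPUp", "MPDown"):
    print(f"{name:6s}  sensor-3 only: {derived.channels[name][0]:8.2f}   "
          f"uniform grip: {derived.channels[name][1]:8.2f}")

print("\nCoMX/CoMZ are the force-weighted mean sensor coordinates (mm): a single")
print("loaded sensor pins them to its own position; MPUp/MPDown are the mean")
print("top/bottom sensor outputs (raw units), i.e. how hard each side is gripped.")
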