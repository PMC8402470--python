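# Methods

## Problem and signal model

A user with a one-sided walking impairment holds a cane contralaterally and
swings it in synchrony with the impaired leg. The handle carries 16
force-sensing resistors — 10 along the top side (palm) and 6 along the
bottom side (fingers) — whose coordinates in the handle-local sagittal frame
(x forward, z along the shaft, millimetres) are fixed by the bundled layout.
FSRs are dependable for *timing* but not for absolute force, so all analysis
is carried out on raw conditioned sensor units and on force-weighted
positions, never on calibrated newtons.

Six per-sample variables summarize the grip: the force-weighted mean sensor
coordinate (a grip centre-of-pressure analogue) over the top subset, bottom
subset and full array in x, the full array in z, and the mean output of each
subset (sum over the subset divided by its size, 10 or 6). Their time
derivatives (prefix `d`) double the signal set to 12. A weighted mean is
undefined when its denominator — the subset's total force — is zero; such
samples are masked invalid rather than filled, because a cane is genuinely
unloaded during parts of its swing. Derivatives are central finite
differences on the timestamps (one-sided at the ends), taken only after
smoothing so that differentiation does not amplify sensor noise; masked
samples are bridged by linear interpolation for the stencil and re-masked
afterwards.

## Gait segmentation

A stride runs between successive initial contacts of the tracked
(impaired-side) foot and is split into seven phases; initial contact is
merged with loading response because alone it spans only ~8% of the cycle.
The detection rules, each consuming one threshold of the configuration:

| onset | rule |
|---|---|
| initial contact / loading response | tracked-foot speed falls below the stance threshold (0.4 m/s) after a swing interval |
| mid stance | opposite-foot speed rises above the swing threshold (0.8 m/s): opposite toe-off |
| terminal stance | tracked foot angle rises through 0° (heel rise) while the foot is still in stance speed |
| pre-swing | opposite-foot speed falls below the stance threshold: opposite initial contact |
| initial swing | tracked-foot speed exceeds the swing threshold with foot angle below −9° (toe-down at toe-off) |
| mid swing | feet adjacent: local minimum of the inter-feet distance below 0.4 m |
| terminal swing | tibia angle crosses 90° from the horizontal (vertical shank) |

Onsets are searched sequentially within each stride, each strictly after the
previous one; this ordering resolves the ambiguity that the feet pass each
other twice per stride. Every threshold crossing carries a hysteresis of 2
reference samples on both sides to suppress chatter, and the onset time is
the linear interpolation of the crossing between the bracketing samples,
giving sub-sample accuracy on clean signals. A stride missing any onset is
dropped as incomplete; fewer than 3 complete strides is an error. The full
branch structure of the segmentation is a reconstruction from the stated
thresholds and the standard Perry-cycle events they name; it is deliberately
exposed, rule by rule, in `SegmentationConfig`.

Terminal stance is segmented but excluded as an event reference by default:
it lies so close to pre-swing that events cannot be resolved between the
two, and its kinematic signature (heel rise) is the least reliable of the
seven. The exclusion list is configurable.

## Stream synchronization

The cane electronics (50 Hz) and the reference motion-capture stream
(100 Hz) run on independent clocks but both observe the cane's inclination
to the vertical. Alignment: normalize both signals to [0, 1]; trim each to
the span between its first and last local peak (strict maxima with
prominence ≥ 5% of the normalized range, so noise cannot define the trim
bounds); linearly interpolate the cane segment onto the reference sampling
interval; scan integer-sample shifts within a ±5 s window for the maximum
Pearson correlation, breaking ties toward the smallest absolute lag; refine
the argmax by a parabolic fit through the three correlations around it. The
resulting single global lag is added to every cane-stream timestamp — no
drift correction, matching the short (~2 min) recordings the device targets.
Linear interpolation suffices because cane dynamics are slow relative to
both grids; the parabolic refinement removes the 10 ms grid quantization
that an integer argmax would impose.

## Event detection

After synchronization the 12 channels are smoothed with a 3rd-order
Savitzky–Golay filter. The window is 11 samples (0.22 s at 50 Hz) by
default: long enough to suppress single-sample spikes, shorter than any
phase at walking cadence, so peak timing is preserved; order 3 reproduces
cubic trends exactly. The 30 central strides of the recording are analyzed
(surplus strides split evenly, the odd extra discarded from the start) to
avoid gait initiation and termination.

Per stride and per channel, local maxima and minima are detected with a
prominence floor of 5% of the channel's interquartile range over the
analyzed span — a scale-free guard against residual noise peaks; extremum
times are refined by a parabolic vertex fit. Each extremum is referenced to
the phase onset with the smallest absolute signed offset among the onsets of
its own and the following stride (so an extremum late in a stride can
anticipate the next initial contact); near-equidistant ties go to the onset
still ahead, the anticipating reading. Candidates are grouped by (variable,
extremum kind, referenced phase); a group is reported only if it appears in
at least 25 of the 30 strides, each stride represented by its
smallest-offset candidate, and is summarized by the median and interquartile
range of its offsets. Negative offsets mean the event precedes the phase.

For inspection, every stride can be resampled onto a normalized [0, 1]
stride-time grid (101 points; 0 = initial contact, 1 = next initial
contact) together with the across-stride mean curve and mean phase-onset
fractions.

## The simulator

No recordings of this sensor pair are public, so the package generates its
own, with ground truth. Design choices:

- **Kinematics** are cyclic piecewise-linear templates in stride fraction,
  built so that each segmentation rule's crossing falls exactly at the
  configured phase fraction (defaults: mid stance 0.10, terminal stance
  0.30, pre-swing 0.50, initial swing 0.60, mid swing 0.73, terminal swing
  0.87 — a standard ~60% stance cycle). A half-stride lead-in precedes the
  first contact so the first stride is complete.
- **Grip forces** are a shared stride-periodic load curve (Gaussian loading
  bump peaking mid-stance, 8–12% residual grip during swing so the CoM
  variables stay defined) distributed over the sensors with fixed
  per-channel weights. Fixed weights make every CoM variable constant by
  construction, so planted extrema are the only deterministic CoM structure
  and their ground-truth times are exact.
- **Planted events** are Gaussian force bumps (σ = 4% of the cycle) added to
  a variable-specific sensor subset — top sensors to raise CoMZ, high-x
  sensors to raise CoMX, and so on; minima load the opposing subset, and
  mean-pressure minima are multiplicative unloading dips so forces stay
  non-negative. Events in a derivative variable are planted as steep pulse
  edges in the parent variable. A planted bump riding on the sloping load
  curve has its extremum displaced by ≈ σ²·L′/L — about 8 ms at the default
  settings — which is the dominant bias in end-to-end timing checks.
- **Cane inclination** is stride-periodic with a slow sinusoidal amplitude
  envelope (period 13.7 s, incommensurate with the stride), emulating
  stride-to-stride variability. Without the envelope the inter-stream lag
  would only be identifiable modulo one stride period; with it, correlation
  has a unique global peak over the ±5 s search window. Under heavy noise
  an individual recording can still alias by one period, which is why lag
  accuracy is stated as a median over recordings.
- **Noise** defaults are modest and realistic for conditioned FSRs and an
  inertial reference: additive Gaussian noise of 0.02 sensor units on
  forces (~2% of the loading peak), 0.01 m/s on foot speeds (angles ×10,
  distances ×0.1 of that), 0.1° on the cane angles. One seeded generator
  drives all randomness; identical configs are bitwise-reproducible.
- A `corrupt` helper zeroes a fraction of samples and injects spikes for
  robustness checks, leaving ground truth untouched.

What the simulator does *not* emulate: FSR nonlinearity, hysteresis and
drift; inter-subject variability in grip style and cane timing; clock drift
between the streams; treadmill-speed fluctuations; genuinely pathological
gait. Passing tests therefore demonstrate that the pipeline recovers what
the model family plants under realistic noise — not that any particular
human will show a given event, which the large inter-subject variability of
cane grip makes an explicitly per-user question.

## Numerical choices and degenerate inputs

- Zero total force ⇒ CoM masked invalid; masked samples never become event
  candidates.
- Constant signals are rejected by normalization (no unit range); signals
  with fewer than two qualifying peaks are rejected by trimming.
- Correlation ties are broken toward the smallest |lag|; reported peak
  correlation is clipped at 1.
- The consistency filter is exact at its boundary: 25 of 30 is retained,
  24 is not; both counts are configurable for shorter recordings.
- Problem sizes used by the test suite and the acceptance script — 12–40
  stride recordings, 10–20 random seeds per property — were chosen so each
  statistical check is stable seed-to-seed while the whole suite stays
  interactive.

## Known limitations

- The segmentation branch logic is a reconstruction (see above); against
  real motion-capture data its thresholds would need per-setup tuning.
- Event offsets inherit the planted-bump bias described above (≈ 8 ms at
  defaults) when the underlying variable rides on a sloping baseline.
- One global lag assumes drift-free clocks over the recording.
- The event consolidation treats phases independently; an extremum drifting
  across two adjacent onsets between strides (a known inter-subject effect)
  splits into two groups that can both fall under the consistency threshold.
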