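# canegait

Gait-event detection from the grip of an instrumented cane.

People who walk with a one-sided impairment and a contralateral cane move the
cane in synchrony with the impaired leg. If the cane handle carries an array
of force-sensing resistors (FSRs), the way the hand loads the handle over the
gait cycle becomes a signal: its per-stride maxima and minima recur at fixed
points of the cycle and often *precede* the onsets of the gait phases. Such
anticipating events are valuable for controlling prostheses, exoskeletons and
functional electrical stimulation, whose actuators need tens of milliseconds
of advance notice — and the cane carries the sensors, not the user's body.

`canegait` implements the full analysis for a 16-sensor handle (10 sensors on
the top side under the palm, 6 on the bottom side under the fingers) scanned
at 50 Hz, against a faster motion-capture reference stream used for gait
segmentation. It is a library first; a thin `canegait` CLI wraps the same
calls, and `examples/` holds one short script per capability.

## The variables and the method

Given sensor outputs `f(i)` at coordinates `(x(i), z(i))` (mm, handle-local
sagittal frame, z along the shaft), six per-sample grip variables are
computed, plus their time derivatives (`d` prefix):

    CoMXUp   = Σ_top f(i)·x(i) / Σ_top f(i)        top-side grip centre, x
    CoMXDown = Σ_bot f(i)·x(i) / Σ_bot f(i)        bottom-side grip centre, x
    CoMX     = Σ_all f(i)·x(i) / Σ_all f(i)        overall grip centre, x
    CoMZ     = Σ_all f(i)·z(i) / Σ_all f(i)        overall grip centre, z
    MPUp     = Σ_top f(i) / 10                     top-side mean pressure
    MPDown   = Σ_bot f(i) / 6                      bottom-side mean pressure

The pipeline then:

1. **synchronizes** the two acquisition streams on the cane-inclination
   signal both of them observe (normalize to [0, 1], trim to first/last
   swing peak, upsample the 50 Hz stream, maximize Pearson correlation over
   shifts; one global lag);
2. **smooths** the 12 signals with a 3rd-order Savitzky–Golay filter and
   differentiates after smoothing;
3. **segments** the reference kinematics into seven phase onsets per stride
   (initial contact merged with loading response; thresholds: stance
   < 0.4 m/s, swing > 0.8 m/s, toe-down angle −9°, feet-adjacent minimum
   < 0.4 m, tibia vertical at 90°);
4. selects the **30 central strides**, detects per-stride extrema of every
   signal, references each to the nearest phase onset (signed offset,
   negative = anticipates), and keeps only events present in **≥ 25 of 30
   strides**. `terminal_stance` is segmented but not used as a reference by
   default — it sits too close to pre-swing to resolve events between them.

No public recordings of this sensor pair exist, so the package bundles a
ground-truthed simulator (`canegait.simulate`) that emits both streams with
configurable phase fractions, an injected inter-stream lag, plantable
extrema at chosen cycle fractions, and per-stream noise. Every stage is
tested against the simulator's ground truth.

## Worked example

`python examples/04_detect_events.py` plants a CoMZ maximum 55 ms before
every pre-swing onset (10 ms stride-to-stride jitter) on a noisy recording
whose cane clock lags the reference by 0.3 s, then runs the whole pipeline:

```
recovered lag 0.2999 s; 30 central strides analyzed; 82 stride-consistent events

planted event: CoMZ max referenced to pre_swing
  detected in 30/30 strides
  median offset -47.4 ms (planted -55 ms), IQR 13.5 ms
```

The lag is recovered to a tenth of a millisecond; the planted grip maximum
is found in every analyzed stride and reported with a negative offset — it
anticipates pre-swing, which is exactly what makes it usable as a
pre-trigger. (The ~8 ms bias toward zero is the known interaction between a
planted bump and the sloping stride-periodic grip load; see
`docs/methods.md`.) The other reported events are genuine recurring extrema
of the simulated grip pattern and of the noise floor binned to their nearest
onsets.

The same run from the shell:

```
canegait run --seed 1 --lag 0.3 --out-dir out/
```

writes `report.json`, `events.tsv` and `timeline.csv`.

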