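# Methods

This note documents the models and procedures implemented in `emgait`,
their assumptions, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open.

## 1. Synthetic gait sessions (`emgait.simulate`)

The generator replaces private recordings of healthy adults walking in a
lower-limb exoskeleton, overground (WO) and on a treadmill (WT).  It is a
*stated world*: its defaults encode the protocol the pipeline assumes, and
tests are run against the truth it emits.

**Kinematic templates.**  Each gait cycle (nominal duration 1.2 s, the
exoskeleton's programmed step time; stance fraction 0.60) is built from a
shape-preserving cubic (PCHIP) template through anchor points, sampled on
the 100 Hz inertial-sensor grid:

* hip angle (HA, degrees, flexion positive, default range of motion 40°):
  loading-response rebound at 12% of the cycle, extension trough at 50%,
  flexion maximum at 90%, and a local minimum at the heel strike itself.
  The heel-strike minimum is placed *below* the cycle mean so the
  high-pass/rectify detector (below) sees it as the first local maximum of
  its processed trace, ahead of the deeper extension trough.
* knee angle (KA): small flexion at contact, a ~20° stance flexion
  wavelet, a pre-swing minimum, **exactly** 60% of the swing peak at the
  toe-off instant, and the swing peak (default 65°, hence 39° at toe off)
  at 75% of the cycle.  PCHIP interpolation is monotone between anchors,
  so the 60% value is crossed exactly once per cycle on the rising limb.

Walking bouts begin with a partial lead-in cycle starting at the toe-off
phase (0.60) — which both guarantees the first heel strike is preceded by
a hip flexion maximum and keeps nominal anchors on the 100 Hz grid — and
end truncated at phase 0.88 of the final cycle so no spurious extra heel
strike is generated.  Quiet standing (WO only) renders near-constant
angles with ~0.3 s posture-transition ramps.  Cycle durations are jittered
multiplicatively with a configurable coefficient of variation (default
0.02 in the study configuration: exoskeleton-driven gait is highly
regular).  Angle noise defaults to 0.5° (typical inertial angle
estimation error).

**EMG synthesis.**  Each channel is the standard surrogate-EMG
construction: zero-mean Gaussian carrier noise, band-limited to the
30–400 Hz conditioning passband, amplitude-modulated by a per-muscle
activation envelope.  Envelopes are sums of per-cycle Gaussian bursts at
physiologic phases — tibialis anterior around contact and through swing,
vastus lateralis in early stance, soleus in late stance, biceps femoris at
contact and in late swing — each shifted **earlier** than its kinematic
anchor by the activation lead (default 120 ms, the electromechanical
anticipation of muscle drive over limb motion).  A baseline noise floor
(default 0.05 of the unit burst amplitude) persists through standing.

**MVIC trials.**  Three 5 s maximal-contraction trials per muscle: the
dynamometer force (75 Hz) ramps smoothly from 0.5 s to a plateau reached
by second 3, so the average force over the 4th second equals the plateau;
the single-channel EMG envelope tracks the normalized force.

**What the generator does not emulate** — and hence what a green test does
not establish: inter-subject anatomical variability, electrode-lift and
motion artefacts, EMG signal-quality differences between subjects,
non-stationary fatigue effects, and pathological gait.  Synthetic
envelopes are far cleaner than human sEMG; end-to-end accuracies on this
world characterize pipeline consistency, not clinical performance.

## 2. Activity segmentation and event detection (`emgait.labeling`)

**Walking/standing HMM.**  The hip angle is low-passed at 10 Hz
(zero-phase) and converted to an activity proxy: the magnitude of its
first difference in deg/s, averaged over a sliding window of one nominal
cycle (1.2 s).  Shorter windows were tried and rejected: |dHA/dt| dips at
every angle extremum, and sub-cycle windows let expectation–maximization
split walking itself into two states.  The proxy is binned into 8
equal-width symbols between zero and its 95th percentile (gait saturates
the top symbol; quiescence sits at the bottom; quantile binning was
rejected because on a mostly-walking session it devotes nearly the whole
alphabet to within-walking variation).  A 2-state categorical HMM with
fixed sticky transitions (self-transition 0.99) and deterministic
low-symbol/high-symbol emission initialization is fitted by EM (emissions
and start probabilities only) and decoded by the most likely path; the
state with the larger mean emission symbol is walking.  A trace whose
proxy never exceeds 5 deg/s cannot contain gait and is returned as all
standing without fitting.  Measured on simulated sessions with a standing
interlude: ≈99% per-sample agreement, bout boundaries within ≈0.25 s.

**Heel strike.**  Within each window from a cycle's dominant hip-flexion
maximum (peak prominence ≥ half the best prominence, extrema separated by
≥0.25 s) to the deepest following minimum, the hip trace is high-pass
filtered (2nd-order Butterworth, 0.5 Hz, zero-phase — phase handling is
unstated in the source procedure; zero-phase mirrors the EMG convention),
its positive part set to zero and the remainder rectified; the first local
maximum of that processed trace is the heel strike.

**Toe off.**  For each dominant knee swing peak, the window from the
deepest preceding local minimum (the nearest-minimum variant mislocks onto
noise wiggles on the rising limb) to the peak is searched for the first
crossing of 0.60 × peak; the crossing is located by linear interpolation
and reported at the nearer sample.  A peak with no preceding minimum (the
lead-in of a bout) is skipped with a logged warning.

**Label track.**  Stance = [heel strike, toe off), swing = [toe off, next
heel strike), half-open at 0-based sample indices.  Standing samples, one
full stride on each side of every standing bout (the source procedure
does not quantify "strides immediately before and after"; one per side is
implemented), and samples outside complete strides are excluded (−1).
Exactly one toe off must fall between consecutive heel strikes of a bout;
violations raise an error naming the offending pair.

## 3. EMG conditioning (`emgait.preprocess`)

Per channel: mean removal; 4th-order Butterworth band-pass 30–400 Hz
applied forward and backward (zero net phase; coefficients designed at the
stated order, the squared magnitude response accepted); envelope =
full-wave rectification + zero-phase 4th-order 5 Hz low-pass, clipped at
zero (negative filter ripple is unphysical for an envelope); normalization
by the MVIC reference; decimation by keeping every 3rd sample (phase 0
retained; the 5 Hz envelope filter has already removed anything that could
alias).  Zero-phase filtering uses reflective padding of up to 1 s.  The
MVIC reference is the mean envelope over a 250 ms window centered on the
global envelope peak (window clipped at trial edges) of the trial with the
largest average expressed force; force traces are resampled to 1500 Hz by
linear interpolation before averaging over the [3 s, 4 s) window.  The
envelope-peak search uses the global peak; onset transients are not
excluded (unstated in the source procedure).

## 4. Dataset construction (`emgait.dataset`)

Labels at 100 Hz are mapped to the EMG grid by nearest-sample assignment
(midpoint ties to the earlier sample).  Windows are 500 samples with
per-sample label vectors (sequence-to-sequence; a window never carries a
majority-vote label), cut inside contiguous non-excluded segments only —
windows straddling an exclusion are dropped rather than re-anchored.
Training windows overlap 50%; test windows do not.  Training windows whose
swing share exceeds 70% are duplicated once (duplication factor 1; the
source procedure says "replicating" without a factor).  Splits are
cross-subject; validation is a seeded 20% sample at the *sequence* level
within training subjects (the alternative, a time-level 20%, is equally
consistent with the source's wording); treadmill windows are test-only.

## 5. Classifier (`emgait.model`)

Implemented directly on numpy (float32): the environment provides no deep
learning framework, and the stack is the package's core contribution.
Standard LSTM cell (gates i, f, g, o; forget bias initialized to 1;
Glorot-uniform weights), bidirectional by running a second cell on the
reversed sequence and concatenating; every layer preserves the time
dimension; time-distributed dense layers use ReLU (activation unstated in
the source; ReLU is the field default), the output layer a per-timestep
softmax.  Inverted dropout (default 0.60) follows every bidirectional and
hidden dense layer during training only; inference is deterministic, and
exact probability ties resolve to stance.  Training minimizes mean
per-timestep cross-entropy with Adam (learning rate 1e−3, batch 64 —
field defaults, unstated in the source), early-stops on validation loss
(patience 5) and restores the best-validation weights.  Gradients are
exact backpropagation through time, verified against central finite
differences in float64 (worst relative error ~1e−5).

The closed-form parameter count is `8u(d+u+1)` per bidirectional layer
and `(d+1)m` per dense layer.  The printed reference totals (324,800 for
the first layer; 1,233,677 overall) are mutually consistent only with a
per-timestep input dimension of 2, although four muscles are recorded;
the discrepancy is preserved rather than resolved: `ModelConfig()`
defaults to `input_dim=4` (1,236,877 parameters) and
`ModelConfig.reference_counts()` reproduces the printed counts with
`input_dim=2`.

Partial retraining (the 1500 Hz adaptation experiment) continues Adam on
a seeded 30% subset of the 1500 Hz training windows, all weights free.

## 6. Evaluation (`emgait.evaluate`)

Metrics are pooled per-sample over all test timesteps (per-acquisition
averaging is available for the per-subject table, which takes the
unweighted mean over acquisitions per subject and scenario).  ROC uses
stance as the positive class, the threshold set of unique scores, and
trapezoid-rule AUC.  The streaming harness consumes consecutive
non-overlapping windows of raw 1500 Hz EMG — 1 s per window on the 500 Hz
path, 0.333 s on the 1500 Hz path — runs the full conditioning chain plus
prediction per window, and reports median wall-clock preprocessing and
classification times from a monotonic clock.  Timings are informational
only: they are hardware-dependent and never asserted.

## 7. Desk-scale study (`emgait.study`)

14 synthetic subjects (12 train / 2 test), 26-step overground sessions
with a 6 s standing interlude after step 13, 16-step treadmill sessions
for test subjects only, reduced layer widths (bidirectional 32/16, dense
32/16, dropout 0.30 — lighter regularization matching the reduced
capacity), 8 training epochs, 3 retraining epochs.  Every stage runs the
real pipeline: MVIC simulation → conditioning → HMM + event detection →
windowing → training → the three test configurations (500 Hz; 1500 Hz
windows with the same weights; 1500 Hz after partial retraining).  The
whole study completes in about a minute on one CPU.

## Known limitations

* Zero-phase (non-causal) filters are replayed per window by the
  streaming harness; a truly causal online variant would incur delay and
  is out of scope.
* The HMM alphabet and window were tuned for robustness on gait-scale
  motion; very slow shuffling gaits near the 5 deg/s floor would be
  classified as standing.
* Sub-phase detection (loading response, mid-stance, …) is not attempted.
* float32 arithmetic makes training bit-reproducible for a fixed seed on
  a given BLAS, but not across differing BLAS builds.
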