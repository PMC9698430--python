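# Methods

## Problem and system

`locomode` classifies lower-limb locomotion from one or two inertial
measurement units (IMUs), each a triaxial accelerometer plus a triaxial
gyroscope (6 or 12 channels).  Three label families are predicted jointly:

* **Locomotion modes** (7): sitting (S), standing (ST), level-ground
  walking (W), ramp ascent/descent (RA/RD), stair ascent/descent (SA/SD).
* **Transitions**: ordered mode pairs such as `W-ST`.  The allowed set is a
  property of the recording protocol, so it is part of the label schema
  (12 transitions in the healthy-subject-style schema, 19 in the
  amputee-style schema).
* **Gait phases** (27): walking has 7 sub-phases of the gait cycle, each
  ramp/stair mode has 5.  Static modes (S, ST) have none.

The classifier is hierarchical.  Level 1 (one network) assigns one of the
seven modes, treating a transition window as its *starting* mode.  Its
argmax routes the window to level 2A — one network per mode, separating the
steady mode `m-m` from the transitions `m-m'` departing from it — and to
level 2B — one network per non-static mode, classifying the gait phase.
2A and 2B are independent; neither is gated on the other.  The outputs
compose into labels such as `W to ST-W6`.  A level-1 misroute propagates:
the wrong sub-models label the window, and the end-to-end evaluation counts
it wrong.

## Windowing and labels

The per-sample mode track is enriched with transitions first: a 500 ms
window centered at each mode-change point is relabeled `m-m'`.  Sequences
of 1.3 s are then cut with a 50 ms stride (650 samples at 500 Hz, 1300 at
1000 Hz) and each window's label is resolved by three rules: (i) uniform
windows keep their label; (ii) a window spanning mode-then-transition takes
the majority label, with the >= 50% tie going to the transition (the rarer
class); (iii) a window spanning transition-then-mode takes the *mode* — the
informative part of a transition is its onset, and labeling the tail as the
new mode keeps it out of the transition classes.  Windows spanning three or
more label runs (not covered by the three rules) fall back to the global
per-sample majority with the same transition-favoring tie-break; remaining
ties go to the label whose last occurrence is latest, consistent with the
"later transition wins" rule used when two transition windows overlap.

A window's gait phase comes from the per-sample phase track, computed on
the pre-transition-marking labels and restricted to samples of the window's
level-1 mode, so a `W-ST` transition window keeps a walking phase.  A 1.3 s
window spans about one full gait cycle, so no single-phase ground truth
exists and a window-to-phase reduction must be chosen.  The default is the
*current* phase — the phase of the window's last phased sample, i.e. the
phase in effect when the classification becomes available, which is what a
prosthesis controller consumes.  A majority reduction (most frequent phase
in the window) is also provided; note it degenerates when the cycle length
approaches the window length, because then every phase covers a near-equal
share of the window and the majority hinges on a few samples.  Windows
containing no phased samples stay unphased and are excluded from level-2B
training; at evaluation time an unphased truth constrains only the
activity.

## Frequency encoding

Each channel becomes a 10 x 50 image: a short-time Fourier transform with a
periodic Hann window of 20 samples and hop 13, squared to power, projected
onto 10 triangular filters equally spaced on the mel axis
(`m(f) = 2595 log10(1 + f/700)`) between 0 Hz and Nyquist, converted to dB
(floor 1e-10) and min-max normalized per image into [0, 1].  The mel
warping expands the band below a few Hz where locomotion energy lives
(dominant content below 3.5 Hz); 10 bands is as fine as a 20-point FFT at
500 Hz allows without producing empty bands, and the filterbank constructor
rejects configurations that would.

Framing is non-centered, giving `1 + floor((650 - 20) / 13) = 49` frames; a
fixed fit-to-width step repeats the final frame once (or crops) to enforce
the 10 x 50 network contract, since neither standard framing convention
lands on 50 exactly (non-centered gives 49, center-padded 51).  Streams
sampled at 1000 Hz are anti-alias filtered and decimated to 500 Hz before
encoding so every network sees one input geometry.  Per-image (rather than
dataset-level) min-max normalization needs no global statistics and makes
the encoding invariant to overall signal amplitude; the amplitude
information that survives is the *relative* time-frequency pattern, which
is what distinguishes the modes.  A zero-dynamic-range image maps to all
0.5 by convention.

## Networks and training

Three architectures share a convolutional trunk on the (channels, 10, 50)
stack — 5 x 5 kernels, 64 then 128 filters ("same" padding), each followed
by 2 x 2 max pooling:

* **CNN**: dropout 0.25, dense 512, dense 256, softmax.
* **CNN-GRU / CNN-LSTM**: the pooled frame axis (50 -> 25 -> 12) becomes
  the recurrent time axis with `filters x pooled-rows` features per step,
  then two recurrent layers (120, 60 units), dense 30, dropout 0.25,
  softmax.  Pooling in the recurrent variants is this package's reading:
  without it the recurrent input would be 50 steps of 1280 features,
  out of proportion to the small recurrent sizes.

Grid-search "hidden profiles" like `[32, 64, 60, 30, 15]` map onto (conv1,
conv2, rnn1, rnn2, dense).  The networks are implemented in numpy
(float32): im2col convolutions, backpropagation through time, Glorot
initialization from a seeded generator.  Two numerical choices that matter:
the mel images are centered from [0, 1] to [-1, 1] by a fixed affine input
layer (all-positive inputs slow early convolution training markedly), and
gradients are clipped to a global L2 norm of 5.0 (the standard recurrent
stabilizer; configurable, 0 disables).

Training minimizes class-weighted categorical cross-entropy — balanced
inverse-frequency weights `w_c = N / (K n_c)` compensate the rarity of
transition windows — with Adam (default) or RMSProp at a baseline learning
rate of 1e-4, batch size 64, up to 400 epochs with early stopping: training
ends when the validation loss has not improved by at least 0.001 for 10
epochs, and the best-validation weights are restored (weights track the raw
best epoch; the patience counter only resets on >= 0.001 improvements).
Data partitioning is 80/20 train/validation with a further 20% of the
training portion held out as an untouched inner test set, all stratified by
activity label; classes with fewer than 3 windows cannot be stratified and
stay in the training split with a warning.  The hyperparameter grid spans
3 activations x 2 learning rates x 2 optimizers x 2 profiles x
2 dropouts = 48 points, scored by stratified k-fold CV accuracy.

Argmax ties (routing and prediction) break to the earliest class in the
fixed class order: steady label first, then that mode's transitions in
schema declaration order.

## Evaluation

The F1-score per class uses one-vs-rest counts under the *joint*
correctness rule: a composite prediction is correct only if both the
activity and the phase are right (vacuously right when the truth is
unphased).  Macro (unweighted) averaging is used throughout — with
transition classes an order of magnitude rarer than steady ones, a
weighted mean would hide exactly the failures that matter.  Two macro
aggregations are reported.  ``mean_f1`` averages over the composite
classes, i.e. every distinct activity-phase rendering; it is the strictest
view, but each transition type splits across 5-7 phases, so on held-out
sets of a few thousand windows most transition-phase composites have
support 1-2 and the average is dominated by singleton classes that a
single ambiguous boundary window can zero.  ``mean_f1_levels`` averages
over the activity classes plus the gait-phase classes — the units
per-class confusion matrices are built from — with every window still
scored by the joint rule; supports are one order of magnitude larger and
the number is stable, so it is the headline score and the one the
end-to-end check asserts.  Architecture comparisons use a two-sided paired
t-test on per-seed/per-subject score pairs; zero-variance differences use
documented conventions (identical lists: t = 0, p = 1; constant nonzero
difference: t = +-inf, p = 0).

## The synthetic gait simulator

The simulator generates labeled streams with the statistical structure the
pipeline assumes about real lower-limb IMU data, so every stage is testable
without external recordings.  Per mode, each channel is a sum of the first
three harmonics of the mode's gait-cycle frequency (walking 1.0 Hz, ramps
0.8/0.9 Hz, stairs 0.8/0.9 Hz — keeping 3 x f0 at or below 3.5 Hz), a
constant gravity projection encoding segment orientation (sitting vs
standing differ mainly here), Gaussian sensor noise (sd = 8% of each
channel's oscillation amplitude; the `noise_scale` knob multiplies it), and
short Gaussian-windowed bursts (~26 Hz at heel strike, ~16 Hz at toe-off)
mimicking foot-impact transients.  The bursts are what makes the position
within the gait cycle visible to a spectrogram classifier, as impact
transients do in real accelerometry.  A property test verifies that >= 90%
of each non-static channel's non-DC power lies below 3.5 Hz.

Mode changes are linear parameter cross-fades over 0.5 s centered at each
segment boundary, giving transition windows transition-specific structure
rather than discontinuities.  Heel strikes sit at cycle starts and toe-offs
at 60% of the cycle (the standard stance/swing split).  Gait phases divide
each complete stride into equal-duration stance sub-phases (walking 4,
others 3) and swing sub-phases (walking 3, others 2); the true event-based
phase boundaries of clinical gait analysis are not reproduced — the
convention object makes the subdivision swappable.  The partial stride at
the end of a bout is phased by carrying the previous stride's duration
forward (the estimate an online phase tracker would make); samples before
a bout's first heel strike stay unphased.

Dataset generation walks the schema's transition graph favoring the
least-used edge, so every allowed transition appears at least `min_count`
times, with segment durations of ~4 s jittered +-15%.

**What the simulator does not emulate:** inter-subject variability,
within-mode speed changes, soft-tissue artifacts and sensor drift,
asymmetric or pathological gait, and the continuous within-cycle waveform
changes of real locomotion (between bursts each mode is a stationary
harmonic process).  Passing the end-to-end test therefore shows that the
pipeline's machinery — labeling, encoding, routing, weighted training,
composite scoring — is correct and that the networks can learn separable
quasi-periodic classes; it does not certify performance on real recordings.

## Problem sizes in the checked end-to-end run

The end-to-end check trains the CNN-LSTM multi-level system (the
`[32, 64, 60, 30, 15]` profile with ELU — the smaller of the two
grid-search profiles, and the activation that trains reliably at every
network size) on ~6 minutes of synthetic 2-IMU data (~3 s segments, every
transition at least 5 times), learning rate 1e-3, batch 64; the level-1
net runs at most 12 epochs (it converges within ~10), the
mode/transition nets at most 20, and the gait-phase nets — whose loss
plateaus before dropping — at most 24 with patience 10.  Evaluation is on
a *freshly generated* held-out set (different scenario seeds), the
sternest test of generalization, and the check asserts a level-wise macro
F1 of at least 0.90 — the strictest surface in the suite, and one that
desk-scale training does not always clear (the transition classes are the
usual bottleneck; see the limitations below).  These sizes are the
package's chosen desk-scale defaults: large enough that all 12
transitions and 27 phases are exercised with usable support, small enough
to run on one CPU core in minutes.  The CNN and CNN-GRU variants are
trained briefly on the same data to verify the shared machinery.

## Known limitations

* Window-level transition labels are intrinsically near-ambiguous: the
  500 ms transition zone covers at most 250 of a 1.3 s window's 650
  samples, so the ">= 50% majority" scenario can never fire and only the
  plurality generalization produces transition windows — about three
  stride positions per transition occurrence, each differing from its
  mode-labeled neighbors by a single 50 ms stride.  On the simulator,
  whose cross-fades are exactly as wide as the labeled zone, transition
  classes are therefore the ceiling on any end-to-end macro average;
  real locomotion carries broader anticipatory signatures (deceleration,
  stride adjustment) that soften but do not remove this ambiguity.
* The numpy networks are CPU-bound and an order of magnitude slower than a
  GPU framework; the package targets correctness and desk-scale
  experiments, not production training throughput.
* Level-2B windows of a transition inherit the starting mode's phase track;
  windows without complete strides nearby stay unphased and unscored on the
  phase axis.
* The STFT fit-to-width step duplicates one frame (49 -> 50); the duplicated
  frame carries no independent information.
* `paired_t_test` assumes paired scores from identical conditions; it does
  not correct for multiple comparisons.
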