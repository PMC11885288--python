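# Methods

## Scope and model

`scalebp` implements a pulse-transit-time (PTT) pipeline for cuffless blood
pressure from a weight-fat scale.  The proximal timing reference is the
ballistocardiogram J wave; the distal reference is the impedance
plethysmogram of the lower limbs (foot for PTT1, derivative peak for PTT2).
A conventional ECG + finger-PPG chain provides the reference arrival times
(PAT1/PAT2) used only to label beat quality.  Blood-pressure estimation
itself is a supervised regression from segment-level PTT/HR features to
cuff-referenced SBP/DBP; no physical BP model is inverted.  The underlying
physiological premise is the inverse, approximately linear relation between
PTT and arterial pressure over the post-exercise range covered here.

## Session simulator

Real recordings of this kind are IRB-restricted, so the simulator defines
the study conditions and supplies exact per-beat ground truth.

**Trajectories.**  A session is `rest_duration_s` (default 60 s) of standing
rest at resting BP, followed by a post-exercise recovery in which SBP and
DBP decay exponentially from peak to rest with time constant
`decay_tau_s = 120 s`.  Defaults: SBP 139 → 113 mmHg, DBP 74 → 69 mmHg,
heart rate 100 → 70 bpm — the printed post-exercise operating range.  Per
beat, `PTT2 = a − b·SBP` with `(a, b) = (495.23 ms, 1.4615 ms/mmHg)`, the
unique line through the two printed operating points (SBP 139 → PTT2
292 ms, SBP 113 → 330 ms); `PAT2 = PTT2 − 62 ms` (constant device offset);
PAT1/PTT1 trail PAT2/PTT2 by the 80 ms foot-to-derivative-peak lag.

**Morphologies** are analytic stand-ins that pin the landmarks, not
hemodynamic models:

* ECG: Gaussian R spike (σ = 10 ms) with small P/T bumps;
* BCG: damped sinusoid (4.5 Hz, τ = 150 ms) entered through a smooth
  half-period amplitude ramp so the complex starts with the negative I
  lobe; the J-wave offset from complex onset is located numerically on a
  10 µs grid and the complex is placed so the true J lands at R + 150 ms.
  The smooth lead-in matters: an abrupt onset leaves out-of-band energy
  that zero-phase filtering smears, displacing the detected J by ~6 ms;
* PPG/IPG: raised-cosine upstroke from foot to peak over 160 ms, half-cosine
  decay to the next foot.  The upstroke's derivative peaks exactly halfway
  up, so the derivative-peak lag after the foot is 80 ms by construction,
  and the foot is a smooth minimum whose derivative crosses zero
  transversally — the zero-crossing detector's operating assumption.

Additive white Gaussian noise (default SD 0.02 in normalized units) is
applied per channel.  "Clean condition" in the tests means SD 0.005, chosen
as the regime where the sensor noise, after band-pass filtering, is small
against the pulse upstroke slope.

**Artifacts** emulate a mistimed IPG pulse foot: the samples around one
beat's pulse are resampled through a piecewise-linear time warp that
translates the foot-to-peak stretch by `shift_ms` while staying continuous
at the window edges.  The measured DIPG peak moves by exactly the shift;
the measured foot moves by the shift to within the filter-induced
systematic shared by all beats.  Artifacts are injected only after the rest
phase (motion artifacts while standing post-exercise), keeping the
rest-phase bias calibration well defined.  The default shift, 120 ms,
exceeds 0.4·PAT2 for every beat of the default trajectory, so artifact
beats violate the 30 % quality rule unambiguously.

**Cohort feature simulator.**  Regression experiments need cohort-scale
feature tables; synthesizing waveforms for thousands of segments buys
nothing for that layer, so `simulate_cohort_features` samples the same
BP/PTT coupling at trajectory level: per subject it draws resting/peak
pressures (SBP_rest ~ N(113, 8), DBP_rest ~ N(69, 5), independent draws), a
coupling intercept perturbed by N(0, 10 ms) (anatomy and electrode
placement shift absolute transit times between subjects — this is what
makes resting-BP calibration informative), per-segment beat-timing noise of
2 ms averaged over 3 beats, and cuff-measurement noise of 2 mmHg on the BP
targets (oscillometric reference accuracy).  Because the subject pressures
are drawn independently, diastolic pressure is only indirectly inferable
from the SBP-coupled transit times; DBP correlations are accordingly lower
than SBP ones, a deliberately conservative setting.

**What the simulator does not capture:** real BCG/IPG morphology and its
beat-to-beat variability, EMG interference, respiration, baseline drift
beyond what the band-pass removes, and subject-specific nonlinearity of the
PTT-BP relation.  Passing recovery tests therefore demonstrates that the
pipeline's detectors and estimators are correct against their own
contracts, not that they would achieve the same figures on scale data.

## Signal processing

All channels pass a 4th-order Butterworth band-pass, 0.5–10 Hz at 500 Hz.
The filter is applied forward–backward (`sosfiltfilt`), which cancels the
phase response exactly; this replaces a dedicated all-pass group-delay
equalizer, is exact for offline processing, and is the package's chosen
delay-equalization strategy (a user-supplied band/order can be passed
through every API).  DPPG/DIPG are central differences scaled to units/s,
computed after filtering so broadband noise is not amplified.
Normalization is `(x − mean)/s` with population SD; zero-spread segments
raise a dedicated error and are discarded upstream.

## Fiducial detection

R waves: Pan-Tompkins (derivative → squaring → 150 ms moving-window
integral → adaptive signal/noise thresholds, 250 ms refractory), refined to
the ECG maximum within ±60 ms.  J wave: earliest strict local maximum of
BCG in (R, R + 400 ms] whose amplitude reaches 30 % of the window maximum.
Feet: first negative-to-positive zero crossing of the derivative channel
after R, interpolated linearly between the bracketing samples.  Derivative
peaks: earliest qualifying local maximum after the foot (amplitude ≥ 50 %
of the segment maximum).  Peak positions are refined to sub-sample
precision by a three-point parabola; without this, sample quantization at
500 Hz alone consumes most of the 2 ms recovery budget.

The relative-amplitude guards are a deliberate addition to the bare
"first peak" rule: sample-level noise ripples otherwise pre-empt the
physiologic peak arbitrarily close after R or the foot.  Among qualifying
candidates the earliest is always returned, preserving the first-peak
semantics.  Missing landmarks are recorded (`status` column), never raised;
beats with incomplete fiducial sets are excluded from timing analysis.

Known systematic: the 0.5 Hz high-pass reshapes the pulse train's
low-frequency content and shifts detected feet ~11 ms early — identically
for every beat, so PTT1/PAT1 carry a constant offset that cancels in
within-session variation and in the bias-calibrated quality rule.  PTT2 and
PAT2, measured at derivative peaks, recover ground truth to < 1 ms
noiseless and within 2 ms for ≥ 99 % of beats in the clean condition.

## Quality labeling

`E = (PAT2 − PTT2 + bias)/PAT2 × 100 %`, with `bias` the mean PTT2 − PAT2
delay over the first five complete rest-phase beats.  The sign convention
makes E vanish at rest; the label rule uses |E| > 30 % (strict), since a
mistimed foot can push E in either direction.  Both the magnitude
convention and the choice of the first five rest beats are configurable;
they are the package's resolutions of genuinely open conventions.

Per-beat reference BP is linear interpolation of the per-minute cuff rows,
clamped outside the covered span.  Interpolation is meaningful within the
smooth recovery decay; across the rest-to-exercise boundary the bracketing
readings straddle the unrecorded treadmill period, and per-beat BP there
inherits that ambiguity (a protocol property, visible in the simulator as a
step at the phase change).

## Segmentation

1024-sample windows, 512-sample hop, trailing partial window dropped.  A
beat belongs to a window iff its R wave falls inside it (R anchors every
other landmark).  Windows need ≥ 2 member beats (a ~2 s window must hold at
least two PTT measurements); windows with any unlabeled member beat or
mixed labels are deleted; kept windows are z-normalized per channel.
Dataset splitting is seeded-random with floor-based sizes, remainder to the
last partition (22,620 at 70:30 → 15,834/6,786; 2,262 at 80:20 →
1,809/453), with optional stratification.

## Quality classifier

The stacked model splits a 1024×3 segment into two 512-sample sub-windows
sharing one conv stack (32 filters; kernels 3, 5, 13 for layers 1–3; stride
2; ReLU; "same" padding; 2× max pool; flatten → 1024 features per step),
runs the 2-step sequence through a single-layer GRU (1024 units), and
closes with dropout 0.5 and dense 1024–256–1 with sigmoid.  Binary
cross-entropy, Adam at 1e-4, batch 512, output threshold 0.5 with ≥ as the
tie direction.  Dropout is applied between the GRU and the first dense
layer only.

The implementation is pure NumPy with hand-derived backpropagation
(im2col convolutions, BPTT through the 2-step GRU); every gradient is
validated against central finite differences in the test suite, in float64
on a width-reduced configuration.  Desk-scale experiments (tests, the
acceptance script) use the same topology at reduced width — GRU 256, dense
256–64–1, batch 64, learning rate 1e-3, ≤ 10 epochs on 2,000 segments —
sized so a full training run takes well under a minute on one CPU while
leaving the full-scale configuration as the default.  The synthetic
clean-vs-corrupted classes are separable by construction, and the
classifier reaches validation accuracy ≥ 0.95 within 10 epochs.

## BP regression

Random forest: 300 trees, `min_samples_leaf=4`, `min_samples_split=2` (the
standard parameters matching "minimum number of leaves/splits").  XGBoost:
300 trees, depth 3, learning rate 0.1.  SBP and DBP are two independent
single-output regressors.  Feature sets: calibration-based
(PTT1_SYS, PTT1_DIA, PTT2_SYS, PTT2_DIA), calibration-free
(mPTT1, mPTT2, mHR), and the working 7-feature union.  Ratio
(mPTT1/mPTT2) is excluded from the working set after permutation
importance (mean R² drop over independent single-column shuffles) shows it
carries no incremental information.

Cross-validation: seeded shuffled k-fold (k = 5); fold metrics are Pearson
correlation and mean absolute difference; aggregates are mean ± population
SD over folds — the convention that reproduces the self-consistent printed
fold rows.  MAD is reported as the mean absolute error; a
`sqrt(S² + D̄²)` variant (error SD and mean error combined) is exposed as an
alternative because the literature formula this name descends from is
ambiguous.  Specificity is TN/(TN+FP); the accuracy identity
`acc = (sens·P + spec·N)/(P+N)` is asserted as an invariant.  Bland–Altman
uses population SD and the estimate − reference sign convention, limits at
bias ± 1.96·SD; error bins at 5/10/15 mmHg count |e| ≤ bound inclusively.

## Numerical choices and degenerate inputs

* Local maximum = strictly greater than both neighbors; ties resolve to the
  earlier sample.
* Zero crossings are located between bracketing samples by linear
  interpolation; peaks by three-point parabolic interpolation clamped to
  ±0.5 sample.
* Floor-based split sizes add a 1e-9 epsilon before flooring so exact
  ratio·n products are not rounded down by floating point.
* Constant segments (zero spread) raise `DegenerateSegmentError`; zero
  metric denominators report NaN rather than raising; beats with
  non-positive or missing intervals are marked incomplete.
* One global seed drives every stochastic stage; NumPy `default_rng`
  throughout, no global RNG state.

## Known limitations

Validation is entirely against the synthetic contract; no claim is made
about real scale data.  The foot detector's constant filter-induced offset
means absolute PTT1/PAT1 values are biased (their variation is not).  The
pipeline is offline by design: zero-phase filtering and whole-session bias
calibration have no causal counterpart here.  The quality classifier's
desk-scale figures come from separable synthetic classes; real-world
accuracy depends on artifact morphology the simulator does not model.
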