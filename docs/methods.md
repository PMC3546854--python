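# Methods

## Problem and pipeline

The package estimates the three wrist degrees of freedom — flexion/extension
(DoF1), radial/ulnar deviation (DoF2), pronation/supination (DoF3) — as
continuous angle trajectories from 7-channel forearm surface EMG, in the
mirror-training setting used for unilateral transradial amputees: EMG from
one arm is regressed onto joint angles measured on the opposite arm while
both arms perform mirrored movements. The stages are

1. band-pass the EMG (10–450 Hz, 2nd-order Butterworth) at its native
   2048 Hz;
2. compute per-frame wrist angles from the marker trajectories at their
   native 256 Hz, low-pass them (6 Hz, 2nd-order Butterworth);
3. trim both streams to the first rising edge of the shared 20 Hz square
   wave and resample both to a common 1024 Hz;
4. extract TDAR features on 100 ms windows advanced by 40 ms;
5. train one dedicated MLP per DoF and evaluate by 5-fold cross-validation
   with 30-restart winner selection, scoring with the multivariate R² and
   the per-DoF R²ᵢ.

## Preprocessing

**Zero-phase filtering.** All offline filtering defaults to
forward–backward (`sosfiltfilt`) application. The regression pairs EMG
envelope features with angle targets sample-by-sample, so group delay in
either stream would systematically shift the learned map; zero-phase
filtering removes that bias. A single-pass (causal) mode is available by
flag for studies of real-time behaviour; the band edges of the single-pass
filter are the classical −3 dB points.

**Resampling.** The rate ratios in play (2048→1024, 256→1024) are exact
rationals, so resampling uses polyphase FIR filtering (`resample_poly`),
which applies the anti-aliasing low-pass implicitly on decimation and avoids
interpolation drift. Output length is defined as `round(n·fs_out/fs_in)`.
The signal is resampled about its mean: the polyphase FIR has finite
stop-band attenuation, and for signals with a large DC component (the raw
pronation angle sits near 90°) the residual ripple (~6·10⁻⁴ relative) would
otherwise leak into the angle traces.

**Synchronization.** The sync square wave is ±5 V at 20 Hz. The edge
detector waits until the trace first dips below −2.5 V and then takes the
first positive-going zero crossing, which rejects power-on transients and
any flat lead-in before the generator is switched on. Both streams are
trimmed to their own edge; the signed difference of the edge times is
reported as `offset_applied`. A mean inter-edge period deviating more than
10 % from the nominal 50 ms raises a drift warning. Note the inherent
limitation of a periodic sync signal: offsets are only identifiable when
the square wave has a detectable onset within both records (it cannot
disambiguate lags that are exact multiples of its period between two
free-running periodic traces).

**Marker gaps.** Drop-outs are encoded as NaN, never as zeros. Gaps up to
250 ms are bridged by linear interpolation before filtering; longer interior
gaps invalidate the trial, mirroring the experimental practice of
re-recording trials with excessive gaps rather than repairing them. Gaps
touching the record edges hold the nearest valid frame. Trials with more
than 20 % invalid frames (gaps or out-of-range geometry) are rejected.

## TDAR features

Windows are 100 ms advanced by 40 ms (60 ms overlap); at 1024 Hz the nominal
lengths are non-integer, so they are rounded to the nearest sample
(L = 102, S = 41), which fixes the window count for a given record length:
`n = floor((n_samples − L)/S) + 1`, trailing partial windows discarded.
Features are computed at 1024 Hz, after resampling, so that feature windows
and angle samples share one timeline.

Per channel and window: the four Hudgins time-domain descriptors and six AR
coefficients, channel-major ordering.

- MAV = mean |x|; WL = Σ|Δx|.
- ZC counts sign changes between consecutive samples whose amplitude step
  exceeds a threshold; SSC counts interior samples whose two adjacent slopes
  have opposite signs with at least one step above a threshold. Both
  thresholds default to 0 µV, appropriate for the noiseless synthetic data;
  for recorded EMG a few µV should be used to reject baseline noise. With
  threshold 0, flat segments (exact zeros / equal neighbours) are not
  counted, since the products are then not strictly negative/positive.
- AR coefficients follow the convention `x[n] = Σ a_k x[n−k] + e[n]` (an
  AR(1) process generated with coefficient 0.5 yields a₁ ≈ 0.5), estimated
  on the mean-removed window by Levinson–Durbin on the biased
  autocorrelation sequence (= Yule–Walker). The biased estimator guarantees
  a non-negative-definite sequence and hence a stable recursion. Burg's
  method is available by flag. Constant windows are degenerate: the
  pipeline emits all-zero coefficients for them (an error by default in the
  low-level function).

## Wrist angles

Frame per time sample: origin O = midpoint(STR, STU); elbow
E = midpoint(MEP, LEP); z = unit(E − O), positive proximally; y orthogonal
to z and to the styloid line STR − STU (the dorsopalmar axis); x = y × z.
With H = midpoint(RMC, UMC) and (Hx, Hy, Hz) its frame coordinates,

- α₁ = atan2(Hy, −Hz), α₂ = atan2(Hx, −Hz) in degrees. Because the hand
  lies distally, Hz < 0, and the arctangent of Hy/Hz alone would flip the
  intended sign (flexion positive, radial positive); using −Hz keeps the
  magnitude of atan(Hy/Hz) and fixes the sign. |α₁|, |α₂| ≤ 90° by
  construction; frames with the hand not distal to the wrist (−Hz ≤ 0) are
  flagged not-available.
- α₃ = angle between w = LEP − MEP and l = STR − STU, raw in [0°, 180°],
  neutral ≈ 90°, values below 90° indicating supination. The regression
  target uses the centred form α₃ − 90 (pronation positive) so that all
  three targets are near zero at rest; this choice is recorded in the model
  metadata. Negative α₂ is taken as ulnar deviation, by symmetry with the
  flexion/extension convention.

**Handedness.** A frame that is right-handed on both arms cannot keep y
anterior *and* x lateral on both, because mirroring flips exactly one of
them. The implementation keeps the frame right-handed with y anterior on
either side (the session's `side` field selects the sign of y) and negates
α₂ on the left arm, so mirrored bilateral movements produce identical
(α₁, α₂, α₃) traces on both sides — the property the mirror-training
paradigm requires. Angles are invariant to rigid motions and uniform
scaling of all markers (covered by property tests).

Angles are computed at 256 Hz, filtered, then upsampled
(filter-then-resample), since the angle signal is band-limited far below
the marker rate.

## Estimation protocol

**Dataset assembly.** Each feature window is paired with the mean target
angle over the window span (midpoint-sample targets available by flag; the
mean is the default because it matches the averaging implicit in the
amplitude features). Windows are labelled by contraction id; a scenario
keeps only its contractions: DoF12 = {1, 2, 4, 5}, DoF13 = {1, 3, 6, 7},
DoF23 = {2, 3, 8, 9} (inferred by symmetry with the two explicit listings),
DoF123 = all ten. Laterality selects the EMG side relative to the
kinematics side: contra = opposite, ipsi = same.

**Blocking.** The five cross-validation blocks are contiguous in time
*within each contraction*: each contraction's window sequence is cut into
five consecutive chunks and block k pools chunk k of every contraction.
Adjacent windows overlap by 60 %, so row-level random splits would leak
training samples into the test set; contiguous blocks confine that leakage
to one boundary window per contraction per fold. Every block still samples
all contractions, keeping fold difficulty homogeneous.

**Network and training.** One MLP per DoF, `[70 → 3 → 1]`, tanh hidden
units, linear output — 3 hidden units is the balance point between accuracy
and computational cost for this feature set. Features and the target are
z-scored with training-partition statistics only (stored in the model).
Within each fold the four non-test blocks are split 3 + 1 into training and
validation, the validation block rotating with the fold index. Optimization
is Adam (learning rate 0.01, mini-batch ≤ 256) via scikit-learn's
`MLPRegressor`, driven one epoch at a time; after each epoch the validation
R²ᵢ is evaluated, the best-so-far weights are retained, and training stops
after 20 epochs without an improvement above 10⁻⁴ (max 500 epochs). All of
this is deterministic given the seed.

**Winner selection.** Per fold and DoF, 30 restarts differ only in their
initial weights (seeds derived from the master seed via `SeedSequence`
spawn keys (fold, dof, restart)). The restart with the highest *validation*
R²ᵢ is the winner — validation, not test, so the test block stays untouched
until final scoring; ties resolve to the first (lowest-seed) restart.
Restarts that hit the epoch limit are flagged but not excluded: a
poorly-converged model simply loses the validation comparison.

**Scoring.** Fold score = multivariate R² of the winners' test-block
estimates, pooled over the scenario's DoFs, plus per-DoF R²ᵢ. The pooled
index is algebraically the total-variance-weighted mean of the per-DoF
indices; both can be negative for estimators worse than the per-DoF mean.
Aggregates are mean ± SD over the five folds.

## Synthetic sessions

The generator emulates the recording protocol so every stage is testable
without experimental data. What it reproduces: the contraction taxonomy and
trial structure, the marker geometry (exactly), the sampling rates and sync
wave, and an EMG whose amplitude envelope is a known function of the
angles. What it does not reproduce: motor-unit physiology, electrode shift,
fatigue, crosstalk dynamics, soft-tissue artifact, or amputee-specific
muscle atrophy. Passing tests therefore demonstrate that the pipeline
recovers a learnable amplitude-to-angle map under realistic geometry and
timing — not clinical-grade performance on recorded EMG.

**Angle trajectories.** Ten trials: ids 1–3 single-DoF sinusoids, ids 4–9
two-DoF combinations (first DoF of the pair sinusoidal, second held at 80 %
of its amplitude — "close to maximal range"), id 10 three smooth
band-limited (≤ 1 Hz) pseudo-random curves. Sinusoid frequencies are fixed
per trial within the protocol's 0.5–1 Hz band. Default amplitudes 35°
(DoF1), 25° (DoF2), 45° (DoF3) — typical comfortable dynamic ranges, with
deviation the smallest as it is anatomically. Every trial starts and ends
at rest through 2 s / 1 s half-cosine ramps, keeping the concatenated
session band-limited below the 6 Hz angle filter. Trials are separated by
1 s of rest. The prescribed waveform is an analytic function of time,
evaluable at any rate, which makes exact round-trip checks possible.

**Markers.** The right arm lives in a canonical frame (wrist origin at 0,
elbow at +z, epicondylar axis along +x, forearm 250 mm, elbow/wrist/hand
widths 60/50/70 mm, hand length 80 mm). The styloid line is rotated in the
x–y plane by α₃ and the metacarpal midpoint placed along the frame
direction (tan α₂, tan α₁, −1) — the exact inverse of the angle equations,
so the noiseless round trip through the full chain errs < 0.1° (filter
edges excluded). The left arm is the mirror image (world x negated).
Gaussian marker noise (mm) and random short gaps are available for
robustness tests.

**EMG.** Six non-negative directional drives — half-rectified centred
angles normalized by 60° (flexion, extension, radial, ulnar, pronation,
supination) — model antagonist muscle pairs: no single channel sees a
signed angle, so the estimator must combine channels. A non-negative 7×6
synergy matrix with Gaussian ring tuning (channels equi-spaced around the
forearm, each direction driving a sector, σ = 0.9 rad) maps drives to
channel envelopes; a relative noise floor (default 0.05) keeps resting
channels alive. Each channel is its envelope times an independent
unit-variance 20–400 Hz Gaussian carrier at 2048 Hz, scaled to ~100 µV —
standard surface-EMG phenomenology, sufficient because the features exploit
amplitude structure. Motor-unit simulation is a non-goal.

**Mirroring imperfection.** The contralateral ("amputated") side uses the
mirrored drives with a perturbed synergy matrix
W′ = W ∘ (1 + asymmetry·ε), ε ~ N(0,1), clipped non-negative, drawn *per
trial*: imperfect mirroring varies from repetition to repetition, so a
fixed alternative map would remain perfectly learnable and no contra/ipsi
gap could emerge. With per-trial perturbation the training set contains
mutually inconsistent maps, degrading contra-lateral accuracy
monotonically with the asymmetry level while ipsi-lateral accuracy is
unaffected — the synthetic analogue of the amputee-versus-control contrast.
At asymmetry 0 both sides share envelopes exactly and differ only by
carrier realization.

**Problem sizes.** Default trials last 10 s (65 s available by flag),
giving ≈ 2 500 analysis windows per session — enough for stable five-fold
statistics while keeping a full 5-fold × 30-restart × 3-DoF study in the
minutes range on one CPU.

## Numerical choices and edge cases

- Window counts, feature ordering and block boundaries are pure functions
  of (n_samples, schedule, labels); the full pipeline is byte-reproducible
  given the master seed (reports avoid timestamps; timings go to the log).
- R² computations use the same summation expression for numerator and
  denominator, so the mean predictor scores exactly 0 and perfect estimates
  exactly 1 in floating point.
- Degenerate inputs raise typed errors: cutoffs at/above Nyquist, constant
  windows (AR), zero target variance (R²), coincident or collinear markers,
  signals shorter than one window, missing sync edges.
- Feature z-scoring guards against zero variance with a 10⁻¹² floor;
  Levinson–Durbin stops updating rows whose prediction error reaches zero.

## Known limitations

- The EMG model is stationary within a trial; no fatigue, electrode lift or
  spectral drift, so AR features carry little information here (they are
  amplitude-invariant) and act mainly as benign extra inputs.
- The sync model assumes both recorders capture the square wave's onset;
  free-running periodic traces are aligned only modulo the 50 ms period.
- C3D motion-capture files are not read; marker data enter via the HDF5 or
  CSV layouts.
- Group-level statistics (ANOVA across subjects/conditions) are out of
  scope; the package evaluates single sessions.
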