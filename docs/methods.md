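# Methods

`imustate` classifies seabird behavioral states from tri-axial
accelerometer and magnetometer (IMU) records. This note documents the
models, the numerical choices, and what the bundled synthetic benchmark
does and does not demonstrate.

## The observation pipeline

Raw series arrive at 25 Hz (or an integer multiple, decimated with a
zero-phase 8th-order Butterworth low-pass at 0.8x the target Nyquist
followed by integer downsampling; zero-phase filtering avoids shifting
wingbeat onsets across window boundaries).

**Frame correction.** A tag mounted with a slight roll tilt is detected
from resting-on-water segments, where the mean specific force should be
(0, 0, 1) g; the persistent mean sway angle `atan2(sway, heave)` is the
roll offset, and both sensors are de-rotated by it. Resting segments are
found with a simple rolling-ODBA threshold (default 0.08 g over 10 s);
this heuristic feeds only the roll-offset estimate, never the
classification.

**Magnetometer cleaning and calibration.** Deployment edges are trimmed
(default 2 h at the start, for handling effects) by marking samples
invalid, and a 5-sample running median removes interference spikes.
Hard/soft-iron calibration is a least-squares ellipsoid fit: a linear
sphere fit initializes the center, then a Cholesky-parameterized
least-squares refinement fits center plus shape, constrained to ellipsoids
by construction. Two stabilizers matter in practice:

1. *Weak sphere prior.* A free-flying animal visits only a band of
   orientations, and an unconstrained quadric fit of a shallow band has a
   near-flat direction along which an enormous osculating ellipsoid fits
   the data arbitrarily well. A weak quadratic pull toward the initial
   sphere (equivalent to about 1% of the data weight) pins that runaway
   without measurably biasing well-covered directions.
2. *Attitude-aided refinement.* The accelerometer attitude supplies the
   constraints the orientation coverage lacks: after tilt de-rotation the
   corrected field must have a constant vertical component and a constant
   horizontal magnitude at every heading. A second least-squares pass over
   (center, symmetric correction) enforces these two invariants together
   with the unit-norm residual. The symmetric parameterization fixes the
   rotational gauge, so the refinement cannot introduce a constant heading
   bias. An ellipsoid fit alone identifies the soft-iron distortion only
   up to an orthogonal factor; the symmetric representative is exact for
   symmetric distortions, which is what the generator produces.

**Attitude and heading.** Pitch `atan2(a_x, hypot(a_y, a_z))` and roll
`atan2(a_y, a_z)` come from a gravity estimate obtained with a zero-phase
4th-order Butterworth low-pass at 0.5 Hz. The boxcar running mean used for
the feature split (below) is *not* used here: a 2-s boxcar attenuates a
10-s banked-turn roll oscillation by ~6.5%, i.e. ~2.6 deg of roll error at
the bank peaks, while the 0.5 Hz Butterworth is maximally flat at those
timescales and still suppresses the wingbeat band by >100 dB. The
magnetometer is de-rotated by `Ry(-pitch) Rx(roll)` and heading is
`atan2(-m_y, m_x)` in degrees clockwise from magnetic north, in [0, 360).
Output is magnetic heading; no declination correction is applied.

## Movement features

Eight candidate features per fixed, non-overlapping 30-s window (750
samples), anchored at the record start; incomplete trailing windows are
dropped, and windows with more than 50% invalid samples are emitted as
missing:

| feature | definition |
|---|---|
| df | dominant frequency of total heave (Hz) |
| hf | highest dominant frequency (Hz) |
| ms, ss | mean and SD of static heave (g) |
| p5 | 95th percentile of static heave (g) — the top-fifth-percentile boundary |
| iqr | inter-quartile range of dynamic heave (g) |
| mo | mean ODBA (g) |
| sh | circular SD of heading (radians) |

Static acceleration is a centered 2-s running mean; dynamic is the
residual, so the split reconstructs the total exactly. ODBA is the sum of
absolute dynamic acceleration over the three axes. "Dominant frequencies"
are local maxima of the mean-removed power spectrum (no taper; the 1/30 Hz
bin spacing already separates the wingbeat near 2.6 Hz from swell near
0.1 Hz) whose power reaches 5% of the spectral maximum, DC excluded; a
flat spectrum yields the 0 Hz sentinel. `sh = sqrt(-2 ln Rbar)` is
computed in radians and clipped into [1e-6, 4.0] so degenerate windows
stay inside the Weibull support. Feature selection uses pairwise Pearson
correlations over complete rows with greedy elimination above a threshold
(default |r| = 0.7), dropping the member of the worst pair with the larger
mean absolute correlation; `sh` is treated as a non-negative dispersion
magnitude, not an angle.

## The hidden Markov model

Windows are the model's time steps. Given state `i`, features are
independent Weibull variates with state/feature-specific shape and scale.
Transitions follow a row-wise multinomial logit with the diagonal as
reference; a categorical covariate (species) adds level-specific offsets
to the off-diagonal logits, with the first level as reference. Individuals
are independent realizations of the shared model. The initial distribution
is a shared free parameter by default (`delta_mode="stationary"`
substitutes the stationary vector of the reference-level matrix instead;
in that mode the small gradient contribution through the transition
coefficients is omitted, which is why "estimate" is the default).

**Likelihood and gradient.** The scaled forward recursion runs over a
padded batch of chains; padded steps carry all-ones emissions and are
transparent to the likelihood because the transition matrices are
row-stochastic. Missing windows likewise contribute a unit emission factor
(the transition structure still bridges them); runs of missingness longer
than 10 windows split the chain instead. Gradients are exact: by the
Fisher identity the score equals the posterior expectation of the
complete-data score, which one forward-backward pass yields — posterior
state weights drive the Weibull shape/scale derivatives, expected
transition counts drive the logit coefficients. The recursions are
JIT-compiled (numba) with a pure-Python fallback.

**Maximization.** Parameters are transformed to an unconstrained scale
(log shapes/scales, free logits, additive-log-ratio initial distribution)
and the negative log-likelihood is minimized with L-BFGS-B (bounded to
keep shapes in [0.05, 200] and scales in [1e-7, 1e4], which prevents
degenerate spikes on nearly-atomic features); a Nelder-Mead fallback
handles quasi-Newton failures. Of `n_restarts = 25` starts, the first is
informed — Weibull moment-matching within a k-means partition of the
standardized log-features, playing the role of values anticipated per
state — and the rest draw scales near data quantiles randomly assigned to
states, log-uniform shapes in [0.7, 6], and transition intercepts near a
diagonally dominant matrix. The best restart receives an extra polishing
run (the likelihood ridge near the optimum is flat and the quasi-Newton
tail converges slowly). Restarts within 1e-3 log-likelihood units of the
best are counted as numerically stable. AIC uses
`2 S F + S(S-1) L + (S-1)` free parameters (emissions, transitions over
`L` covariate levels, initial distribution).

Viterbi decoding runs in log space with ties broken toward the lower
state index. Decoded states are relabeled by feature means: largest
Weibull mean of `hf` is flapping; of the rest, the larger `sh` mean (or
`p5` if `sh` is absent) is soaring. Forecast pseudo-residuals map each
feature through its model-implied CDF given the chain's past and then the
standard normal quantile; under a correct model they are iid standard
normal per feature.

## The synthetic benchmark

The generator is a stylized emulator, not an aerodynamic model. Hidden
states follow a window-scale Markov chain; the two covariate levels use
the two published 3-state transition-matrix estimates for this system
(rows renormalized), and the initial distribution is the stationary vector
of the first. Within windows, signals are rendered at 25 Hz:

* **flap** — heave sinusoid at N(2.6, 0.1^2) Hz (anchored to the reported
  2.5-2.7 Hz wingbeat range), amplitude 0.9 g with a 30% surge component,
  0.05 g noise per axis, heading drifting at N(0, 1.5^2) deg/s;
* **soar** — heading arcs of 80 deg amplitude with N(10, 1) s period;
  roll (40 deg) and pitch (10 deg) proportional to the heading-arc
  derivative (banked turns), and a 1/cos^2(roll) load factor so static
  heave rises in the banks — this is what separates soaring from on-water
  on `p5` and exercises tilt correction non-trivially;
* **water** — heave 1 g plus a 0.05 g swell at N(0.125, 0.015^2) Hz
  (an 8-s swell period; also keeps the on-water spectral peak below the
  soar load-factor tone at 0.2 Hz so the per-state `hf` clouds stay
  ordered), 0.02 g noise, near-constant heading.

Heading jitter is an Ornstein-Uhlenbeck yaw wander (SD 2-3 deg, 1-s
correlation) rather than white noise — a gliding or floating bird has
rotational inertia, and smooth jitter is also what makes the heading truth
recoverable through the median filter. The magnetometer sees a 45 uT field
at 60 deg inclination rotated into the instantaneous tag frame, distorted
by a symmetric soft-iron matrix (diag ~ 1.10/0.96/0.88), a (12, -8, 5) uT
hard-iron offset and 0.3 uT white noise; a 5 deg tag-mount roll offset
rotates both sensors. All values are config defaults, not claims about
albatrosses.

The default benchmark is 20 individuals x 500 windows (~4.2 h each,
~83 h total) over five replicate seeds; the synthetic runs skip the 2-h
start trim since the generator does not emulate handling effects. These
sizes keep the full five-replicate benchmark within minutes on one CPU
while leaving per-replicate Monte-Carlo error on the decoded accuracy well
below a percentage point.

**What passing does not show.** Within-window state purity is assumed
(real 30-s windows can mix behaviors; the validation convention is the
dominant behavior). Emissions are generated as conditionally independent
Weibulls at the window scale, the same family the model fits, so the
benchmark validates recovery and decoding machinery rather than
robustness to emission misspecification — the pseudo-residual power check
probes the latter separately. Real magnetometer distortions need not be
symmetric, real noise is not white, and GPS, wind and wave processes are
not modeled.

## Known limitations

* Calibration quality depends on orientation coverage; the attitude-aided
  refinement needs banked flight (or similar attitude variety) somewhere
  in the record.
* The covariate enters transitions only; covariates on emission
  parameters are out of scope.
* Bouts and budgets inherit the 30-s resolution; sub-window behaviors are
  invisible.
* `delta_mode="stationary"` uses an approximate gradient (see above).
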