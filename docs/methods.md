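# Methods

## The problem

During closed-loop brain-machine-interface (BMI) control, a subject drives a
cursor through a linear decoder while watching delayed visual feedback.  The
subject is assumed to hold an *internal forward model* of the cursor — beliefs
about its physics and about how each recorded unit pushes it — and to issue
neural commands that aim straight at the target from an internal, up-to-date
prediction of the cursor state.  A mismatch between this internal model and
the actual decoder produces structured movement errors.  This package
implements the estimation framework that extracts such an internal model
from population spike counts, cursor kinematics and target positions (IME:
internal model estimation), together with a closed-loop simulator that makes
the whole pipeline testable against ground truth.

## The decoder

The cursor follows a position/velocity decoder with timestep Δ = 33 ms:

    p_t = p_{t-1} + v_{t-1} Δ
    v_t = B_v u_t + b_v

where `u_t` is the mean of the last W = 5 raw spike-count vectors (a causal
boxcar; at trial start the mean runs over the available history).  The
columns of `B_v` (mm/s per count) are the units' *pushing vectors*.
Unsmoothed single-timestep commands `v_t_raw = B_v u_t_raw + b_v` are used
wherever single-bin temporal resolution is required (latency and lag
analyses).  Calibration follows the population-vector recipe: per-unit
cosine-tuning regressions on target-direction unit vectors, assembled into
`B_v` with the offset cancelling baseline firing, refined over closed-loop
sequences with decreasing perpendicular-velocity assistance
(1.0, 0.75, 0.5, 0.25, 0.0 by default).

Decoder perturbations rotate a chosen subset of pushing vectors.  When the
mapping records the baseline rates its offset cancels, each rotated unit's
share of the baseline cancellation rotates with its pushing vector, so that
baseline firing still decodes to zero velocity and a 100% rotation acts as an
exact visuomotor rotation of decoded velocities.  (Rotating the columns but
not the offset would instead add a large constant drift, which is not what a
rotated population-vector decoder does.)

## The internal model and its latent structure

The subject's model has the same linear form, over beliefs
`x̃ = (p̃, ṽ)`:

    p̃_k = p̃_{k-1} + ṽ_{k-1} Δ                        (deterministic)
    ṽ_k = Ã_v ṽ_{k-1} + B̃_v u_k_raw + b̃_v + w_k,    w_k ~ N(0, w I)

At each timestep t the subject grounds its belief at the τ-delayed visual
feedback, `x̃_{t-τ} = x_{t-τ}` (position and the displayed, smoothed
velocity), and unrolls the model through the raw commands issued since.
The resulting τ-step path of predicted states is the *whisker*; its last
element is the subject's current belief.  Straight-to-target aiming enters
as one Gaussian observation per timestep,

    G = p̃_t + α_t ṽ_t + r_t,    r_t ~ N(0, r I),  α_t ≥ 0,

where the per-timestep distance scale α_t leaves intended speed free.

Because the position recursion carries no noise, the only latent variables
in a whisker are its τ 2-D velocities; positions are affine functions of
them.  Whiskers at different timesteps share no latent variables, so the
posterior factorizes per whisker.

## Fitting

**E-step.**  Per whisker the prior over the stacked velocities is a small
Gaussian chain whose covariance depends only on `(Ã_v, w)`; the aiming
observation is a rank-2 linear functional of the latents with weights
(Δ, …, Δ, α_t).  Exact conditioning is a closed-form 2×2 update, vectorized
across all whiskers.  Covariance blocks are symmetrized after conditioning.
The per-timestep marginal likelihood of the aiming observations is the
objective EM ascends; its trace is checked to be non-decreasing (relative
tolerance 1e-9) on every fit.

**M-step.**  All updates are closed form: `(Ã_v, B̃_v, b̃_v)` from a joint
linear regression of each latent velocity on [previous velocity; raw counts;
1] under posterior expectations (ridge fallback, penalty 1e-8·trace-scaled,
if the design is rank-deficient); isotropic `w` from the dynamics residual;
α_t from scalar least squares, clamped at zero; isotropic `r` from the
aiming residual.  τ is held fixed (default 3 timesteps ≈ 100 ms, the
visuomotor latency the latency analysis recovers).

**Initialization and convergence.**  The decoder is the natural prior
belief; EM initializes at its AR(1)-equivalent form (`Ã_v = (1−1/W) I`,
readout scaled by 1/W) so the initial steady-state gain matches the
smoothing the dynamics encode.  Noise scales start at 10% of the data
variance.  Convergence: relative log-likelihood change < 1e-9 or max-abs
parameter change < 1e-8, capped at 5000 iterations by default; the tests and
experiments in this repository cap at 120–300 iterations, which the
convergence diagnostics show is past the point where held-out errors and
recovered readout directions stabilize at these problem sizes.

**Cross-validation.**  Trials are assigned to folds with one trial per
unique target per fold; K is the minimum per-target count, and surplus
trials are permanent training trials.  Held-out whiskers are pure
noise-free unrolls of the fitted model from feedback — neither the target
nor the aiming equation is used, so whiskers pointing at held-out targets
reflect structure in the neural activity, not circularity.

**Variants.**  Neural-only (`Ã_v = 0`) isolates explanatory power carried by
high-dimensional neural structure and is scored against unsmoothed cursor
commands; the behavior-fit control replaces the q-dimensional counts with
2-D velocity commands; the aim-from-feedback alternative regresses
speed-matched straight-to-target velocities (from the τ-delayed position)
on raw counts, with no forward prediction.

### Identifiability notes

Two degeneracies of the model family matter when interpreting fits.
First, on data whose spike patterns span a low-dimensional subspace
(e.g. noiseless minimum-norm commands), `B̃_v` is only identified on that
subspace; parameter-space comparisons are meaningful only with full-rank
spiking noise.  Second, part of an output rotation of the readout can be
traded against a rotational component in `Ã_v` with little likelihood cost,
and maximum likelihood tends to prefer slightly heavier dynamics smoothing
than the generating model because it attenuates spiking noise in the
whisker endpoints.  Recovered readouts therefore carry a few degrees of
row-space estimation noise at realistic session sizes, and fitted `Ã_v` is
biased high.  Sliding-window fits inherit a related risk: a warm-started
model arriving overconfident (small fitted `r`) can be yanked into a poor
local optimum, so window fits re-temper their noise scales on the new data
and keep the better of a warm start and a stable-reference start by final
log-likelihood.

## The synthetic-data generator

The generator stands in for the unavailable primate recordings and emulates
the study conditions: 16 evenly spaced radial targets at 85 mm, 7-mm cursor
and target radii, Δ = 33 ms, W = 5, τ = 3, center-hold then a 3-timestep
sensory delay after target onset, target acquisition on sustained visible
overlap, success rates near 100% under the intuitive mapping, and movement
durations under a second.  Per timestep the subject: grounds and unrolls its
*true* internal model (whisker), aims at the (delay-gated) target with a
saturating distance-to-speed policy (fast far from the target, slow near
it; ceiling 120 mm/s), and emits the minimum-norm mean spike pattern whose
image under its believed readout realizes the intended velocity, plus
seeded variability in the believed readout's null space.  Rates are
rectified (the clip rate is logged and stays well under 1% at defaults) and
counts drawn Poisson, optionally correlated through a Gaussian copula.  The
decoder then updates the actual cursor.

Design choices a reader should know:

- **Mismatch** is composed of a global rotation of the believed pushing
  vectors, per-unit gain jitter, and components in the null space of the
  decoder readout.  Zero mismatch makes the subject decoder-equivalent.
- **Boxcar vs AR(1).**  The decoder's 5-tap boxcar is not a member of the
  AR(1) internal-model family; the decoder-equivalent belief uses the
  steady-state-equivalent AR(1) form.  Exact matched-model identities
  (whiskers coinciding with trajectories to machine precision) therefore
  hold with `smooth_window = 1`, where the correspondence is exact, and the
  matched-model tests use that configuration.
- **Push policy.**  By default the subject compensates its believed dynamics
  so its up-to-date velocity belief equals the intended velocity exactly
  ("compensate"); the "steady" option pushes only the share not inherited
  through the believed dynamics, making raw commands point at the aim point
  at the cost of belief lag during turns.  A per-step acceleration cap
  (scaled by the believed smoothing so the reachable steady-state speed is
  150 mm/s regardless of `Ã_v`) keeps spike-pattern excursions within
  physiological range and makes rate rectification rare.
- **Decoder gain** is scaled so a coherent half-count-per-unit population
  push reaches the speed ceiling, which gives single-timestep commands a
  realistic direction signal-to-noise ratio over Poisson noise; baseline
  rates are drawn uniformly in 1.5–4 counts/bin and the decoder offset
  cancels them.
- **Adaptation** experiments drift the subject's believed model toward the
  decoder-equivalent of the active mapping by an exponential per-trial rate.

What the generator does *not* emulate: non-Poisson count dispersion,
low-dimensional shared variability (beyond the optional copula), slow
nonstationarities in tuning, eye movements, reaction-time variability
beyond the fixed sensory delay, and any biophysical spiking dynamics.
Passing tests therefore certify the estimation and analysis machinery under
the model's own assumptions plus realistic count noise — not robustness to
every failure mode of real recordings.

## Analyses

- **Latency**: per-trial baseline error before target onset; paired
  two-sided Wilcoxon signed-rank of each post-onset timestep against
  baseline across trials, Holm-Bonferroni over timesteps; the latency is
  the first significant decrease (0-based timesteps).  Errors use
  unsmoothed commands.
- **Lag sweep**: mean absolute error of unsmoothed commands evaluated as
  originating from lagged positions, −100…+300 ms, restricted to timesteps
  ≥ 100 ms post onset for which every lag lies inside the trial — the
  identical subset at every lag.  At this package's synthetic workspace
  scales the overlap-zone metric's distance-to-target bias is strong
  relative to the direction signal, so the delay-compensation contrast is
  run with the target-center metric (the two metrics agree qualitatively
  otherwise).
- **Session errors**: absolute angular errors to the cursor-target overlap
  zone, averaged within trial then across trials; the decoder view uses
  `(p_t, v_t)`, the internal view `(p̃_t, ṽ_t)` from held-out whiskers, the
  neural-only view compares against unsmoothed commands.  Fraction of
  cursor error explained = (cursor − internal)/cursor.
- **Speed**: intended speed is the magnitude of the held-out velocity
  belief; the curve reports mean ± SEM actual speed per intended-speed bin;
  hold phase = pre-onset timesteps; movement phase = the single timestep
  where cursor-target distance first drops below half the center-to-target
  distance.
- **Noise control**: raw patterns labeled by the nearest of 32 directions of
  their decoder image; per-direction mean (idealized) patterns; residuals
  pooled across directions and resampled with replacement (seeded) to build
  noisy patterns with per-direction counts matched to the data; errors
  evaluated through the decoder and through cross-validated internal
  models, scoring a simulated pattern only through a model that never saw
  the trial its residual came from.
- **Null-space shuffle**: spike counts decomposed against the decoder
  readout's row space; null-space components permuted across all timesteps.
  Decoder velocities are preserved to machine precision.
- **Adaptation tracking**: a time-varying internal model refit every 16
  trials on the preceding 48 (evaluation trials disjoint from each training
  window; per-window fits use tempered multi-start EM as described above),
  plus a late-intuitive model from the last 48 intuitive trials.  Error
  traces run each mapping's counterfactual whiskers (exact for the active
  mapping) and the models' held-out whiskers, smoothed with a causal
  24-trial boxcar.  Signed-angle traces compare the model's and each
  mapping's *unsmoothed* readouts of the same activity — whisker endpoints
  inherit the active mapping's frame through the fed-back anchor velocity,
  so the unsmoothed comparison is the frame-pure one — with signs flipped
  for counter-clockwise perturbations.
- **Pushing-vector rescaling**: internal-model pushing vectors are scaled by
  1/(1 − trace(Ã_v)/2) before comparison with decoder pushing vectors, to
  normalize out the share of each velocity prediction inherited from the
  previous one.

## Problem sizes

The test-suite experiments run at desk scale, chosen to finish in minutes
while leaving the conclusions clear: sessions of 8–16 targets with 2–10
trials per target and 8–20 units; the recovery experiment uses 20 sessions
(q = 20, 16 targets, 10 trials/target, 30° rotation mismatch, seeds 0–19);
adaptation experiments use 96/144/96-trial blocks with a 12-unit
population.  EM iteration caps per fit are stated in each experiment.

## Known limitations

- The overlap-zone error is defined as 90° half-angle when the cursor
  already overlaps the target; the estimation itself never evaluates that
  regime.
- With fewer than W timesteps of history the boxcar runs over the available
  history; stored sessions therefore reproduce their velocities exactly on
  reload, but splicing trials would not.
- α_t is one free parameter per training timestep with no prior; it is
  clamped at zero and absorbs intended-speed variation, which is what
  leaves speed unconstrained but also contributes to the identifiability
  effects noted above.
- The latency test's Wilcoxon uses trials as the replication unit; pooling
  timesteps would overstate n.
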