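# Methods

## Model

The core model is a continuous-time leaky rate RNN,

    T dr/dt = -r + f(W_rec r + b + W_inp h_ext + eta),    y = g(W_out r),

simulated by forward Euler with dt = 5 ms and a uniform membrane time
constant tau = 100 ms (20 fine steps per time constant). `f` is ReLU
(tanh, softplus and identity are supported; identity is used for the
linear-regime convergence and gradient checks). The readout `g` is a
per-channel sigmoid for the ring tasks and a softmax for the rule task.
External input enters through trainable input weights inside the
activation, consistent with the set of optimized parameters
(W_inp, W_rec, W_out, b).

**Noise.** eta is drawn independently per Euler step inside the activation
argument with standard deviation `sigma_noise * sqrt(2 tau / dt_eff)`,
where `dt_eff` is the step actually simulated. This variance-preserving
scaling keeps the accumulated trajectory noise power invariant to the
discretization factor, which matters when CD changes the effective step
size mid-training: otherwise annealing theta would also anneal the noise.
Default `sigma_noise = 0.01` (stationary rate noise of about 0.01), a
conservative value typical of this modeling literature.

**Initialization.** W_rec is Gaussian rescaled to spectral radius 0.8
(contractive), W_inp and W_out Gaussian with variance 1/fan-in, b = 0,
r0 = 0. Default network size is 256 units (desk presets use 80).

## Surrogate integrators

Skip segments are half-open fine-grid intervals `(s, e)`; periodic
segments span `theta` steps starting every `theta` steps, and *strategic*
segments span whole trials of multi-trial episodes (they coexist with the
periodic ones and share their mixing ratio and schedule). At a segment end
the state is replaced by

* SCTT: `(1-beta) r_s + beta r_base`,
* DASC: `(1-beta) cd(r_s) + beta r_base`, with `cd` a single Euler step of
  size `(e-s) dt` from the segment start,

and the mixed state seeds the following steps. CD instead simulates the
whole trial on a coarse grid of `ceil(n_steps/theta)` macro steps (loss,
inputs and targets are subsampled to that grid). A trailing partial
segment that would overrun the trial runs plain base steps with no mix.
When several segments end at the same index, shorter (periodic) mixes are
applied before longer (strategic) ones; the backward pass mirrors this
order.

**Gradient contract.** BPTT is hand-written reverse mode (no autodiff
framework is used). At each mix the incoming adjoint splits into a `beta`
branch that backpropagates through the fine chain and a `(1-beta)` branch
routed directly to the segment start, bypassing the theta recurrent
Jacobian factors; DASC's bypass additionally passes through the one-step
coarse Jacobian. All four methods' gradients were verified against central
finite differences in float64 (including overlapping strategic segments
and the closed-loop rule task).

**Annealing.** A schedule takes `step_count + 1` plateau values over the
first `horizon` training steps (default 20,000) in equal intervals —
`beta0 + k (1 - beta0)/step_count` for SCTT/DASC, and the same linear
interpolation rounded to integers >= 1 for CD's theta — and is exactly its
terminal value 1 at and beyond the horizon, at which point the forward
pass is bit-identical to the base model (the reduction identities
SCTT(beta=1) = DASC(beta=1) = CD(theta=1) = base hold bitwise under shared
noise, which the tests assert).

## Task battery

Ring tasks use 65 input channels (fixation + two 32-unit modality rings)
and 33 outputs (fixation + one ring). Unit i prefers direction
`2 pi i / 32`; input activation is `gamma * 0.8 * exp(-0.5 (8 d / pi)^2)`
with wrapped angular distance d, and output targets add a 0.05 baseline
with a 0.85 peak. The printed exponent of the tuning formula is
typographically ambiguous in its source; it is implemented as
`-1/2 (8 d / pi)^2`, the standard form in the multi-task suite this
battery follows, which reproduces the printed constants (peak 0.8 gamma,
baseline 0.05). The fixation target is 0.85 while fixating and 0.05
during response, leaving >= 0.3 margin on both sides of the 0.5 decision
threshold.

Epoch durations at full scale are sampled per trial (fixation 500–1500 ms,
stimulus 500–1000 ms, delay 1000–4000 ms, response 500 ms) and padded/
trimmed so totals land in the 1500–2500-step range; desk presets fix much
shorter epochs explicitly and warn. Decision-making magnitude differences
are drawn from the discrete set {0.16, 0.32, 0.64} around a unit mean.
The category boundary for dmc/dnmc splits the circle at [0, pi) vs
[pi, 2 pi). The loss is masked MSE; the mask zeroes a 100 ms grace window
after each epoch transition (no penalty for reaction lag) and doubles the
fixation-channel weight.

**Performance** of a trial is 1 iff fixation was never broken before the
response epoch and either the population-vector decode of the output ring
lies within 0.3 rad of the target direction (when a saccade is required;
the vector must also exceed a minimal length of 0.2, versus ~4 for an
exact target bump), or no saccade was emitted when fixation had to be
maintained. Network performance is the mean over a frozen evaluation
batch.

**Rule-reversal task.** Two stimuli, two responses, two hidden rules
(identity and reversed mapping) that switch without cue; the only cue is a
positive/negative feedback one-hot after each response. Episodes
concatenate 5 trials (stimulus+response+feedback windows); during training
the feedback reflects the network's own argmax response (closed loop), so
rule inference must come from feedback. The loss is cross-entropy of the
softmax readout over response-epoch steps. The stored reference episodes
use a rule-following agent that flips its belief after negative feedback,
so it errs exactly on the first trial after each switch.

**Population masks.** For ring tasks the first quarter of units is the
input population, the second quarter the output population, the rest
auxiliary; W_inp rows and W_out columns outside these sets are re-zeroed
after every optimizer step, forcing computation through recurrent
interactions. The rule task uses no population separation.

## Training protocol

Adam (lr 1e-3 full scale, beta1 0.9, beta2 0.999), batch 64, per-network
gradient-norm clipping at 1.0, cohorts of 100 networks trained in lockstep
on a shared task stream with independent initializations and noise,
evaluated every 100 steps on a frozen 512-trial batch, stopped when the
mean performance of the members ranked in the 10th–90th percentile band
(ranks `ceil(n/10)+1 .. floor(9n/10)`; 11–90 for n = 100) reaches 0.99, or
at 40,000 steps, in which case a plateau check verifies the band-mean
slope over the last tenth of evaluations is below 1e-4 per evaluation.
During annealing the stopping criterion is evaluated under the currently
scheduled surrogate; past the horizon the evaluation is exactly the base
model. A small L2 penalty on rates (1e-3 full scale) is added to the task
loss: with a saturating readout the MSE alone places no ceiling on rates,
and unregularized cohorts drift into runaway-rate regimes. Members whose
states go non-finite or exceed 1e6 are flagged failed, frozen, and scored
zero while the cohort continues.

Training internals run in float32 (the gradient signal sits far above
single-precision resolution; verification against finite differences is
done in float64, which remains selectable via `TrainConfig.dtype`).
Everything is vectorized over the cohort axis; identical configs rerun
bit-identically.

**FLOP accounting** is analytic: `2 n^2 + 2 n (n_in + n_out)`
multiply-adds per simulated step and trial, times 3 for forward+backward,
times batch and simulated steps; CD phases divide the simulated steps by
the currently scheduled theta.

## Dynamics discrepancy

True vs modified trajectories are compared at zero noise from identical
initial states; CD on its coarse time points only (interpolation would
attribute resampling error to the method). The normalized MSE divides the
mean squared state difference by the time-and-unit variance of the true
trajectory (invariant to additive offsets and common rescaling). A
trajectory is flagged *unstable* when any rate magnitude exceeds 50:
ring-task networks operate with rates well below 1, stable surrogate
trajectories of random contractive networks stay below ~1, and unstable
coarse discretizations overshoot geometrically to 1e2–1e14, so any
threshold in that wide gap classifies identically; 50 sits inside it with
two orders of magnitude of margin on either side. With theta dt > tau the
CD macro map's leak multiplier `1 - theta dt / tau` is negative and random
contractive networks amplify along eigendirections with
`|1 - theta dt/tau + theta dt/tau * lambda(DW)| > 1`, so instability
emerges over enough macro steps: at full-length trials (2500 steps) a
majority of random 64-unit networks flag at theta = 30 and essentially all
at theta = 40, while SCTT/DASC (convex mixes of bounded states) never do.

## Desk-scale presets and what they show

Full-protocol cohorts are cluster-scale jobs. The desk presets used by the
test suite shrink every axis at once: 80 units, ~300-step trials, cohorts
of 8 (band = ranks 2..7), batches of 16–24, step caps of order 1e3, and a
proportionally shortened annealing horizon. For the delayed-go
training-efficiency contrast the preset additionally draws stimulus
directions from 8 equally spaced values (instead of the continuum) and
scales stimulus magnitudes by 3, with the rate penalty at 1e-4 and Adam at
1e-2: with ~1e4 training trials in the budget, a continuum of directions
at unit contrast is not learnable by any method, and the contrast of
interest — whether gradients can cross an 8-tau memory delay at all — is
preserved under these simplifications. The delay (160 steps = 8 tau) is
what blocks the control: its end-of-delay state retains only a few percent
of the stimulus-driven activity, while skip segments carry state across
the delay with retention `(1-beta)` per segment during training.

Passing desk-scale tests therefore demonstrates the mechanisms (gradient
shortcuts, dynamics alignment, annealing back to the base model), not the
full-scale step counts or success proportions, which depend on the
complete protocol. A finding from these scaled-down runs, consistent with
the dynamics-discrepancy analysis: DASC reaches the cohort criterion
quickly because performance under its dynamics-aligned surrogate transfers
across annealing, whereas SCTT — whose surrogate attenuates the dynamics —
needs substantially more training after annealing to re-fit, so at
aggressively reduced step budgets SCTT may fail the desk-scale criterion
that DASC meets even though both succeed at full scale.

## Numerical and design choices

* Euler map and mixes are evaluated exactly as written; the reduction
  identities hold bitwise, not just approximately, because `(1-beta)=0`
  and `beta=1` make the mix an IEEE identity.
* CD's annealed theta plateaus are rounded to the nearest integer >= 1;
  inputs/targets are resampled to the coarse grid at each plateau.
* Divergence during *simulation* raises an error naming the step and
  method; during *training* it flags the member; in *analysis* it marks
  the (method, theta) cell unstable rather than erroring.
* Degenerate inputs: zero-length simulations return just r0; an all-zero
  loss mask is rejected; percentile bands on cohorts too small to hold a
  band fall back to the plain mean.
* Seed handling: one user-facing seed expands through
  `numpy.random.SeedSequence.spawn` into independent init / task / noise /
  evaluation streams; the evaluation noise stream is re-seeded identically
  at every evaluation so criterion crossings are deterministic given
  parameters.

## Known limitations

* The synthetic battery uses idealized epochs and noiseless targets; real
  behavioral data have graded difficulty (e.g. continuous coherences),
  which the discrete magnitude set only sketches.
* The rule task's closed-loop feedback uses the argmax response; no
  exploration or stochastic policy is modeled.
* FLOP counts are analytic conventions, not hardware measurements;
  wall-clock comparisons across methods depend on implementation constants
  that this pure-NumPy engine does not share with GPU frameworks.
* Full-scale cohort numbers (steps-to-criterion on 1500–2500-step trials,
  100-network success proportions) are out of desk-scale reach; the
  configurations are constructible and validated, but running them is a
  cluster job.
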