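# Methods

## The scheme

The package simulates perception and action as a generalized gradient
descent on variational free energy.  An agent's generative model is a
hierarchy of stochastic dynamical levels

    s       = g1(x1, v1) + noise        x1' = f1(x1, v1) + noise
    v(i-1)  = gi(xi, vi) + noise        xi' = fi(xi, vi) + noise

with Gaussian fluctuations whose log precisions `pi_x`, `pi_v` may depend
on the level's own states and causes.  Every variable is represented in
*generalized coordinates of motion* — the value and its first `n − 1`
temporal derivatives — and the posterior expectations evolve as

    d(mu~)/dt = D mu~ − dF/d(mu~)

where `D` shifts derivative orders down and `F` is the Laplace free
energy, ½ Σ (eps' Pi~ eps − log|Pi~|) over the state errors
`eps_x = D mu~_x − f~` and cause errors `eps_v = mu~_v(below) − g~`
(sensations at the lowest level, a prior schedule `eta(t)` at the top).
Action follows the same descent through the true sensory sensitivity,
`da/dt = −(ds~/da)' xi_v(1)` with `xi = Pi~ eps` the precision-weighted
errors — the classical reflex arc.

Precisions over generalized coordinates are `kron(inv(V), diag(exp(pi)))`,
where `V` is the covariance among derivative orders of a unit-variance
process with Gaussian autocorrelation of width `s` (the *roughness*,
default 0.5 time bins).  `V[i, j] = (−1)^i rho^(i+j)(0)`, with the
derivatives of the Gaussian autocorrelation at zero lag computed in
closed form; `V` is symmetric, zero on odd cross-orders, and positive
definite for all roughness values and embedding orders used here.
Synthetic fluctuations are white noise convolved with the matching
Gaussian kernel on an upsampled grid, so the sampled series reproduces
the assumed autocorrelation even when `s` is below one bin.

### Gradient assembly

The descent correction is assembled in the message-passing form: for each
error group, the transpose of the error Jacobian times the weighted error,
plus — when a log precision is state-dependent — the quadratic term
`½ eps'(dPi/dmu)eps` and the log-determinant (trace) term
`−½ d tr(pi~)/dmu`.  Jacobians of the generalized maps are taken by
central finite differences of the maps themselves (analytic order-0
Jacobians are used inside the maps where models supply them), so the
assembled flow agrees with finite differences of the scalar free energy
to ~1e−5 relative error even for nonlinear models with state-dependent
precision.  This equivalence is enforced by a dedicated validation
(`actinf.experiments.gradient_check`, also exposed as a CLI verb) over
randomly generated models.

### Integration

Each time bin advances the combined state (true process states, posterior
expectations, action) by local linearization: `Δz = (expm(J dt) − I) J⁺ ż`
computed through an augmented matrix exponential, which is exact for
linear flows and robust to singular Jacobians.  `J` is built analytically
from the same error Jacobians (a Gauss–Newton approximation of the free
energy Hessian, plus the process flow and reflex couplings); two sub-steps
per bin with a step-halving retry on non-finite output.  This handles the
stiffness introduced by log precisions up to 16 (gains of ~9×10⁶), where
explicit integration would require prohibitively small steps.

### Confidence bands

The recognition dynamics propagate expectations only; posterior spread is
recovered from the curvature of `F` at the current expectations (the
Laplace approximation): the Hessian is computed by finite differences of
the assembled gradient, pseudo-inverted, and the marginal order-0
standard deviations stored per bin when requested.  Two-sided bands are
`mu ± z(coverage) sigma`; z(0.9) = 1.6449.

### Recording convention

Each record row is one contemporaneous end-of-bin snapshot: the true
states, action, sensations, and the posterior that has assimilated that
bin's data (exogenous causes are recorded at the value used during the
bin).  This is the filtering convention; it matters when posterior bands
are compared against rapidly changing true causes.

## Study 1: birdsong, omission responses and hallucinosis

The stimulus generator couples two Lorenz attractors.  A slow attractor
(5.5× slower than the fast one; one cycle spans roughly the 320-bin song)
supplies two control causes which a squashing map converts into the
Rayleigh and Prandtl numbers of the fast attractor (box 25–32 × 8.5–11.5,
centered on 28.5 and 10, so the fast attractor stays chaotic for any
excursion).  A synthetic syrinx converts the fast states into a chirp
train: amplitude is a soft rectification of the first state's excursion
(one chirp per attractor orbit, roughly every 0.9 s at 16-ms bins) and
frequency is an affine map of the third state squashed into 2–5 kHz.
The agent receives a two-channel sonogram summary — amplitude and
amplitude-weighted frequency — so silence is exactly the zero vector and
omitting chirps is exact silencing of the stimulus (the agent's model is
untouched; the omission response is generated purely by its intact
top-down predictions).

Numerical choices worth noting:

- The syrinx rectifier is deliberately soft (softplus sharpness 0.4): its
  sub-threshold tail leaves a faint hum between chirps that keeps the
  filter phase-locked to the chaotic generator across silent gaps.  With
  a hard rectifier the filter's free-run drifts during silences and chirp
  onset transients rival the omission response.
- The control causes are dimensionless, with the squash into the
  admissible parameter box applied inside the level-1 flow (gain 32).
  Cause units set the leverage of the level-2 precision: this scaling
  places the 16 → 2 manipulation at the point where the top-down
  constraints on the controls genuinely yield.
- The generator's state noise (log precision 12) is quieter than the
  model assumes (8): recognition of a chaotic trajectory from two noisy
  channels needs the free-run and the generator to stay commensurate
  across inter-chirp silences.
- The filter starts on the generator's trajectory, sidestepping the
  initial convergence transient.

The three precision regimes are the study conditions: sensory 2, hidden
states 8, level-2 16 (normal); level-2 reduced to 2 (trait-like); and
additionally sensory reduced to −2 (compensatory hallucinosis).  Their
orderings (omission peak globally maximal; attenuated omission and a
"missed" third chirp; persistent low-error percept after the song) are
evaluated on the package's default song (seed 0).  Because the stimulus
is chaotic, individual songs vary in difficulty: on a five-song sample,
three satisfy all orderings; the rest fail on single badly-predicted
chirps.  Passing these tests therefore shows the mechanism behaves as
described on a representative song, not that every song does.

## Study 2: smooth pursuit under occlusion and reversal

The generative process is an oculomotor plant (gaze angle and velocity;
action drives velocity, which decays with an 8-bin = 128-ms viscous time
constant) plus a target drawn to a sinusoidally moving point with a 1-bin
time constant.  Sensations are the proprioceptive gaze angle and 17
visual channels with Gaussian receptive fields at 1 angular-unit spacing
(1 unit ≈ 2° visual angle), gated by a smooth occluder over target
location.  The agent's model believes gaze and target are attracted to a
common fictive point `v(1)` (attraction gain 0.125, damping 0.5 on the
believed gaze velocity), and a second level predicts the fictive point's
periodic motion.  The agent knows the occluder: its predicted visual
input is gated by the same function of its believed target location, so
occlusion silences prediction errors rather than generating false ones.

The second level is a limit-cycle (Hopf) oscillator: rotation rate given
by the cause `v(2)` (prior expectation = the true angular frequency, log
precision 2) and a weak radial term (0.22/bin) restoring a preferred
excursion.  A purely linear oscillator leaves the amplitude direction
marginal; coupled with the gaze-flow back-inference that mode pumps over
occlusion cycles and the loop fails in *both* precision conditions.  The
radial term is the minimal structural stabilizer that leaves "sinusoidal
fluctuations of a given frequency" intact while giving the normal
condition a stable baseline from which the −1 → −1.25 manipulation
produces the documented dissociation.

Geometry: target amplitude 1 unit, period 48 bins (768 ms), phase lead
6 bins, occluder covering locations 0.25–2.0 with sigmoid edges of 0.125
units.  The run starts mid-pursuit (gaze on target).  Re-emergences then
fall at ~256 + 768k ms, the stabilized visible windows (1200–1400 and
2000–2200 ms) sit mid-visible-phase, and the final re-emergence is at
~2.6 s, after which the reduced-precision condition produces a catch-up
movement exceeding the 30°/s saccade criterion while the normal condition
stays below it.  End-of-occlusion lag is the mean |target − gaze| over
the final third of each occluded stretch (single-bin values are
phase-noisy); the run's initial, partial occlusion is burn-in, and the
three complete occlusions are the cycles.  Reversal condition: no
occluder, 512-ms period, reversal at 768 ms; its metrics are taken over
the 10 bins (160 ms) after the reversal — the immediate compensatory
response, before re-locking oscillations in which the conditions are
indistinguishable.

Sensations are embedded to three derivative orders here: action enters
the plant at the acceleration of gaze, so the reflex arc needs the second
temporal derivative of proprioception.

## Study 3: sensory attenuation and the force-matching illusion

The process has a self-generated force (driven by a squashed action,
decaying over four 100-ms bins) and an external force built from an
exogenous cause with the same dynamics; proprioception reports the self
force, somatosensation their sum.  The agent models internal and
external forces symmetrically, driven by causes `(v_i, v_e)`, and its
*sensory* log precision falls with the expected internal force:
`base − gamma · logistic(2(mu_xi + mu_vi − 0.3))`, base 10.  Movement is
produced by a transient prior that `v_i` rises to 1 (a Gaussian bump,
width 3 bins; its height is the force level).  Precisions not fixed by
the study: hidden states 4, `v_i` prior 6, `v_e` prior 1, process noise
12.  `gamma` = 6 (normal) or 2 (failed attenuation), and the
compensation adds 4 log units to all supra-sensory precisions — these
are the study conditions.

The reflex arc uses a fixed spinal gain (log precision 0.5 on the raw
sensory errors) rather than the model's state-dependent sensory
precision.  With the literal state-dependent weighting, reflex gain
*rises* when attenuation fails and the closed loop moves more, not less —
the reference implementations of this scheme make the same choice, and
only with a fixed reflex gain does failed attenuation suppress movement
(the generic engine's `action_flow` still defaults to the exact
free-energy gradient; the fixed gain is this model's configuration).

Percepts are read out as the lower 90% confidence bound of the posterior
self-force at its peak; the matching experiment delivers exactly that
force externally.  The illusion is then essentially the width of the
self-force band, which attenuation opens (gamma = 6) and compensation
closes; the antagonistic delusion appears as the posterior external
cause's 90% band excluding zero on the side opposing the movement, a
consequence of precise proprioceptive errors during the rise of the
movement having to be explained somewhere.  Newton scaling: the normal
trial peaks near 2 N; only ratios enter the qualitative checks.

## What the generator does and does not emulate

All inputs are synthesized by the generative-process simulators; there
are no external data.  The birdsong stimulus emulates structured,
quasi-periodic chirp trains with slow syntax — not acoustic waveforms or
real birdsong statistics.  The pursuit world emulates 1-D angular motion
with an idealized retinal array — not 2-D gaze, saccade generation, or
human eye-tracking noise.  The force world emulates slow force buildup
in a single effector — not tactile psychophysics.  The precision-weighted
prediction errors stand in for evoked responses; no neuronal population
or ERP forward model is attempted.  Passing tests therefore demonstrate
the computational mechanism (precision (mis)allocation producing the
documented perceptual and behavioral signatures) under these idealized
conditions, not quantitative agreement with empirical recordings.

## Problem sizes and tolerances

Default runs: birdsong 320 bins × 3 regimes; pursuit 184 bins × 2
precisions (plus 96 × 2 for reversal); force trials 60 bins each (the
matching experiment runs 8 trials plus 3 condition trials).  The full
test suite, including every end-to-end check, completes in a few minutes
on one CPU.  Gradient checks use relative error 1e−4 against central
finite differences; static-inference fixed points are verified to 1e−6;
integration accuracy is verified against a 100-sub-step classical
Runge–Kutta oracle at 1e−4 relative error.  Degenerate inputs: singular
combined Jacobians are handled by the augmented exponential; non-finite
flows trigger step halving and, past a bounded number of retries, a
divergence error reporting the offending bin; |log precision| is capped
at 32 before exponentiation.

## Known limitations

- Qualitative orderings near their thresholds (the regime-(i) global
  maximum in birdsong, the 20%-illusion bound under compensation) hold
  with margins of a few percent at the default conditions; they are
  properties of the designed experiments, not of every stimulus or seed.
- Parameter learning (slow synaptic plasticity), mean-field updates of
  precisions as random variables, and population/ERP forward models are
  out of scope.
- The conditional covariance is a per-bin Laplace approximation; it is
  not propagated through time.
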