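# Model and methods

This note documents the model implemented in `vtanet`: its equations and
assumptions, the parameters that matter, the numerical choices, the design
decisions taken where the design was genuinely open, and what the
simulations do and do not establish.

## Circuit and unit dynamics

Eleven populations are simulated (sizes in parentheses): IT (9, three
3-unit clusters, one per cue), LH (4, one unit per taste component), BLA
(36), CE (1), PPTN (2), vmPFC (3 banks x 50 oscillators), NAcc (36), VP
(1), LHb (1), RMTg (1), VTA (1).  Except for the vmPFC oscillators, every
unit is a leaky integrator

    tau * dm/dt + m = drive + B + eta(t),     r = (m)+

with tau = 10 ms, additive uniform noise eta in [-0.1, 0.1] redrawn every
step, and baselines B = 0.5 (VP), 1.0 (LHb), 0.2 (VTA), 0 elsewhere.  All
state advances synchronously on a 1-ms forward-Euler grid: typed input
sums from the rates at time t, then phasic filters, then membranes, then
rates, then the accumbens state machine, then plasticity.  Synchronous
updating removes population-ordering artifacts; with dt/tau = 0.1 the
Euler error is below 5% of any step response (see the closed-form test).

**Phasic transform.**  `Phi_{tau,k}(x) = (x - k*xbar)+` with
`tau dxbar/dt + xbar = x`.  A constant input decays to `x (1-k)`; with
k = 1 the output is a pure onset transient.  This *direct* form is the
default everywhere; a *cascade* form `(xbar - k*xbar2)+` (a smooth bump
peaking near t = tau) is available per filter group through
`NetworkConfig` flags.  The direct form is retained because it reproduces
the amygdala's decay to ~20% of its onset peak under sustained input,
which the cascade form cannot.

**Population specifics.**

* BLA: `m = Phi_500,0.8(g_exc) + (1 - Delta_0.1(g_exc)) * Phi_500,0.8(g_mod)
  - g_inh + eta`; hypothalamic (exc) input gates cortical (mod) input off,
  so the taste drive dominates whenever the reward is present.
* PPTN: two mutually inhibiting units (weight 2) with intrinsically phasic
  excitation (`Phi_50,1`), one driven by LH (reward), one by CE (cue).
* VP: shunting inhibition — accumbens input is effective only when PPTN
  excitation is absent: `m = g_exc - (1 - Delta_0.1(g_exc)) * g_inh + 0.5`.
  The printed equation gates the inhibition *on* with excitation, which
  contradicts the narrated omission behavior; the corrected polarity is
  the default and the literal form is available as `vp_gating_printed`.
* LHb/RMTg: LHb has baseline 1 under 3x VP inhibition; RMTg receives
  1.5x LHb and 1x VP inhibition.  The chain is silent at rest and fires
  only when the accumbens silences VP.
* VTA: `m = g_exc * (1 - Phi_300,1(g_mod)) - (1 - Delta_0.1(g_exc)) *
  Phi_30,1(g_inh) + 0.2`, with g_exc = 1.5x PPTN, g_mod the learned
  accumbens projection (multiplicative cancelation of predicted-reward
  bursts), g_inh = RMTg (effective only when excitation is absent).

**Oscillator banks.**  Each cue activates one bank of 50 units whose
frequencies are drawn once per network from U[2, 8] Hz and phases from
U[0, pi].  When a bank's summed cue input crosses 0.8 the current time is
latched as t0 and each unit relaxes (tau = 1 ms) toward
`(1 + sin(2 pi f (t - t0) + phi)) / 2`; below 0.2 the bank is silenced and
reset.  t0 is not refreshed while the bank stays active.

**Accumbens state machine.**  Each unit carries a two-state input s
(down = -0.9, up = -0.4) and a slow trace `tau_s ds_time/dt + s_time = s`
(tau_s = 450 ms).  Up transitions are forced by a dopamine burst
(VTA >= 0.3) or massive glutamatergic drive (>= 1).  The printed
transition lists latch a unit up forever once s_time crosses -0.45; the
default "relaxation" mode instead uses the trace as a relaxation
oscillator (down when s_time rises past -0.45, up when it falls past
-0.85), producing the spontaneous delta-band alternation the model
description calls for.  The literal "latched" mode is retained as an
option and tested.  s_time is initialized uniformly over its working
range so the spontaneous alternation is desynchronized across units.
Rates are clamped to [0, 1.1]; the cortical (mod) drive counts toward the
glutamatergic up-transition threshold, since the amygdalar input alone
(max 0.3) could never reach it.

## Plasticity

All rules are written `eps * dw/dt = RHS` (larger eps = slower learning)
and bounds are enforced after every Euler step.

* Thresholded Hebb (NAcc->VP: eps 100, post threshold 0.5, bounds [0,2];
  NAcc->VTA: eps 500, bounds [0,2]).
* Anti-Hebbian covariance on lateral inhibition, using rectified
  deviations from the instantaneous population mean (BLA<->BLA and
  NAcc<->NAcc).
* Dopamine-modulated covariance with an Oja-style regularization trace
  (LH->BLA and vmPFC->NAcc):
  `dw ~ K * Phi_dopa * OR(pre_dev, post_dev) - alpha * r_post^2 * w`, with
  OR(x, y) = x*y unless both deviations are negative (then 0), and
  `tau_alpha dalpha/dt + alpha = (r_post - 1)+`.  The dopamine factor is
  the phasically filtered dopaminergic input (tau_dopa = 100 ms for the
  amygdala, 10 ms for the accumbens, k = 1), so potentiation is confined
  to burst onsets.
* Dopamine-gated transfer (IT->BLA):
  `dw ~ Delta_0.3(g_dopa) * pre_dev * post_dev * (g_exc - g_mod)+` — the
  cue pathway is potentiated during bursts until its drive matches the
  reward drive, which equalizes cue- and reward-evoked amygdala responses.

For the accumbens rule the presynaptic population mean is computed over
the *synchronized assembly* (the currently active oscillator banks).
Averaging over all 150 units, two thirds of which are silenced, biases
every active unit's deviation positive and produces a DC-loaded kernel:
the accumbens then fires tonically through the delay and the whole
timing/cancelation/omission behavior collapses.  With the assembly mean,
in-phase oscillators gain positive and anti-phase oscillators negative
weights (floor -0.2), i.e. a zero-mean kernel tuned to the reward-time
phase configuration — the coincidence-detection code of the
striatal-beat-frequency mechanism.

**Dopamine-significance floor.**  The phasic filter passes noise-level
transients of the baseline dopamine signal (< 0.05).  Because the
covariance rule is self-reinforcing (a unit that fires at some pattern is
potentiated toward it), this leak produces runaway "parasitic" learning at
harmonic sidelobes of the oscillator kernel, which measurably displaces
the reward-time peak after ~10 trials and makes the burst cancelation
rebound.  Dopamine-modulated learning is therefore engaged only when the
phasic factor exceeds a floor (0.05 amygdala, 0.03 accumbens) — i.e. only
when dopamine is significantly above baseline, which is the stated role of
the filter.  Both floors sit above the measured noise band (~0.03) and far
below any burst transient (0.25-1.5).

## Calibration choices

Four parameters were set by this package where the printed values could
not reproduce the system-level behavior they are credited with; all other
parameters are as tabulated in the source description.

* **LH->BLA upper weight bound 0.5** (top of the initial range 0.3+-0.2;
  no bound printed).  The three taste patterns overlap and one is a strict
  subset of another; with unbounded per-synapse weights the shared-taste
  weights of any winner grow until it captures every reward (verified to
  be an attractor even from hand-separated initial conditions).  The cap
  makes the unique taste component decisive and one-winner-per-reward
  selectivity emerges in 10/10 seeds.
* **LH->BLA eps 1000 during sensitization** (conditioning remains 100x
  slower).  At eps = 100 a single reward presentation saturates every
  transiently co-active unit at the bound before competition can act,
  leaving degenerate weight ties; 1000 gives convergence over ~5-10
  presentations, matching the 10-trial sensitization schedule.
* **IT->BLA eps 1000.**  At eps = 300 the cue transfer completes within
  1-2 trials instead of the gradual ~5-10-trial rise of the cue burst,
  and the resulting early accumbens cue-response truncates later cue
  bursts.
* **BLA lateral inhibition: initial weight 1.0, eps 30.**  The anti-
  Hebbian competition is what singles out one amygdala unit per reward;
  at the printed strength/speed it cannot resolve a winner at low reward
  magnitudes (drive differences are smaller than the membrane noise), and
  reward responses lose their magnitude proportionality.

The sensitization phase presents the three rewards interleaved in
ascending order (like the conditioning trials), not blocked: with blocked
presentation the later blocks erode the earlier winners' overlapping
taste weights and the per-reward code does not survive.

## Synthetic protocols

Trials are generated programmatically: 1 s reset, cue onset at 1 s, reward
after the association's interval (2/3/4 s) for 1 s with the cue
maintained, 1 s settle.  Omission trials keep the cue timeline without the
reward; early-delivery trials move the reward 1 s forward and end the cue
with it; sensitization trials are 1 s reset / 1 s reward / 1 s settle.
The three associations use overlapping binary taste vectors with
magnitudes 0.8 / 0.5 / 1.0.  The probe schedule follows every conditioning
trial with a learning-off omission probe; the magnitude sweep trains fresh
networks on the first association only.  These protocols emulate
controlled conditioning experiments with noiseless stimulus timing; they
do not model stimulus-sampling variability, trace (gap) conditioning,
probabilistic reward, or motivational state, so passing tests speak to the
circuit mechanism, not to behavioral variability in real animals.

## Numerics, sizes and reproducibility

dt = 1 ms; all simulations are driven by a single `numpy` Generator per
network, and every schedule derives its replicate seeds from one master
seed, so (configuration, seed) determines every output bit-for-bit.  An
optional numba kernel executes whole trials (~12 us/step vs ~300 us for
the numpy reference); both paths consume the identical pre-drawn noise
stream and a test asserts their trajectories agree to ~1e-9.  The full
standard protocol is 375 s of simulated time (~5 s wall with the kernel);
the test suite uses three seeds for trained-network checks, two for the
probe schedule, and a reduced sweep (5 magnitudes x 3 networks); the
acceptance script uses a 12-point grid x 3 networks.

Degenerate inputs: zero-magnitude rewards produce no learning and no
responses beyond noise; the burst-duration metric returns 0 for flat
traces; window metrics raise on out-of-range windows; a missing or
duplicated projection row fails configuration validation by name.

## Known limitations

* The trained reward-burst maximum settles near 0.45 rather than inside
  the published 0.3-0.4 band: the residual is the burst onset sliver that
  escapes before the accumbens reacts (~25-50 ms loop latency), and its
  height trades off against the residual duration (which does match).
* The magnitude-0.5 association acquires its interval code more slowly
  than published (first omission dip after ~13+ conditioning trials or
  not at all, vs 7): its bursts sit near the engagement threshold of the
  dopamine-gated accumbens loop in this calibration.  Consequently the
  sweep thresholds land near 0.2 (cue responses) and 0.6-0.7 (burst
  cancelation) instead of 0.1 and 0.4 — the qualitative threshold
  structure is reproduced, shifted toward larger magnitudes.
* The cue burst of the largest association declines somewhat late in
  training (its accumbens cue response partially truncates the burst), so
  its cue-trend correlation is not monotone.
* Up/down-state alternation is a phenomenological relaxation oscillator,
  not a biophysical bistability model, and the oscillator banks abstract
  a synchronized cortical network rather than modeling how synchronization
  arises.
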