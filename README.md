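# vtanet

A rate-coded neuro-computational model of the afferent network to the
ventral tegmental area (VTA) during appetitive delay conditioning.

## The scientific problem

During Pavlovian conditioning, midbrain dopaminergic neurons fire a phasic
burst for an unexpected reward, gradually stop responding to the reward as
it becomes predicted, start bursting at the onset of the predicting cue,
and pause completely when a predicted reward is omitted.  Reproducing this
pattern requires the brain to *learn the cue-reward interval*.  `vtanet`
implements a circuit-level account of where those signals come from:

* **IT -> BLA/CE -> PPTN** — the basolateral amygdala associates the visual
  cue (CS) with the taste representation of the reward (US, lateral
  hypothalamus) under dopamine-modulated plasticity, and relays cue value
  to the pedunculopontine nucleus, which drives VTA bursts.
* **vmPFC -> NAcc** — a striatal-beat-frequency timer: banks of cortical
  oscillators (2–8 Hz) are synchronized at cue onset, and bistable
  (up/down-state) accumbens units learn, by dopamine-gated covariance
  learning, to detect the oscillator configuration present at the moment
  of reward — a population code for elapsed time.
* **NAcc -> VTA** and **NAcc -> VP -> LHb -> RMTg -> VTA** — the timed
  accumbens signal cancels the reward burst directly, and, when the reward
  fails to arrive, inhibits the ventral pallidum, disinhibiting the
  lateral habenula / rostromedial tegmental pathway that silences VTA
  (the omission dip).

Every population is a leaky-integrator rate unit,
`tau dm/dt + m = drive + B + eta`, `r = (m)+`, advanced with forward Euler
at 1 ms.  Onset transients are produced by a phasic transform
`Phi(x) = (x - k*xbar)+` where `xbar` is a running average of `x`.  Four
plasticity rules (thresholded Hebb, anti-Hebbian covariance,
dopamine-modulated covariance with an Oja-style homeostatic trace, and a
dopamine-gated transfer rule) shape the seven learnable projections.  See
`docs/methods.md` for the full model description and design choices.

The package is aimed at computational-neuroscience users who want to
simulate, perturb (virtual lesions, gating variants, state-machine modes)
and analyze this circuit from Python.

## A worked example

```python
from vtanet import build_network, run_standard_protocol, window_extremum

net = build_network(rng=1)
result = run_standard_protocol(net, record=("VTA",))
for k in (0, 14):
    trace = result.trials(1)[k]["VTA"]        # association 1: 2-s interval
    print(k + 1, round(window_extremum(trace, 1000, 100, "max"), 2),
          round(window_extremum(trace, 3000, 100, "max"), 2))
```

prints (cue-burst and reward-burst maxima, baseline 0.2):

```
1 0.25 1.21
15 0.91 0.46
```

— on trial 1 the dopaminergic unit responds only to the reward (1.21);
after 15 conditioning trials the reward burst has collapsed toward
baseline (0.46) while a cue burst has appeared (0.87).  The scripts in
`examples/` walk through the omission dip, the reward-magnitude sweep and
the internals of the accumbens interval timer the same way.

A thin CLI wraps the same runners:

```bash
vtanet simulate --seed 1 --out results/standard
vtanet probes   --seed 1 --out results/probes
vtanet sweep    --ci-preset --out results/sweep
```

Each command writes CSV traces/metrics, a `config_used.yaml` that
reproduces the run exactly, and figures rendered from the CSVs.

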