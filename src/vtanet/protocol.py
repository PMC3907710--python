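"""Trial construction and experiment schedules.

A conditioning trial is built as: 1 s reset (no input), cue (CS) onset at
t = 1 s, reward (US) delivery after the association's interval with the CS
maintained, 1 s of US, then 1 s of settling — total duration interval + 3 s.
Omission trials keep the CS timeline but never set the US; early-delivery
trials move the US 1 s earlier and terminate the CS with the US;
sensitization trials present the US alone (1 s reset / 1 s US / 1 s settle).

The standard schedule is 10 sensitization trials per reward (blocked), then
45 conditioning trials with the three associations interleaved in ascending
order; the hypothalamus-to-amygdala learning-rate divisor switches from 100
to 10,000 at the phase boundary.  Variants add interleaved learning-off
omission probes (acquisition-speed measurements) or sweep the reward
magnitude across freshly built networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import has_sub_criterion_run, window_extremum
from .network import Network, NetworkConfig, build_network
from .recording import Recorder, TraceRecording

__all__ = [
    "Association",
    "ASSOCIATIONS",
    "TrialSpec",
    "StimulusTimeline",
    "Schedule",
    "make_trial",
    "run_trial",
    "run_sensitization",
    "run_standard_protocol",
    "run_probe_schedule",
    "run_magnitude_sweep",
    "summarize_sweep",
    "StandardProtocolResult",
    "ProbeMetrics",
]


@dataclass(frozen=True)
class Association:
    """One CS-US pairing: cue vector, taste vector, magnitude, interval (s)."""

    cs_vec: tuple[float, ...]
    us_vec: tuple[float, ...]
    magnitude: float
    interval: float


#: The three cue-reward associations used throughout: overlapping taste
#: vectors, magnitudes 0.8 / 0.5 / 1.0 and intervals 2 / 3 / 4 s.
ASSOCIATIONS: dict[int, Association] = {
    1: Association((1, 0, 0), (1, 1, 0, 0), 0.8, 2.0),
    2: Association((0, 1, 0), (1, 0, 1, 0), 0.5, 3.0),
    3: Association((0, 0, 1), (1, 0, 1, 1), 1.0, 4.0),
}


@dataclass
class TrialSpec:
    """Specification of a single trial."""

    assoc_id: int
    variant: str = "paired"      # paired | omission | early | sensitization
    magnitude: float | None = None   # None: the association's magnitude
    interval: float | None = None    # seconds, None: the association's
    learning_on: bool = True

    def __post_init__(self) -> None:
        if self.assoc_id not in ASSOCIATIONS:
            raise ValueError(f"unknown association {self.assoc_id}")
        if self.variant not in ("paired", "omission", "early", "sensitization"):
            raise ValueError(f"unknown trial variant {self.variant!r}")
        a = ASSOCIATIONS[self.assoc_id]
        if self.magnitude is None:
            self.magnitude = a.magnitude
        if self.interval is None:
            self.interval = a.interval
        if self.variant == "early" and self.interval <= 1.0:
            raise ValueError("early delivery needs an interval above 1 s")

    @property
    def cs_vec(self) -> np.ndarray:
        cs = np.array(ASSOCIATIONS[self.assoc_id].cs_vec, dtype=float)
        return np.zeros_like(cs) if self.variant == "sensitization" else cs

    @property
    def us_vec(self) -> np.ndarray:
        return np.array(ASSOCIATIONS[self.assoc_id].us_vec, dtype=float)


@dataclass
class StimulusTimeline:
    """Millisecond-resolved CS/US input streams for one trial."""

    cs: np.ndarray            # (n_steps, 3)
    us: np.ndarray            # (n_steps, 4)
    magnitude: float
    events: dict[str, int]    # onset/offset times in ms from trial start
    spec: TrialSpec

    @property
    def n_steps(self) -> int:
        return self.cs.shape[0]


def make_trial(spec: TrialSpec) -> StimulusTimeline:
    """Lay out one trial's stimulus timeline on the millisecond grid."""
    iv = int(round(spec.interval * 1000))
    cs_vec, us_vec = spec.cs_vec, spec.us_vec
    events: dict[str, int] = {}

    if spec.variant == "sensitization":
        n = 3000
        cs = np.zeros((n, 3))
        us = np.zeros((n, 4))
        us[1000:2000] = us_vec
        events.update(us_onset=1000, us_offset=2000)
    elif spec.variant == "paired":
        n = iv + 3000
        cs = np.zeros((n, 3))
        us = np.zeros((n, 4))
        cs[1000:1000 + iv + 1000] = cs_vec
        us[1000 + iv:1000 + iv + 1000] = us_vec
        events.update(cs_onset=1000, us_onset=1000 + iv,
                      us_offset=2000 + iv, cs_offset=2000 + iv)
    elif spec.variant == "omission":
        n = iv + 3000
        cs = np.zeros((n, 3))
        us = np.zeros((n, 4))
        cs[1000:1000 + iv + 1000] = cs_vec
        events.update(cs_onset=1000, expected_us=1000 + iv,
                      cs_offset=2000 + iv)
    else:  # early: US arrives 1 s before the trained time, CS ends with it
        n = iv + 2000
        cs = np.zeros((n, 3))
        us = np.zeros((n, 4))
        us_on = 1000 + iv - 1000
        cs[1000:us_on + 1000] = cs_vec
        us[us_on:us_on + 1000] = us_vec
        events.update(cs_onset=1000, us_onset=us_on, us_offset=us_on + 1000,
                      cs_offset=us_on + 1000, trained_us=1000 + iv)
    return StimulusTimeline(cs=cs, us=us, magnitude=float(spec.magnitude),
                            events=events, spec=spec)


@dataclass
class Schedule:
    """An ordered list of trials with the phase boundary marked."""

    trials: list[TrialSpec]
    phase_switch_index: int   # first conditioning trial (eps switch point)

    @classmethod
    def standard(cls, n_sensitization: int = 10, n_conditioning: int = 15,
                 assoc_ids=(1, 2, 3)) -> "Schedule":
        trials = [TrialSpec(a, "sensitization")
                  for a in assoc_ids for _ in range(n_sensitization)]
        switch = len(trials)
        for _ in range(n_conditioning):
            trials.extend(TrialSpec(a, "paired") for a in assoc_ids)
        return cls(trials=trials, phase_switch_index=switch)


def run_trial(net: Network, timeline: StimulusTimeline,
              learning_on: bool | None = None,
              record=("VTA",), engine: str = "auto") -> TraceRecording:
    """Simulate one trial; returns the recording of the selected traces.

    ``engine`` selects the compiled kernel ("numba", the default when
    available) or the reference numpy implementation ("numpy"); both
    consume the same pre-drawn noise stream.
    """
    from ._kernel import HAVE_NUMBA, simulate_trial

    if learning_on is None:
        learning_on = timeline.spec.learning_on
    n = timeline.n_steps
    cs, us, mag = timeline.cs, timeline.us, timeline.magnitude
    amp = net.cfg.noise_amp
    noise = net.rng.uniform(-amp, amp, size=(n, net._n_noise))
    if engine == "auto":
        engine = "numba" if HAVE_NUMBA else "numpy"
    if engine == "numba":
        data = simulate_trial(net, cs, us, mag, learning_on, noise, record)
        out = TraceRecording(n_steps=n, dt=net.cfg.dt, data=data)
    elif engine == "numpy":
        rec = Recorder(net, n, record)
        for i in range(n):
            net.step(cs[i], us[i], mag, learning_on, noise=noise[i])
            rec.capture(i)
        out = rec.rec
    else:
        raise ValueError(f"unknown engine {engine!r}")
    out.events = dict(timeline.events)
    out.assoc_id = timeline.spec.assoc_id
    out.variant = timeline.spec.variant
    return out


@dataclass
class StandardProtocolResult:
    net: Network
    conditioning: list[TraceRecording] = field(default_factory=list)
    sensitization: list[TraceRecording] = field(default_factory=list)

    def trials(self, assoc_id: int) -> list[TraceRecording]:
        """Conditioning trials of one association, in order."""
        return [t for t in self.conditioning if t.assoc_id == assoc_id]


def run_sensitization(net: Network, assoc_ids=(1, 2, 3),
                      n_trials: int = 10, record=()) -> list[TraceRecording]:
    """US-alone exposure with fast amygdalar learning.

    The rewards are interleaved in ascending order (1,2,3,1,2,3,...), like
    the conditioning trials.  Presenting each reward as a block instead
    lets the early-block winners be eroded by the later blocks (the taste
    vectors overlap), which destroys the one-cell-per-reward code.
    """
    net.set_conditioning_phase(False)
    traces = []
    for k in range(n_trials):
        for a in assoc_ids:
            tl = make_trial(TrialSpec(a, "sensitization"))
            tr = run_trial(net, tl, learning_on=True, record=record)
            tr.trial_index = k + 1
            traces.append(tr)
    return traces


def run_standard_protocol(net: Network, n_sensitization: int = 10,
                          n_conditioning: int = 15, assoc_ids=(1, 2, 3),
                          record=("VTA",), record_sensitization=()):
    """Sensitization followed by interleaved conditioning.

    Returns a :class:`StandardProtocolResult` with per-trial recordings;
    ``record`` selects the populations stored for conditioning trials.
    """
    result = StandardProtocolResult(net=net)
    result.sensitization = run_sensitization(
        net, assoc_ids, n_sensitization, record=record_sensitization)
    net.set_conditioning_phase(True)
    counters = {a: 0 for a in assoc_ids}
    for _ in range(n_conditioning):
        for a in assoc_ids:
            tl = make_trial(TrialSpec(a, "paired"))
            tr = run_trial(net, tl, learning_on=True, record=record)
            counters[a] += 1
            tr.trial_index = counters[a]
            result.conditioning.append(tr)
    return result


@dataclass
class ProbeMetrics:
    """Summary of one learning-off omission probe."""

    assoc_id: int
    trial_index: int      # conditioning trial the probe followed (1-based)
    min_vta: float        # minimum VTA rate in the second after expected US
    max_nacc: float       # maximum NAcc rate within +-100 ms of expected US
    dipped: bool          # >= 20 consecutive ms below the dip criterion


def run_probe_schedule(net: Network, n_sensitization: int = 10,
                       n_conditioning: int = 15, assoc_ids=(1, 2, 3),
                       dip_criterion: float = 0.05,
                       min_dip_run_ms: int = 20):
    """Conditioning with a learning-off omission probe after every trial.

    The probes measure how fast the cue-reward interval is acquired: the
    minimum VTA rate in the second following the expected reward time and
    the maximum accumbens rate around it, without touching the weights.
    """
    run_sensitization(net, assoc_ids, n_sensitization)
    net.set_conditioning_phase(True)
    metrics: list[ProbeMetrics] = []
    counters = {a: 0 for a in assoc_ids}
    for _ in range(n_conditioning):
        for a in assoc_ids:
            run_trial(net, make_trial(TrialSpec(a, "paired")),
                      learning_on=True, record=())
            counters[a] += 1
            probe = run_trial(net, make_trial(TrialSpec(a, "omission")),
                              learning_on=False, record=("VTA", "NAcc"))
            t_us = probe.events["expected_us"]
            vta = probe["VTA"]
            post = vta[t_us:t_us + 1000]
            nacc_max = window_extremum(probe["NAcc"].max(axis=1), t_us, 100,
                                       "max")
            metrics.append(ProbeMetrics(
                assoc_id=a, trial_index=counters[a],
                min_vta=float(post.min()),
                max_nacc=float(nacc_max),
                dipped=has_sub_criterion_run(post, dip_criterion,
                                             min_dip_run_ms),
            ))
    return metrics, net


def run_magnitude_sweep(magnitudes, n_networks: int = 10,
                        seed: int | None = 0, assoc_id: int = 1,
                        n_sensitization: int = 10, n_conditioning: int = 15,
                        cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """Reward-magnitude sweep with one association trained per network.

    For every magnitude and replicate network: sensitization to the single
    reward, then 15 conditioning trials.  The amygdala (selected unit) and
    VTA maxima in the cue window (900-1100 ms) and reward window
    (interval +- 100 ms) are extracted on the first and last trial.

    Returns a tidy frame with one row per (magnitude, network, trial).
    """
    iv = ASSOCIATIONS[assoc_id].interval
    t_cs, t_us = 1000, int(1000 + iv * 1000)
    children = np.random.SeedSequence(seed).spawn(n_networks)
    rows = []
    for j, child in enumerate(children):
        for mag in magnitudes:
            net = build_network(cfg, np.random.default_rng(child))
            for _ in range(n_sensitization):
                tl = make_trial(TrialSpec(assoc_id, "sensitization",
                                          magnitude=mag))
                run_trial(net, tl, learning_on=True, record=())
            net.set_conditioning_phase(True)
            for k in range(1, n_conditioning + 1):
                want = k in (1, n_conditioning)
                tl = make_trial(TrialSpec(assoc_id, "paired", magnitude=mag))
                tr = run_trial(net, tl, learning_on=True,
                               record=("VTA", "BLA") if want else ())
                if want:
                    bla = tr["BLA"].max(axis=1)
                    vta = tr["VTA"]
                    rows.append({
                        "magnitude": float(mag), "network": j, "trial": k,
                        "cs_bla": window_extremum(bla, t_cs, 100, "max"),
                        "us_bla": window_extremum(bla, t_us, 100, "max"),
                        "cs_vta": window_extremum(vta, t_cs, 100, "max"),
                        "us_vta": window_extremum(vta, t_us, 100, "max"),
                    })
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation over networks per magnitude and trial."""
    keys = ["cs_bla", "us_bla", "cs_vta", "us_vta"]
    g = df.groupby(["magnitude", "trial"])[keys]
    out = g.agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
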