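"""Metric extraction from recorded traces.

Event-locked extrema (the maximal/minimal rate within +-100 ms of cue or
reward onset), burst durations (contiguous time above a threshold around
the window peak), acquisition curves from omission probes, and the
selectivity census of the amygdala after sensitization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EventMetrics",
    "window_extremum",
    "burst_duration",
    "has_sub_criterion_run",
    "trials_to_dip",
    "selectivity_census",
    "burst_series",
    "NOT_ACQUIRED",
]

#: Sentinel returned when no probe ever reaches the dip criterion.
NOT_ACQUIRED = -1

#: Default burst threshold: VTA baseline (0.2) + 0.05, separating the noise
#: band around baseline from bursts of 0.3 and above.
BURST_THRESHOLD = 0.25

#: Default dip criterion on the VTA rate (0 plus noise headroom).
DIP_CRITERION = 0.05


@dataclass
class EventMetrics:
    """Per-trial event-locked VTA measurements."""

    trial_index: int
    cs_burst: float
    us_burst: float
    dip_min: float = np.nan
    burst_duration_ms: float = np.nan


def window_extremum(trace: np.ndarray, t_event: float, half_width: float,
                    mode: str, dt: float = 1.0) -> float:
    """Extremum of ``trace`` over ``[t_event - hw, t_event + hw]`` (ms).

    Raises ``ValueError`` when the window falls outside the trace.
    """
    lo = int(round((t_event - half_width) / dt))
    hi = int(round((t_event + half_width) / dt)) + 1
    if lo < 0 or hi > trace.shape[0]:
        raise ValueError(
            f"window [{t_event - half_width}, {t_event + half_width}] ms "
            f"outside trace of length {trace.shape[0] * dt} ms")
    seg = trace[lo:hi]
    if mode == "max":
        return float(seg.max())
    if mode == "min":
        return float(seg.min())
    raise ValueError("mode must be 'max' or 'min'")


def burst_duration(trace: np.ndarray, t_event: float,
                   threshold: float = BURST_THRESHOLD,
                   half_width: float = 100.0, dt: float = 1.0) -> float:
    """Length (ms) of the contiguous supra-threshold run around the peak.

    The peak is located within +-``half_width`` of ``t_event``; the run is
    the maximal contiguous stretch containing it where the rate exceeds
    ``threshold``.  Returns 0 when the peak itself is below threshold.
    """
    lo = int(round((t_event - half_width) / dt))
    hi = int(round((t_event + half_width) / dt)) + 1
    if lo < 0 or hi > trace.shape[0]:
        raise ValueError("event window outside trace")
    peak = lo + int(np.argmax(trace[lo:hi]))
    if trace[peak] <= threshold:
        return 0.0
    above = trace > threshold
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak
    n = trace.shape[0]
    while end + 1 < n and above[end + 1]:
        end += 1
    return (end - start + 1) * dt


def has_sub_criterion_run(trace: np.ndarray, criterion: float,
                          min_run_ms: float, dt: float = 1.0) -> bool:
    """True when the trace stays below ``criterion`` for >= ``min_run_ms``."""
    below = trace < criterion
    need = int(round(min_run_ms / dt))
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= need:
            return True
    return False


def trials_to_dip(probe_metrics, assoc_id: int,
                  use_dip_flag: bool = True,
                  dip_criterion: float = DIP_CRITERION) -> int:
    """Number of conditioning trials before the first probe with a dip.

    ``probe_metrics`` is the list produced by the probe schedule.  Returns
    the 1-based conditioning-trial index of the first probe of the given
    association whose VTA activity dips (a sustained run below criterion
    when ``use_dip_flag``, else simply a minimum below it), or
    ``NOT_ACQUIRED`` when no probe qualifies.
    """
    for m in probe_metrics:
        if m.assoc_id != assoc_id:
            continue
        hit = m.dipped if use_dip_flag else (m.min_vta < dip_criterion)
        if hit:
            return m.trial_index
    return NOT_ACQUIRED


def selectivity_census(bla_traces: dict[int, np.ndarray],
                       us_windows: dict[int, tuple[float, float]],
                       threshold: float = 0.5, dt: float = 1.0):
    """Winner counts per reward after sensitization.

    Parameters
    ----------
    bla_traces : mapping assoc_id -> (time x units) amygdala rates recorded
        while that reward was presented alone.
    us_windows : mapping assoc_id -> (t_event, half_width) in ms.

    Returns
    -------
    dict assoc_id -> (n_selective, winner_index) where ``n_selective`` is
    the number of units whose window maximum exceeds ``threshold``.
    """
    out = {}
    for a, trace in bla_traces.items():
        t_event, hw = us_windows[a]
        lo = int(round((t_event - hw) / dt))
        hi = int(round((t_event + hw) / dt)) + 1
        peaks = trace[lo:hi].max(axis=0)
        out[a] = (int((peaks > threshold).sum()), int(np.argmax(peaks)))
    return out


def burst_series(traces, event: str, half_width: float = 100.0):
    """CS/US window maxima of the VTA trace across conditioning trials.

    ``traces`` is a list of per-trial recordings of one association (with a
    "VTA" trace); ``event`` names the recorded event timestamp ("cs_onset"
    or "us_onset").  Returns an array ordered by trial.
    """
    vals = []
    for tr in sorted(traces, key=lambda t: t.trial_index):
        vals.append(window_extremum(tr["VTA"], tr.events[event],
                                    half_width, "max", tr.dt))
    return np.array(vals)
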