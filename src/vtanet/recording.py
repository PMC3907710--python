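"""Per-trial recording of population activity.

A :class:`TraceRecording` stores uniformly sampled (1 ms) time series of
firing rates for the populations selected by the caller, plus auxiliary
series (accumbens state variables) and event timestamps (cue onset, reward
onset) used by the analysis routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraceRecording", "Recorder", "RECORDABLE"]

#: population name -> (getter attribute, width attribute or None for scalar)
RECORDABLE = {
    "IT": ("r_it", "n_it"),
    "LH": ("r_lh", "n_lh"),
    "BLA": ("r_bla", "n_bla"),
    "CE": ("r_ce", None),
    "PPTN": ("r_pptn", "n_pptn"),
    "vmPFC": ("r_pfc", "n_pfc"),
    "NAcc": ("r_nacc", "n_nacc"),
    "NAcc_m": ("m_nacc", "n_nacc"),
    "NAcc_s": ("s", "n_nacc"),
    "NAcc_s_time": ("s_time", "n_nacc"),
    "VP": ("r_vp", None),
    "LHb": ("r_lhb", None),
    "RMTg": ("r_rmtg", None),
    "VTA": ("r_vta", None),
}


@dataclass
class TraceRecording:
    """Rates (time x units) for one trial, sampled every ``dt`` ms."""

    n_steps: int
    dt: float = 1.0
    data: dict[str, np.ndarray] = field(default_factory=dict)
    events: dict[str, float] = field(default_factory=dict)
    trial_index: int = 0
    assoc_id: int = 0
    variant: str = "paired"

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def unit(self, name: str, index: int) -> np.ndarray:
        """Single-unit time series (scalar populations ignore ``index``)."""
        arr = self.data[name]
        return arr if arr.ndim == 1 else arr[:, index]


class Recorder:
    """Preallocates and fills the arrays of a :class:`TraceRecording`."""

    def __init__(self, net, n_steps: int, populations) -> None:
        self.rec = TraceRecording(n_steps=n_steps, dt=net.cfg.dt)
        self._getters = []
        for name in populations:
            attr, width = RECORDABLE[name]
            if width is None:
                buf = np.empty(n_steps)
            else:
                buf = np.empty((n_steps, getattr(net.cfg, width)))
            self.rec.data[name] = buf
            self._getters.append((name, attr, buf))
        self._net = net

    def capture(self, i: int) -> None:
        for _, attr, buf in self._getters:
            buf[i] = getattr(self._net, attr)
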