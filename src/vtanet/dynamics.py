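"""Generic rate-coded building blocks.

Every population in the circuit is built from the same primitives: a leaky
integrator on the membrane potential whose firing rate is the positive part,
typed weighted input sums, a phasic transform that converts the onset of a
tonic input into a transient, a hard threshold gate, and additive uniform
noise.  All dynamics are advanced with the forward Euler method on a fixed
grid (1 ms by default).

The membrane potential of a typical unit obeys

    tau * dm/dt + m = drive + B + eta(t),       r = max(m, 0)

where ``drive`` collects the population-specific combination of typed input
sums, ``B`` is the unit's baseline and ``eta`` is uniform noise redrawn at
every step.

The phasic transform ``Phi`` maintains a running average ``xbar`` of its
input ``x`` with time constant ``tau``:

    tau * dxbar/dt + xbar = x,      Phi(x) = max(x - k * xbar, 0)

With retention ``k = 1`` the output is a transient that decays back to zero
under constant input; with ``k = 0`` the input passes through unchanged;
intermediate values retain a fraction ``1 - k`` of a sustained input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DT",
    "NOISE_AMP",
    "PhasicFilter",
    "UnitState",
    "TypedInputs",
    "weighted_sum",
    "threshold_gate",
    "draw_noise",
    "euler_membrane",
]

#: Integration time step in milliseconds.
DT: float = 1.0

#: Default half-width of the additive uniform membrane noise.
NOISE_AMP: float = 0.1


def weighted_sum(weights, rates) -> float:
    """Weighted sum of presynaptic rates, ``sum_i w_i * r_i``.

    Raises
    ------
    ValueError
        If the two vectors differ in length (a wiring/configuration error).
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(rates, dtype=float)
    if w.shape != r.shape:
        raise ValueError(
            f"weight/rate length mismatch: {w.shape} vs {r.shape}"
        )
    return float(w @ r) if w.ndim == 1 else float(np.sum(w * r))


def threshold_gate(x, gamma):
    """Hard gate: 0 where ``x < gamma``, 1 otherwise (equality counts as 1).

    Works element-wise on arrays; scalars return a float.
    """
    out = np.where(np.asarray(x) < gamma, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def draw_noise(rng: np.random.Generator, n: int, amp: float = NOISE_AMP):
    """Draw ``n`` independent uniform values in ``[-amp, amp]``."""
    if amp < 0:
        raise ValueError("noise amplitude must be non-negative")
    if amp == 0.0:
        return np.zeros(n)
    return rng.uniform(-amp, amp, size=n)


def euler_membrane(m, drive, tau: float, dt: float = DT, baseline=0.0, noise=0.0):
    """One forward-Euler step of ``tau*dm/dt + m = drive + B + eta``.

    ``m`` may be a scalar or an array; the updated value is returned (arrays
    are updated in place as well).  ``drive`` must already contain every
    input term except the baseline and noise.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite drive in membrane update")
    return m + (dt / tau) * (drive + baseline + noise - m)


@dataclass
class PhasicFilter:
    """State of the phasic transform ``Phi_{tau,k}``.

    Parameters
    ----------
    tau : float
        Time constant of the running average, in ms.
    k : float
        Retention parameter in [0, 1]; the sustained output of a constant
        input ``x`` is ``x * (1 - k)``.
    xbar : float or ndarray
        Running average; use an array for per-unit filtering.
    """

    tau: float
    k: float
    xbar: np.ndarray | float = 0.0
    cascade: bool = False
    xbar2: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("phasic filter tau must be positive")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("retention k must lie in [0, 1]")

    def step(self, x, dt: float = DT):
        """Advance the running average(s) one Euler step and return Phi(x).

        Direct form (default): ``(x - k*xbar)+`` with ``xbar`` tracking x.
        Cascade form: ``(xbar - k*xbar2)+`` with ``xbar2`` tracking xbar,
        which turns a step input into a smooth bump peaking at ``t = tau``
        (for k=1) instead of an instant onset transient.
        """
        self.xbar = self.xbar + (dt / self.tau) * (x - self.xbar)
        if self.cascade:
            self.xbar2 = self.xbar2 + (dt / self.tau) * (self.xbar - self.xbar2)
            return np.maximum(self.xbar - self.k * self.xbar2, 0.0)
        return np.maximum(x - self.k * self.xbar, 0.0)

    def reset(self) -> None:
        self.xbar = np.zeros_like(self.xbar) if np.ndim(self.xbar) else 0.0
        self.xbar2 = np.zeros_like(self.xbar2) if np.ndim(self.xbar2) else 0.0


@dataclass
class TypedInputs:
    """Per-unit weighted input sums, one slot per synapse type."""

    g_exc: np.ndarray | float = 0.0
    g_inh: np.ndarray | float = 0.0
    g_mod: np.ndarray | float = 0.0
    g_dopa: np.ndarray | float = 0.0


@dataclass
class UnitState:
    """A single leaky-integrator unit (scalar convenience wrapper).

    The network itself advances whole populations with vectorized calls to
    :func:`euler_membrane`; this class exposes the same arithmetic for one
    unit, which is handy for closed-form checks and small scripts.
    """

    m: float = 0.0
    tau: float = 10.0
    B: float = 0.0
    noise_amp: float = NOISE_AMP
    r: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("membrane time constant must be positive")
        self.r = max(self.m, 0.0)

    def step(self, drive: float, rng: np.random.Generator | None = None,
             dt: float = DT) -> "UnitState":
        eta = 0.0
        if rng is not None and self.noise_amp > 0:
            eta = rng.uniform(-self.noise_amp, self.noise_amp)
        self.m = float(euler_membrane(self.m, drive, self.tau, dt,
                                      baseline=self.B, noise=eta))
        self.r = max(self.m, 0.0)
        return self
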