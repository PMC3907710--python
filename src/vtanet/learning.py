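"""Plasticity rules.

Four rules drive weight changes in the circuit, all expressed as
``eps * dw/dt = RHS`` so that a larger ``eps`` means *slower* learning:

* thresholded Hebbian (accumbens -> pallidum / accumbens -> VTA),
* covariance / anti-Hebbian (lateral inhibition in amygdala and accumbens),
* dopamine-modulated covariance with an Oja-style homeostatic trace
  (hypothalamus -> amygdala and prefrontal oscillators -> accumbens),
* dopamine-gated transfer rule (cortex -> amygdala), which copies the
  reward-evoked response onto the cue pathway until both drives match.

Weight matrices are stored as ``(n_post, n_pre)`` so that the typed input
sum of postsynaptic unit ``j`` is ``W[j] @ r_pre``.  Bounds are enforced
after every Euler step.  The dopamine factor of the modulated covariance
rule is the output of the phasic transform applied to the projection's
dopaminergic input, so potentiation is confined to burst onsets.

These kernels sit on the simulation's hot path; pre/post rates must be
passed as 1-D float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DT, threshold_gate

__all__ = [
    "PlasticityParams",
    "RegularizerState",
    "hebbian_threshold_update",
    "covariance_update",
    "da_covariance_update",
    "regularizer_step",
    "modulated_transfer_update",
    "or_product",
]

_INF = float("inf")


@dataclass
class PlasticityParams:
    """Parameters of one learnable projection.

    ``eps`` is the learning-rate divisor (a time constant, in ms); the
    remaining fields are only read by the rules that use them.
    """

    eps: float
    w_min: float = 0.0
    w_max: float = _INF
    theta_pre: float = 0.0
    theta_post: float = 0.0
    K: float = 0.0              # dopamine gain (modulated covariance rule)
    tau_dopa: float = 1.0       # ms, phasic filter on the dopamine input
    k_dopa: float = 1.0
    tau_alpha: float = 1.0      # ms, regularization trace
    r_max: float = 1.0          # postsynaptic rate engaging regularization
    gamma_dopa: float = 0.3     # dopamine gate of the transfer rule
    theta_dopa: float = 0.0     # floor on the phasic dopamine factor

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.tau_alpha <= 0:
            raise ValueError("tau_alpha must be positive")

    @property
    def bounded(self) -> bool:
        return self.w_min > -_INF or self.w_max < _INF


@dataclass
class RegularizerState:
    """Per-postsynaptic-unit homeostatic trace ``alpha``."""

    alpha: np.ndarray

    @classmethod
    def zeros(cls, n_post: int) -> "RegularizerState":
        return cls(alpha=np.zeros(n_post))


def _clamp(W: np.ndarray, p: PlasticityParams) -> np.ndarray:
    if p.bounded:
        np.clip(W, p.w_min, p.w_max, out=W)
    return W


def hebbian_threshold_update(W, r_pre, r_post, p: PlasticityParams,
                             dt: float = DT):
    """Thresholded Hebb: ``dw ~ (r_pre - th_pre)+ * (r_post - th_post)+``."""
    pre = np.maximum(np.asarray(r_pre, dtype=float) - p.theta_pre, 0.0)
    post = np.maximum(np.asarray(r_post, dtype=float) - p.theta_post, 0.0)
    W += (dt / p.eps) * (post[:, None] * pre[None, :])
    return _clamp(W, p)


def covariance_update(W, r_pre, r_post, mean_pre, mean_post,
                      p: PlasticityParams, dt: float = DT):
    """Covariance rule with rectified deviations from the population means."""
    pre = np.maximum(np.asarray(r_pre, dtype=float) - mean_pre, 0.0)
    post = np.maximum(np.asarray(r_post, dtype=float) - mean_post, 0.0)
    W += (dt / p.eps) * (post[:, None] * pre[None, :])
    return _clamp(W, p)


def or_product(x, y):
    """``x*y`` when at least one deviation is positive, else 0.

    The product of two negative deviations would be spuriously positive
    (silent cells potentiating each other), so it is forced to zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.where((x > 0) | (y > 0), x * y, 0.0)


def da_covariance_update(W, r_pre, r_post, mean_pre, mean_post,
                         da_phasic: float, reg: RegularizerState,
                         p: PlasticityParams, dt: float = DT):
    """Dopamine-modulated covariance rule with Oja-style regularization.

    ``dw ~ K * da_phasic * OR(pre_dev, post_dev) - alpha * r_post^2 * w``

    ``da_phasic`` is the phasically filtered dopaminergic input of the
    projection, so potentiation happens only at burst onsets; the second
    term scales down the strongest connections of units firing above
    ``r_max`` (tracked by ``reg``, advanced separately).
    """
    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    scale = dt / p.eps
    da_phasic = max(da_phasic - p.theta_dopa, 0.0)
    if da_phasic != 0.0:
        x = r_pre - mean_pre          # (n_pre,)
        y = r_post - mean_post        # (n_post,)
        mask = (x > 0)[None, :] | (y > 0)[:, None]
        W += (scale * p.K * da_phasic) * (y[:, None] * x[None, :]) * mask
    if reg.alpha.any():
        W -= scale * (reg.alpha * r_post ** 2)[:, None] * W
    return _clamp(W, p)


def regularizer_step(reg: RegularizerState, r_post, p: PlasticityParams,
                     dt: float = DT) -> RegularizerState:
    """Advance ``tau_alpha * dalpha/dt + alpha = (r_post - r_max)+``.

    Values that have decayed below 1e-15 are flushed to exact zero; their
    effect on the weight decay term is far below float resolution.
    """
    target = np.maximum(np.asarray(r_post, dtype=float) - p.r_max, 0.0)
    reg.alpha += (dt / p.tau_alpha) * (target - reg.alpha)
    reg.alpha[reg.alpha < 1e-15] = 0.0
    return reg


def modulated_transfer_update(W, r_pre, r_post, mean_pre, mean_post,
                              g_dopa, g_exc_post, g_mod_post,
                              p: PlasticityParams, dt: float = DT):
    """Dopamine-gated transfer of the reward response onto the cue pathway.

    ``dw ~ gate(g_dopa) * (pre_dev) * (post_dev) * (g_exc - g_mod)+``

    Deviations are *not* rectified here; the ``(g_exc - g_mod)+`` factor
    stops learning once the cue-driven input matches the reward-driven one.
    """
    gate = threshold_gate(g_dopa, p.gamma_dopa)
    if np.ndim(gate) == 0 and gate == 0.0:
        return W
    x = np.asarray(r_pre, dtype=float) - mean_pre
    y = np.asarray(r_post, dtype=float) - mean_post
    headroom = np.maximum(np.asarray(g_exc_post, dtype=float)
                          - np.asarray(g_mod_post, dtype=float), 0.0)
    W += (dt / p.eps) * (gate * headroom * y)[:, None] * x[None, :]
    return _clamp(W, p)
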