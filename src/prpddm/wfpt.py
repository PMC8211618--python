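"""Wiener first-passage-time (WFPT) mathematics for the 4-parameter diffusion model.

The decision process is a Brownian motion with drift ``v`` (evidence units per
second), diffusion constant ``s = 1``, absorbing boundaries at 0 and ``a``
(evidence units), and an unbiased start ``z = a/2``.  The observed response
time is the first-passage time plus a non-decision offset ``t0`` (seconds).
Under accuracy coding the upper boundary is the correct response and the lower
boundary an error.

The density uses the classical pair of series representations for the
first-passage density of the standardized process — a small-time expansion
(images of the start point) and a large-time expansion (spectral/sine series)
— switching per time point to whichever needs fewer terms for a requested
truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["DDMParams", "wfpt_density", "wfpt_loglik", "closed_forms"]

_W = 0.5  # relative start point, fixed: unbiased accumulation
_ERR = 1e-7  # relative truncation error of the series


@dataclass(frozen=True)
class DDMParams:
    """Estimation-side diffusion parameters.

    a : boundary separation (evidence units), > 0
    v : drift rate (evidence units / second), signed toward the upper boundary
    t0 : non-decision time (seconds), >= 0
    z_rel and s are structural constants of the model variant (0.5 and 1).
    """

    a: float
    v: float
    t0: float
    z_rel: float = field(default=0.5)
    s: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.v) and np.isfinite(self.t0)):
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be non-negative, got t0={self.t0}")
        if self.z_rel != 0.5:
            raise ValueError("relative start point is fixed at 0.5 in this model variant")
        if self.s != 1.0:
            raise ValueError("diffusion constant is fixed at 1 in this model variant")


def _fpt_standard(tau: np.ndarray, w: float) -> np.ndarray:
    """Density of the standardized (a=1, v=0) lower-boundary FPT at scaled times tau.

    Chooses the small-time or large-time series per element using the usual
    minimal-terms rule for truncation error ``_ERR``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    t = tau[pos]

    # terms needed by each representation (elementwise)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * _ERR), 0.0) / (np.pi**2 * t))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))
        inner = 2.0 * np.sqrt(2.0 * np.pi * t) * _ERR
        ks = np.where(
            inner < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(np.maximum(inner, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)

    use_small = ks < kl
    dens = np.empty_like(t)

    if np.any(use_small):
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 2)  # symmetric image terms
        arg = w + 2.0 * k[:, None]
        dens_s = np.sum(arg * np.exp(-(arg**2) / (2.0 * ts[None, :])), axis=0)
        dens[use_small] = dens_s / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        dens_l = np.sum(
            k[:, None]
            * np.exp(-(k[:, None] ** 2) * np.pi**2 * tl[None, :] / 2.0)
            * np.sin(k[:, None] * np.pi * w),
            axis=0,
        )
        dens[~use_small] = np.pi * dens_l

    out[pos] = np.maximum(dens, 0.0)
    return out


def _density_lower(t: np.ndarray, a: float, v: float, t0: float) -> np.ndarray:
    """Lower-boundary first-passage density at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    if np.any(pos):
        tau = dt[pos] / a**2
        base = _fpt_standard(tau, _W) / a**2
        out[pos] = base * np.exp(-v * a * _W - v**2 * dt[pos] / 2.0)
    return out


@njit(cache=True)
def _loglik_lower_kernel(rts, a, v, t0):
    """Sum of log lower-boundary densities; compiled hot path for fitting.

    Same small-/large-time series and switching rule as ``_fpt_standard``
    (w = 1/2), evaluated per scalar.  Returns -inf if any rt <= t0.
    """
    total = 0.0
    for i in range(rts.shape[0]):
        dt = rts[i] - t0
        if dt <= 0.0:
            return -np.inf
        tau = dt / (a * a)
        pit = np.pi * tau * _ERR
        if pit < 1.0:
            kl = np.sqrt(-2.0 * np.log(pit) / (np.pi**2 * tau))
            kl = max(kl, 1.0 / (np.pi * np.sqrt(tau)))
        else:
            kl = 1.0 / (np.pi * np.sqrt(tau))
        inner = 2.0 * np.sqrt(2.0 * np.pi * tau) * _ERR
        if inner < 1.0:
            ks = 2.0 + np.sqrt(-2.0 * tau * np.log(inner))
            ks = max(ks, np.sqrt(tau) + 1.0)
        else:
            ks = 2.0
        f = 0.0
        if ks < kl:
            K = int(np.ceil(ks))
            for k in range(-((K - 1) // 2), ((K - 1) // 2) + 2):
                arg = _W + 2.0 * k
                f += arg * np.exp(-arg * arg / (2.0 * tau))
            f /= np.sqrt(2.0 * np.pi * tau**3)
        else:
            K = int(np.ceil(kl))
            for k in range(1, K + 1):
                f += k * np.exp(-(k * k) * np.pi**2 * tau / 2.0) * np.sin(k * np.pi * _W)
            f *= np.pi
        if f <= 0.0:
            return -np.inf
        total += np.log(f) - 2.0 * np.log(a) - v * a * _W - v * v * dt / 2.0
    return total


def wfpt_density(t, params: DDMParams, boundary: str = "upper") -> np.ndarray | float:
    """First-passage density (per second) at response time(s) ``t`` (seconds).

    ``boundary="upper"`` gives the density of correct responses under accuracy
    coding, ``"lower"`` of errors.  Zero for ``t <= t0``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if boundary == "upper":
        # symmetry: reaching a from a/2 with drift v == reaching 0 from a/2 with drift -v
        dens = _density_lower(t_arr, params.a, -params.v, params.t0)
    else:
        dens = _density_lower(t_arr, params.a, params.v, params.t0)
    return float(dens[0]) if scalar else dens


def wfpt_loglik(rts, correct, params: DDMParams) -> float:
    """Joint log-likelihood of accuracy-coded trials.

    rts : response times in seconds; correct : booleans (upper boundary).
    Trials with ``rt <= t0`` have zero density and yield ``-inf``.
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if rts.size == 0:
        raise ValueError("empty trial set has no likelihood")
    if rts.shape != correct.shape:
        raise ValueError("rts and correct must have matching shapes")
    ll = 0.0
    for flag, bnd in ((correct, "upper"), (~correct, "lower")):
        if np.any(flag):
            dens = wfpt_density(rts[flag], params, boundary=bnd)
            if np.any(dens <= 0.0):
                return -np.inf
            ll += float(np.sum(np.log(dens)))
    return ll


def closed_forms(params: DDMParams) -> tuple[float, float]:
    """(absorption probability at the upper boundary, mean decision time in seconds).

    With the unbiased start and unit diffusion these are
    ``p_upper = 1 / (1 + exp(-a v))`` and
    ``mean_dt = (a / 2v) tanh(a v / 2)``, with limits 0.5 and a^2/4 as v -> 0.
    """
    a, v = params.a, params.v
    if v == 0.0:
        return 0.5, a**2 / 4.0
    p_upper = 1.0 / (1.0 + np.exp(-a * v))
    mean_dt = (a / (2.0 * v)) * np.tanh(a * v / 2.0)
    return float(p_upper), float(mean_dt)
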