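"""The three-stage columnar cascade shared by every model area.

Each area processes its input through (i) linear filtering (see
:mod:`shapecortex.kernels`), (ii) modulatory feedback gating, (iii) a
power-law transfer function followed by shunting (divisive) normalization
against the local channel population.  Feedback is strictly modulatory:
it can amplify existing activity but can never create activity on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CascadeParams",
    "modulate",
    "transfer",
    "normalize_steady",
    "normalize_dynamic",
]


@dataclass(frozen=True)
class CascadeParams:
    """Constants of one cascade stage.

    alpha : decay constant of the shunting stage (steepness of the
        compressive non-linearity).
    beta : output scale of the shunting stage.
    k : exponent of the power-law transfer function, >= 1.
    lambda_fb : modulatory feedback strength (unitless gain).
    dt : Euler step for the dynamic form, in units of 1/alpha.
    n_steps : number of Euler steps; the default covers >= 10 time
        constants of the slowest (pure-decay) mode.
    """

    alpha: float = 1.0
    beta: float = 1.0
    k: float = 1.0
    lambda_fb: float = 0.0
    dt: float = 0.1
    n_steps: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.k < 1:
            raise ValueError("transfer exponent k must be >= 1")
        if self.lambda_fb < 0:
            raise ValueError("feedback strength must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def modulate(R: np.ndarray, net_fb: np.ndarray, lambda_fb: float) -> np.ndarray:
    """Modulatory feedback gating ``R * (1 + lambda_fb * net_fb)``.

    Zero input stays zero for any feedback ("feedback alone cannot elicit
    any cell response"); zero feedback leaves the input unchanged.
    """
    R = np.asarray(R, dtype=float)
    net_fb = np.asarray(net_fb, dtype=float)
    if R.shape != net_fb.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {net_fb.shape}")
    return R * (1.0 + lambda_fb * net_fb)


def transfer(R: np.ndarray, k: float) -> np.ndarray:
    """Power-law transfer function ``f(R) = R**k`` for non-negative R."""
    return np.power(np.asarray(R, dtype=float), k)


def normalize_steady(
    R_pop: np.ndarray, alpha: float, beta: float, axis: int = -1
) -> np.ndarray:
    """Closed-form shunting normalization of a channel population.

    Each channel is mapped to ``beta * R_i / (alpha + I_net)`` where
    ``I_net`` is the mean over the population at the same retinotopic
    location (the channel axis only — no spatial pooling).  Ranking of the
    channels is preserved; outputs are bounded by ``beta * R_i / alpha``.
    """
    R_pop = np.asarray(R_pop, dtype=float)
    i_net = R_pop.mean(axis=axis, keepdims=True)
    return beta * R_pop / (alpha + i_net)


def normalize_dynamic(
    R_pop: np.ndarray, params: CascadeParams, axis: int = -1
) -> np.ndarray:
    """Euler-integrated shunting normalization.

    Integrates ``dR/dt = -alpha R_norm + beta R - R_norm * I_net`` from a
    zero initial state.  The trajectory relaxes to the closed form of
    :func:`normalize_steady`.  The step is rescaled by the fastest local
    decay rate so the scheme is unconditionally stable.
    """
    R_pop = np.asarray(R_pop, dtype=float)
    i_net = R_pop.mean(axis=axis, keepdims=True)
    rate_max = params.alpha + float(i_net.max(initial=0.0))
    dt = params.dt / rate_max
    if params.n_steps is None:
        # >= 10 time constants of the slowest mode (decay rate alpha + I_net
        # >= alpha at every location, so 10/alpha always suffices)
        n_steps = int(np.ceil(10.0 / (params.alpha * dt)))
    else:
        n_steps = params.n_steps
    out = np.zeros_like(R_pop)
    drive = params.beta * R_pop
    for step in range(n_steps):
        out = out + dt * (drive - out * (params.alpha + i_net))
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(
                f"shunting normalization diverged at Euler step {step}"
            )
    return out
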