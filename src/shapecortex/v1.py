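"""Model LGN and area V1: center-surround contrast and oriented contrast.

The LGN stage applies a balanced difference-of-Gaussians to the luminance
image and splits the signed response into rectified on/off channels, which
are then shunting-normalized against each other.  V1 simple cells filter
the signed LGN contrast with odd-symmetric oriented kernels at two contrast
polarities; complex cells sum the two rectified polarity responses, pass
them through an expansive power-law (k = 4) and normalize across the
orientation population, which makes them contrast-polarity invariant.
"""

from __future__ import annotations

import numpy as np

from . import kernels as K
from .cascade import modulate, normalize_steady, transfer
from .fields import N_ORIENT, OrientationField, orientations

__all__ = [
    "lgn_response",
    "v1_simple",
    "v1_simple_bank",
    "v1_complex",
    "v1_from_linear",
    "dominant_orientation",
]


def lgn_response(
    I: np.ndarray,
    sigma: float = 1.0,
    kappa: float = 1.5,
    alpha: float = 2.17e-3,
    beta: float = 2.17e-3,
    border_mode: str = "reflect",
) -> tuple[np.ndarray, np.ndarray]:
    """On/off center-surround responses of the LGN stage.

    Returns the rectified positive and negative parts of the DoG response,
    each normalized against the {on, off} pair.
    """
    I = np.asarray(I, dtype=float)
    dog = K.dog_kernel(sigma, kappa)
    r = K.convolve2d(I, dog, border_mode)
    pair = np.stack([K.rectify(r), K.rectify(-r)], axis=-1)
    pair = normalize_steady(pair, alpha, beta, axis=-1)
    return pair[..., 0], pair[..., 1]


def _simple_kernel(theta_i, sigma1_px, sigma2_px, omega1, polarity):
    return K.simple_cell_kernel(theta_i, sigma1_px, sigma2_px, omega1, polarity)


def v1_simple(
    on_off: tuple[np.ndarray, np.ndarray],
    theta_i: float,
    polarity: int,
    sigma1_px: float = 4.83,
    sigma2_px: float = 2.52,
    omega1: float = 3.0,
    border_mode: str = "reflect",
) -> np.ndarray:
    """Rectified response of one odd-symmetric simple cell channel.

    The kernel filters the signed LGN contrast (on - off); the two polarity
    channels see sign-flipped copies of the same kernel.
    """
    on, off = on_off
    c = np.asarray(on, dtype=float) - np.asarray(off, dtype=float)
    kern = _simple_kernel(theta_i, sigma1_px, sigma2_px, omega1, polarity)
    return K.rectify(K.convolve2d(c, kern, border_mode))


def v1_simple_bank(
    on_off: tuple[np.ndarray, np.ndarray],
    n_orient: int = N_ORIENT,
    sigma1_px: float = 4.83,
    sigma2_px: float = 2.52,
    omega1: float = 3.0,
    border_mode: str = "reflect",
) -> np.ndarray:
    """(h, w, N, 2) rectified simple responses for all orientations and
    both polarities."""
    on, off = on_off
    c = np.asarray(on, dtype=float) - np.asarray(off, dtype=float)
    out = np.empty(c.shape + (n_orient, 2), dtype=float)
    for i, th in enumerate(orientations(n_orient)):
        kern = _simple_kernel(th, sigma1_px, sigma2_px, omega1, +1)
        r = K.convolve2d(c, kern, border_mode)
        out[..., i, 0] = K.rectify(r)
        out[..., i, 1] = K.rectify(-r)
    return out


def v1_linear(
    simple_bank: np.ndarray,
    pool_sigma: float = 2.0,
    border_mode: str = "reflect",
) -> np.ndarray:
    """Polarity-invariant linear complex drive.

    Sums the two rectified polarity responses per orientation, then pools
    over a small isotropic Gaussian neighborhood (``pool_sigma`` in image
    pixels; 0 disables it).  The pooling bridges the null line of the
    odd-symmetric operator on thin lines, so the aligned channel stays
    locally dominant across the whole contour instead of handing the
    mid-line over to oblique channels.
    """
    out = simple_bank.sum(axis=-1)
    if pool_sigma > 0:
        pool = K.rotated_gaussian(K.GaussianSpec(sigma1=pool_sigma))
        for i in range(out.shape[-1]):
            out[..., i] = K.filter_bank_apply(out[..., i], pool, border_mode)
    return out


def v1_from_linear(
    linear: np.ndarray,
    k: float = 4.0,
    alpha: float = 2.16e-6,
    beta: float = 1.0,
    feedback: np.ndarray | None = None,
    lambda_fb: float = 0.0,
) -> OrientationField:
    """Complex-cell output stage: (optional modulatory feedback) ->
    power-law transfer -> shunting normalization over the orientation pool.

    ``linear`` is the per-orientation polarity-summed drive; ``feedback``
    the like-oriented top-down signal, already on the V1 grid.
    """
    drive = linear
    if feedback is not None:
        drive = modulate(drive, feedback, lambda_fb)
    out = normalize_steady(transfer(drive, k), alpha, beta, axis=-1)
    return OrientationField(out)


def v1_complex(
    simple_bank: np.ndarray,
    k: float = 4.0,
    alpha: float = 2.16e-6,
    beta: float = 1.0,
) -> OrientationField:
    """Complex cells from a full simple-cell bank (no feedback)."""
    return v1_from_linear(v1_linear(simple_bank), k=k, alpha=alpha, beta=beta)


def dominant_orientation(fld: OrientationField) -> np.ndarray:
    """Per-pixel arg-max orientation channel; ties go to the lowest index."""
    return np.argmax(fld.data, axis=-1)
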