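"""Model area IT: large-field figure-ground cells.

An IT cell at x0 pools border-ownership evidence on a Gaussian annulus of
radius omega_it around x0, weighting each boundary point by the rectified
cosine between its ownership direction and the vector pointing back toward
x0.  Regions surrounded by inward-pointing (convex) boundaries therefore
light up, which is the contextual signal fed back to resolve ownership.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import kernels as K
from .cascade import normalize_steady, transfer
from .fields import N_BOWN, BOwnField, bown_directions

__all__ = ["ITParams", "it_response", "it_feedback_to_bown"]


@dataclass(frozen=True)
class ITParams:
    """Annulus radius and widths are in V2-grid pixels; ``k_it`` is the
    output non-linearity and ``alpha_norm`` the shunting decay."""

    omega_it: float = 17.0
    sigma_it: float = 0.43  # reserved secondary width; unused by default
    sigma_radial: float = 29.0
    k_it: float = 3.0
    alpha_norm: float = 5.49e-5
    beta_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_it <= 0 or self.sigma_radial <= 0:
            raise ValueError("annulus radius and width must be positive")


@lru_cache(maxsize=4)
def _annulus_kernels(
    omega_it: float, sigma_radial: float, n_dir: int = N_BOWN
) -> np.ndarray:
    """W[d, y, x]: weight of ownership direction d at offset p from the IT
    cell, = ring(|p|) * max(0, cos(angle(u_d, -p)))."""
    rad = int(np.ceil(omega_it + 2.0 * sigma_radial))
    coords = np.arange(-rad, rad + 1, dtype=float)
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(dx, dy)
    ring = np.exp(-((omega_it - rr) ** 2) / sigma_radial**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        px, py = dx / rr, dy / rr
    W = np.empty((n_dir, 2 * rad + 1, 2 * rad + 1))
    for d, phi in enumerate(bown_directions(n_dir)):
        ux, uy = np.cos(phi), np.sin(phi)
        cosang = -(ux * px + uy * py)  # ownership pointing back toward x0
        cosang = np.nan_to_num(cosang, nan=0.0)
        W[d] = ring * np.maximum(0.0, cosang)
    # unit total mass: the pooled value is a weighted average of ownership
    # activity, which keeps the output scale independent of the annulus size
    return W / W.sum()


def it_response(
    bown: BOwnField, params: ITParams = ITParams(), border_mode: str = "zero"
) -> np.ndarray:
    """2-D figure-ground map from a border-ownership field.

    Zero padding is the default here: the region outside the image provides
    no ownership evidence, so a reflected border must not fabricate any.
    """
    W = _annulus_kernels(params.omega_it, params.sigma_radial)
    rad = (W.shape[-1] - 1) // 2
    acc = np.zeros(bown.data.shape[:2])
    for d in range(N_BOWN):
        # correlation over offsets: flip the kernel for convolution
        kern = K.Kernel2D(W[d][::-1, ::-1], rad)
        acc += K.filter_bank_apply(bown.data[..., d], kern, border_mode)
    out = transfer(acc, params.k_it)
    # single-channel shunting: the pool is the cell's own activity
    return normalize_steady(out[..., None], params.alpha_norm, params.beta_norm)[..., 0]


def it_feedback_to_bown(
    it_map: np.ndarray, params: ITParams = ITParams(), border_mode: str = "zero"
) -> np.ndarray:
    """(h, w, 4) compatibility of IT activity with each ownership direction.

    The transpose of the forward pooling: an ownership hypothesis at x
    pointing along u_d is supported by IT activity at annulus distance in
    direction u_d (the figure side it claims).
    """
    W = _annulus_kernels(params.omega_it, params.sigma_radial)
    rad = (W.shape[-1] - 1) // 2
    out = np.empty(np.asarray(it_map).shape + (N_BOWN,))
    for d in range(N_BOWN):
        # transpose of the forward correlation == plain convolution
        kern = K.Kernel2D(W[d], rad)
        out[..., d] = K.filter_bank_apply(it_map, kern, border_mode)
    # scale-free support in [0, 1]; numerically-silent maps stay silent
    peak = out.max(initial=0.0)
    if peak > 1e-12:
        out = out / peak
    return out
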