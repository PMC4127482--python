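"""Elementary filter construction and linear filtering.

Every model area is driven by linear filtering of its input with a kernel
built from rotated anisotropic Gaussian lobes.  The conventions used
throughout the package are fixed here:

* images are indexed ``(row, col)`` with the origin at the top left;
* a spatial offset is expressed as ``(x, y) = (col - c, row - r)``;
* an orientation ``theta`` is an axis (defined modulo pi), measured
  counter-clockwise from the horizontal image axis, so the ``theta = pi/2``
  channel prefers vertical contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "GaussianSpec",
    "Kernel2D",
    "rotated_gaussian",
    "dog_kernel",
    "simple_cell_kernel",
    "convolve2d",
    "filter_bank_apply",
    "rectify",
    "default_support_radius",
]


@dataclass(frozen=True)
class GaussianSpec:
    """Parameters of a rotated, shifted anisotropic Gaussian.

    ``sigma1`` is the standard deviation along the orientation axis
    (the elongation axis), ``sigma2`` across it.  ``mu`` shifts the center
    in ``(x, y)`` pixel units.
    """

    theta: float = 0.0
    sigma1: float = 1.0
    sigma2: float | None = None
    mu: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sigma2 is None:
            object.__setattr__(self, "sigma2", self.sigma1)
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian standard deviations must be positive")


@dataclass(frozen=True)
class Kernel2D:
    """Finite-support square kernel with its center at
    ``(support_radius, support_radius)``."""

    weights: np.ndarray
    support_radius: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        r = self.support_radius
        if w.shape != (2 * r + 1, 2 * r + 1):
            raise ValueError(
                f"kernel shape {w.shape} inconsistent with support radius {r}"
            )


def default_support_radius(*sigmas: float) -> int:
    """Truncation radius ceil(3 * max(sigma)); truncated mass < 0.3 %."""
    return max(1, int(np.ceil(3.0 * max(sigmas))))


def _offset_grids(support_radius: int) -> tuple[np.ndarray, np.ndarray]:
    coords = np.arange(-support_radius, support_radius + 1, dtype=float)
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    return dx, dy


def rotated_gaussian(
    spec: GaussianSpec, support_radius: int | None = None, normalize: bool = True
) -> Kernel2D:
    """Sample a rotated anisotropic Gaussian on the integer pixel grid.

    The density is maximal at ``mu`` and elongated with ``sigma1`` along the
    ``theta`` axis.  By default the weights are normalized to unit mass so
    kernels built from lobe differences are balanced.
    """
    if support_radius is None:
        support_radius = default_support_radius(
            spec.sigma1, spec.sigma2, abs(spec.mu[0]), abs(spec.mu[1])
        )
    if support_radius < 1:
        raise ValueError("support_radius must be >= 1")
    dx, dy = _offset_grids(support_radius)
    dx = dx - spec.mu[0]
    dy = dy - spec.mu[1]
    c, s = np.cos(spec.theta), np.sin(spec.theta)
    # coordinates in the rotated frame: a along the orientation axis
    a = c * dx + s * dy
    b = -s * dx + c * dy
    w = np.exp(-0.5 * ((a / spec.sigma1) ** 2 + (b / spec.sigma2) ** 2))
    if normalize:
        w = w / w.sum()
    return Kernel2D(w, support_radius)


def dog_kernel(
    sigma: float, kappa: float = 1.5, support_radius: int | None = None
) -> Kernel2D:
    """Difference-of-Gaussians center-surround kernel.

    Center std-dev ``sigma``, surround ``kappa * sigma`` (kappa > 1).  Each
    lobe is normalized to unit mass before subtraction, so the kernel is
    exactly balanced and gives zero response on constant input.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if kappa <= 1:
        raise ValueError("surround must be wider than center (kappa > 1)")
    if support_radius is None:
        support_radius = default_support_radius(kappa * sigma)
    center = rotated_gaussian(GaussianSpec(sigma1=sigma), support_radius)
    surround = rotated_gaussian(GaussianSpec(sigma1=kappa * sigma), support_radius)
    return Kernel2D(center.weights - surround.weights, support_radius)


def simple_cell_kernel(
    theta_i: float,
    sigma1: float,
    sigma2: float,
    omega1: float,
    polarity: int = +1,
    support_radius: int | None = None,
) -> Kernel2D:
    """Odd-symmetric oriented contrast (simple cell) kernel.

    Two Gaussian lobes elongated along ``theta_i`` (std ``sigma1`` axially,
    ``sigma2`` across) of opposite sign, displaced by ``+-omega1`` along the
    axis perpendicular to the elongation.  A vertical luminance edge
    therefore maximally drives the ``theta = pi/2`` channel.  Flipping
    ``polarity`` negates the kernel.

    The lobes have unit peak amplitude (not unit mass): the response scale
    then grows with the integration area, which puts contour responses in
    the operating range of the downstream divisive-normalization constants.
    """
    if omega1 <= 0:
        raise ValueError("subfield excentricity omega1 must be positive")
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    if support_radius is None:
        support_radius = default_support_radius(sigma1, sigma2 + omega1)
    # unit normal to the orientation axis
    nx, ny = -np.sin(theta_i), np.cos(theta_i)
    pos = rotated_gaussian(
        GaussianSpec(theta_i, sigma1, sigma2, (omega1 * nx, omega1 * ny)),
        support_radius,
        normalize=False,
    )
    neg = rotated_gaussian(
        GaussianSpec(theta_i, sigma1, sigma2, (-omega1 * nx, -omega1 * ny)),
        support_radius,
        normalize=False,
    )
    return Kernel2D(polarity * (pos.weights - neg.weights), support_radius)


def convolve2d(
    fld: np.ndarray, kernel: Kernel2D, border_mode: str = "reflect"
) -> np.ndarray:
    """2-D convolution of a field with a finite kernel.

    ``border_mode`` is ``reflect`` (default; avoids spurious border
    contrasts) or ``zero``.  The kernel must fit inside the field.
    """
    fld = np.asarray(fld, dtype=float)
    if not np.all(np.isfinite(fld)):
        raise ValueError("field contains non-finite values")
    k = kernel.weights
    if k.shape[0] > fld.shape[0] or k.shape[1] > fld.shape[1]:
        raise ValueError("kernel larger than field")
    if border_mode == "reflect":
        mode = "reflect"
    elif border_mode == "zero":
        mode = "constant"
    else:
        raise ValueError(f"unknown border mode {border_mode!r}")
    return ndimage.convolve(fld, k, mode=mode, cval=0.0)


def filter_bank_apply(
    fld: np.ndarray, kernel: Kernel2D, border_mode: str = "reflect"
) -> np.ndarray:
    """FFT-based convolution used for large integration fields.

    Equivalent to :func:`convolve2d` up to floating-point error but without
    the kernel-fits-inside-field restriction; kernels wider than the field
    are handled by padding the field.
    """
    fld = np.asarray(fld, dtype=float)
    r = kernel.support_radius
    if border_mode == "reflect":
        # np.pad 'reflect' requires pad <= dim - 1; fall back to 'symmetric'
        # style growth by chunks for very large kernels
        padded = _pad_reflect(fld, r)
    elif border_mode == "zero":
        padded = np.pad(fld, r, mode="constant")
    else:
        raise ValueError(f"unknown border mode {border_mode!r}")
    out = signal.fftconvolve(padded, kernel.weights, mode="same")
    return out[r : r + fld.shape[0], r : r + fld.shape[1]]


def _pad_reflect(fld: np.ndarray, r: int) -> np.ndarray:
    # 'symmetric' repeats the edge sample, matching ndimage's 'reflect'
    out = fld
    remaining = r
    while remaining > 0:
        step = min(remaining, out.shape[0], out.shape[1])
        out = np.pad(out, step, mode="symmetric")
        remaining -= step
    return out


def rectify(fld: np.ndarray) -> np.ndarray:
    """Half-wave rectification, elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(fld, dtype=float))
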