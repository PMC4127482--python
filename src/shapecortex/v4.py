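"""Model area V4: opponent curvature-selective cells at coarse scale.

Two bipartite subfield pools A and B integrate left- and right-sign V2
curvature responses through displaced elongated Gaussians.  Opponent
shunting dynamics, solved at equilibrium, yield a response proportional to
|A - B| normalized by the total drive: strong for a single dominant
curvature sign, silent for straight contours that feed both signs equally,
and saturating (contrast-gain invariant) for large drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels as K
from .fields import CurvatureField, OrientationField, orientations

__all__ = [
    "V4Params",
    "v4_subfield_responses",
    "v4_curvature_response",
    "v4_opponent_equilibria",
]


@dataclass(frozen=True)
class V4Params:
    """V4 filter constants.

    ``sigma4`` (cross-axial, narrow) and ``sigma4b`` (axial, broad) are
    fractions of the filter size, which Table-style convention states in
    image pixels and is converted to the 1:4 V4 grid here.  ``omegaV4`` is
    the subfield center offset in V4 pixels; its negative sign flips the
    offset direction relative to the orientation vector.
    """

    alpha4: float = 0.01
    sigma4: float = 0.43
    sigma4b: float = 1.35
    omegaV4: float = -1.0
    filter_size: float = 31.0
    scale: int = 4

    def __post_init__(self) -> None:
        if self.alpha4 <= 0:
            raise ValueError("alpha4 must be positive")
        if self.sigma4b <= self.sigma4:
            raise ValueError("broad subfield width must exceed the narrow one")

    @property
    def _size_own_grid(self) -> float:
        return self.filter_size / self.scale

    @property
    def sigma4_px(self) -> float:
        return self.sigma4 * self._size_own_grid

    @property
    def sigma4b_px(self) -> float:
        return self.sigma4b * self._size_own_grid


def v4_subfield_responses(
    v2curv: CurvatureField,
    params: V4Params = V4Params(),
    extra_input: np.ndarray | None = None,
    border_mode: str = "reflect",
) -> tuple[OrientationField, OrientationField]:
    """Subfield pools A (left-sign) and B (right-sign curvature input).

    ``v2curv`` must already live on the V4 grid.  ``extra_input`` is an
    optional congruent excitatory (h, w, N) drive (the V2/V3 corner field)
    added to both pools before filtering.
    """
    data = v2curv.data
    n = data.shape[2]
    A = np.empty(data.shape[:2] + (n,))
    B = np.empty_like(A)
    for i, th in enumerate(orientations(n)):
        u = np.array([np.cos(th), np.sin(th)])
        mu = params.omegaV4 * u
        kern_a = K.rotated_gaussian(
            K.GaussianSpec(th, params.sigma4b_px, params.sigma4_px, tuple(mu))
        )
        kern_b = K.rotated_gaussian(
            K.GaussianSpec(th, params.sigma4b_px, params.sigma4_px, tuple(-mu))
        )
        A[..., i] = K.rectify(K.filter_bank_apply(data[..., i, 0], kern_a, border_mode))
        B[..., i] = K.rectify(K.filter_bank_apply(data[..., i, 1], kern_b, border_mode))
        if extra_input is not None:
            # congruent excitatory drive enters both pools through the same
            # centered kernel, so it cannot by itself unbalance the opponency
            kern_c = K.rotated_gaussian(
                K.GaussianSpec(th, params.sigma4b_px, params.sigma4_px)
            )
            pooled = K.rectify(
                K.filter_bank_apply(extra_input[..., i], kern_c, border_mode)
            )
            A[..., i] += pooled
            B[..., i] += pooled
    return OrientationField(A, resolution_scale=params.scale), OrientationField(
        B, resolution_scale=params.scale
    )


def v4_opponent_equilibria(
    A: np.ndarray, B: np.ndarray, alpha4: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibria of the opponent shunting pair.

    The left cell obeys dR/dt = -alpha4 R + (1-R) A - (1+R) B and settles
    at (A-B)/(alpha4+A+B); the right cell sees A and B exchanged.  Returns
    the rectified pair.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    denom = alpha4 + A + B
    return K.rectify((A - B) / denom), K.rectify((B - A) / denom)


def v4_curvature_response(
    A: OrientationField | np.ndarray,
    B: OrientationField | np.ndarray,
    alpha4: float = 0.01,
) -> OrientationField | np.ndarray:
    """Combined opponent response |A-B| / (2 (alpha4 + A + B)).

    Zero when A = B (straight contours), bounded above by 1/2.
    """
    a = A.data if isinstance(A, OrientationField) else np.asarray(A, dtype=float)
    b = B.data if isinstance(B, OrientationField) else np.asarray(B, dtype=float)
    left, right = v4_opponent_equilibria(a, b, alpha4)
    out = 0.5 * (left + right)
    if isinstance(A, OrientationField):
        return OrientationField(out, resolution_scale=A.resolution_scale)
    return out
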