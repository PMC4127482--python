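"""Model area V2/V3: contour grouping, curvature, corners, border ownership.

V2 long-range cells link like-oriented V1 responses over larger distances
with two elongated excitatory subfields combined multiplicatively (an AND
gate that bridges contour gaps, e.g. across Kanizsa inducers) and a
cross-axial pair of isotropic inhibitory pools that suppress clutter.

V2 curvature cells integrate oriented responses along the arc of an
osculating circle of tuning radius omega_c placed to the left or right of
the tangent; V2/V3 corner cells multiply orthogonal orientation channels;
border-ownership cells hold four direction hypotheses that are driven by
the perpendicular contour orientation and disambiguated by competition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import kernels as K
from .cascade import normalize_steady, transfer
from .fields import (
    N_BOWN,
    N_ORIENT,
    BOwnField,
    CurvatureField,
    OrientationField,
    bown_directions,
    orientations,
)

__all__ = [
    "V2Params",
    "subsample",
    "v2_longrange",
    "v2_curvature",
    "v2v3_corner",
    "bown_init",
    "bown_compete_step",
]


@dataclass(frozen=True)
class V2Params:
    """Long-range grouping constants.

    ``filter_size`` is the kernel diameter in image pixels; the three
    receptive-field widths are fractions of it (sigma1 along the contour
    for the excitatory subfields, sigma2 across, sigma3 for the isotropic
    inhibitory pools).  The subfield offsets ``omega_ex``/``omega_inh``
    are in V2-grid pixels, like the responses themselves.
    """

    filter_size: float = 41.0
    sigma1: float = 0.21
    sigma2: float = 0.02
    sigma3: float = 0.10
    omega_ex: float = 3.7
    omega_inh: float = 2.5
    gamma: float = 0.10
    k: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    combine: str = "geometric"  # or "product"
    grid_scale: int = 3  # V1:V2 subsampling, converts image-px widths

    @property
    def sigma1_px(self) -> float:
        return self.sigma1 * self.filter_size / self.grid_scale

    @property
    def sigma2_px(self) -> float:
        return self.sigma2 * self.filter_size / self.grid_scale

    @property
    def sigma3_px(self) -> float:
        return self.sigma3 * self.filter_size / self.grid_scale

    @property
    def support_radius(self) -> int:
        # wide enough for the displaced excitatory lobes
        return int(
            np.ceil(
                max(
                    self.filter_size / (2 * self.grid_scale),
                    self.omega_ex + 2.5 * self.sigma1_px,
                    self.omega_inh + 2.5 * self.sigma3_px,
                )
            )
        )


def subsample(fld: np.ndarray, factor: int) -> np.ndarray:
    """Block-average downsampling; output dims = ceil(input / factor).

    Ragged borders are edge-padded before averaging so constant fields stay
    constant.  Works on 2-D fields or on (h, w, ...) channel stacks.
    """
    if factor < 1:
        raise ValueError("subsampling factor must be >= 1")
    fld = np.asarray(fld, dtype=float)
    h, w = fld.shape[:2]
    ph = (-h) % factor
    pw = (-w) % factor
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (fld.ndim - 2)
    padded = np.pad(fld, pad, mode="edge")
    hh, ww = padded.shape[0] // factor, padded.shape[1] // factor
    shaped = padded.reshape((hh, factor, ww, factor) + padded.shape[2:])
    return shaped.mean(axis=(1, 3))


def v2_longrange(
    v1: OrientationField,
    params: V2Params = V2Params(),
    border_mode: str = "reflect",
) -> OrientationField:
    """Long-range contour grouping of (subsampled) V1 complex responses."""
    data = v1.data
    n = v1.n_channels
    out = np.empty_like(data)
    r = params.support_radius
    sum_all = data.sum(axis=-1)
    for i, th in enumerate(orientations(n)):
        u = np.array([np.cos(th), np.sin(th)])
        nrm = np.array([-np.sin(th), np.cos(th)])
        lobes = []
        for s in (+1, -1):
            mu = s * params.omega_ex * u
            kern = K.rotated_gaussian(
                K.GaussianSpec(th, params.sigma1_px, params.sigma2_px, tuple(mu)), r
            )
            # FFT roundoff can leave tiny negative values in a non-negative
            # pooling result; clamp before the multiplicative combination
            lobes.append(K.rectify(K.filter_bank_apply(data[..., i], kern, border_mode)))
        if params.combine == "geometric":
            exc = np.sqrt(lobes[0] * lobes[1])
        elif params.combine == "product":
            exc = lobes[0] * lobes[1]
        else:
            raise ValueError(f"unknown subfield combination {params.combine!r}")
        inh = np.zeros_like(exc)
        for s in (+1, -1):
            mu = s * params.omega_inh * nrm
            kern = K.rotated_gaussian(
                K.GaussianSpec(0.0, params.sigma3_px, params.sigma3_px, tuple(mu)), r
            )
            inh += K.filter_bank_apply(sum_all, kern, border_mode)
        out[..., i] = K.rectify(exc - params.gamma * inh)
    out = normalize_steady(transfer(out, params.k), params.alpha, params.beta)
    return OrientationField(out, resolution_scale=v1.resolution_scale)


@lru_cache(maxsize=8)
def _curvature_kernels(
    omega_c: float,
    sigma1_dist: float,
    sigma2_ring: float,
    n_orient: int,
) -> np.ndarray:
    """Weight kernels W[i, s, j, y, x] for curvature integration.

    For tangent orientation i and sign s, the osculating-circle center sits
    at ``c = +-omega_c * n_i`` (n_i the unit normal); an input orientation j
    at offset p is weighted by a distance falloff from the cell center, a
    Gaussian ring around radius omega_c from c, and the alignment of j with
    the circle's local tangent (negative alignments clamped to zero).
    """
    rad = int(np.ceil(2 * omega_c + 3 * sigma2_ring))
    coords = np.arange(-rad, rad + 1, dtype=float)
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    thetas = orientations(n_orient)
    W = np.zeros((n_orient, 2, n_orient, 2 * rad + 1, 2 * rad + 1))
    dist2 = dx**2 + dy**2
    w_dist = np.exp(-dist2 / sigma1_dist**2)
    for i, th in enumerate(thetas):
        nrm = np.array([-np.sin(th), np.cos(th)])
        for s, sign in enumerate((+1.0, -1.0)):
            cx, cy = sign * omega_c * nrm
            rx, ry = dx - cx, dy - cy
            rr = np.hypot(rx, ry)
            ring = np.exp(-((rr - omega_c) ** 2) / sigma2_ring**2)
            # local tangent of the circle at the integrated position
            tau = np.arctan2(ry, rx) + np.pi / 2
            for j, thj in enumerate(thetas):
                align = np.maximum(0.0, np.cos(2.0 * (thj - tau)))
                W[i, s, j] = w_dist * ring * align
    return W


def v2_curvature(
    v1: OrientationField,
    omega_c: float = 15.0,
    sigma1_dist: float = 40.0,
    sigma2_ring: float = 2.0,
    border_mode: str = "reflect",
    gate_local: bool = True,
) -> CurvatureField:
    """Curvature-selective population from (subsampled) V1 responses.

    Produces a 16-channel population: 8 tangent orientations times two
    curvature signs (left/right of the tangent).  The response peaks for
    contour arcs whose radius matches ``omega_c``; all lengths are in
    V2-grid pixels.

    With ``gate_local`` the ring integral is multiplied by the cell's own
    tangent-orientation response at its center (an AND-gate, like the
    long-range subfields): a curvature cell only fires when the contour
    actually passes through its receptive-field center.  Without the gate
    a cell responds whenever its osculating ring grazes any remote
    contour, which smears curvature responses far off the contours.
    """
    if omega_c <= 0:
        raise ValueError("tuning radius omega_c must be positive")
    data = v1.data
    n = v1.n_channels
    W = _curvature_kernels(omega_c, sigma1_dist, sigma2_ring, n)
    rad = (W.shape[-1] - 1) // 2
    out = np.zeros(data.shape[:2] + (n, 2))
    for i in range(n):
        for s in range(2):
            acc = np.zeros(data.shape[:2])
            for j in range(n):
                # correlation: flip the offset kernel for convolve
                kern = K.Kernel2D(W[i, s, j][::-1, ::-1], rad)
                acc += K.filter_bank_apply(data[..., j], kern, border_mode)
            if gate_local:
                acc = acc * data[..., i]
            out[..., i, s] = K.rectify(acc)
    return CurvatureField(out, omega_c=omega_c)


def v2v3_corner(
    v1: OrientationField,
    pool_sigma: float = 2.0,
    border_mode: str = "reflect",
) -> OrientationField:
    """Corner/junction cells: product of orthogonal orientation channels,
    pooled over a small Gaussian surround."""
    data = v1.data
    n = v1.n_channels
    pool = K.rotated_gaussian(K.GaussianSpec(sigma1=pool_sigma))
    out = np.empty_like(data)
    for i in range(n):
        j = (i + n // 2) % n
        prod = data[..., i] * data[..., j]
        out[..., i] = K.rectify(K.filter_bank_apply(prod, pool, border_mode))
    return OrientationField(out, resolution_scale=v1.resolution_scale)


def bown_drive(v2: OrientationField, k: float = 1.0) -> np.ndarray:
    """(h, w, 4) orientation-selective border-ownership drive.

    Each direction phi is driven by contour orientations perpendicular to
    it, with a smooth sin^2 falloff toward parallel orientations (a
    vertical contour drives the left/right channels and leaves up/down at
    zero).
    """
    f = transfer(v2.data, k)
    th = orientations(v2.n_channels)
    phis = bown_directions()
    weights = np.sin(th[None, :] - phis[:, None]) ** 2  # (4, N)
    return np.einsum("hwn,dn->hwd", f, weights)


def bown_init(
    v2: OrientationField, k: float = 1.0, isotropic: bool = False, h_tonic: float = 0.0
) -> BOwnField:
    """Initial border-ownership hypotheses gated by local contour activity.

    With ``isotropic=True`` all four directions receive the mean contour
    energy (the pre-orientation onset state in which every hypothesis is
    equally likely); otherwise the two directions perpendicular to the
    local contour orientation are driven and the parallel ones stay silent.
    """
    if isotropic:
        e = transfer(v2.data, k).mean(axis=-1)
        data = np.repeat(e[..., None], N_BOWN, axis=-1)
    else:
        data = bown_drive(v2, k)
    return BOwnField(data, h_tonic=h_tonic)


def bown_compete_step(
    a: np.ndarray,
    b: np.ndarray,
    A: np.ndarray,
    alpha: float = 0.2,
    beta_inh: float = 1.0,
    dt: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of mutual competition between opposing directions.

    da/dt = -alpha*a + A*(1 - a) - beta_inh*b  (and symmetrically for b):
    shared drive A pushes both toward saturation while each inhibits the
    other, so an initial imbalance grows into winner-take-all.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    A = np.asarray(A, dtype=float)
    a2 = a + dt * (-alpha * a + A * (1.0 - a) - beta_inh * b)
    b2 = b + dt * (-alpha * b + A * (1.0 - b) - beta_inh * a)
    if not (np.all(np.isfinite(a2)) and np.all(np.isfinite(b2))):
        raise FloatingPointError("border-ownership competition diverged")
    return np.maximum(a2, 0.0), np.maximum(b2, 0.0)
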