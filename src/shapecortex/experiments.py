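"""Standard simulation protocols: tuning curves and disambiguation runs.

These reproduce the package's reference experiments on synthetic stimuli:
a curvature cell probed with an arc-radius sweep, and the border-ownership
hypothesis count followed across feedback iterations on a convex shape.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fields import OrientationField
from .model import ModelConfig, ModelState, run_model
from .stimuli import StimulusSpec, render
from .v1 import lgn_response, v1_from_linear, v1_linear, v1_simple_bank
from .v2v3 import subsample, v2_curvature

__all__ = [
    "probe_curvature_cell",
    "curvature_tuning_curve",
    "bown_disambiguation_run",
    "bown_counts",
    "surviving_direction_inward_fraction",
]

def _arc_probe_image(radius_v2: float, config: ModelConfig, line_width: float = 2.0):
    """Render a closed circular arc of the given V2-grid radius.

    The probe point (the cell's receptive-field center) sits on the rim at
    the top of the circle, where the tangent is horizontal and the
    curvature center lies below.  A closed contour lets a matched cell
    collect support along its entire osculating ring, which is what makes
    the radius tuning sharp; partial arcs shorter than the ring mostly
    flatten the curve.
    """
    sub = config.v2_subsampling
    r_img = radius_v2 * sub
    pad = 25.0
    h = w = int(2 * r_img + 2 * pad)
    spec = StimulusSpec(
        kind="circle",
        canvas=(h, w),
        radius=r_img,
        line_width=line_width,
    )
    return render(spec), (pad, w / 2.0)


def probe_curvature_cell(
    radius_v2: float, omega_c: float, config: ModelConfig = ModelConfig()
) -> float:
    """Response of one V2 curvature cell to an arc of the given radius.

    The probed cell sits on the arc at its horizontal-tangent midpoint,
    prefers tangent orientation 0 with the curvature center below
    (matching the stimulus geometry), and is tuned to radius ``omega_c``
    (all radii in V2-grid pixels).
    """
    img, (y0, x0) = _arc_probe_image(radius_v2, config)
    on_off = lgn_response(
        img, config.lgn_sigma, config.lgn_kappa, config.lgn_alpha,
        config.lgn_beta, config.border_mode,
    )
    lin = v1_linear(
        v1_simple_bank(
            on_off, config.n_orientations, config.v1_sigma1_px,
            config.v1_sigma2_px, config.v1_omega1, config.border_mode,
        )
    )
    v1f = v1_from_linear(lin, k=config.v1_k, alpha=config.v1_alpha, beta=config.v1_beta)
    sub = config.v2_subsampling
    v1_v2 = OrientationField(subsample(v1f.data, sub), resolution_scale=sub)
    curv = v2_curvature(
        v1_v2, omega_c, config.curv_sigma_dist, config.curv_sigma_ring,
        config.border_mode,
    )
    ry, rx = int(round(y0 / sub)), int(round(x0 / sub))
    # +-1 px window absorbs the rounding of the arc onto the coarse grid
    patch = curv.data[max(ry - 1, 0) : ry + 2, max(rx - 1, 0) : rx + 2, 0, 0]
    return float(patch.max())


def curvature_tuning_curve(
    omega_c: float,
    radii,
    config: ModelConfig = ModelConfig(),
) -> list[tuple[float, float]]:
    """(stimulus radius, response) pairs for one curvature cell."""
    return [(float(r), probe_curvature_cell(float(r), omega_c, config)) for r in radii]


def bown_disambiguation_run(
    radius: float = 55.0,
    canvas: int = 128,
    config: ModelConfig | None = None,
    n_iterations: int = 10,
) -> tuple[list[ModelState], np.ndarray, np.ndarray]:
    """Run the full recurrent model on a convex shape (disc outline).

    Returns the state history, the boundary mask on the V2 grid and the
    rendered image.
    """
    if config is None:
        config = ModelConfig()
    config = replace(config, n_iterations=n_iterations)
    img = render(
        StimulusSpec(kind="circle", radius=radius, line_width=2.0,
                     canvas=(canvas, canvas))
    )
    history = run_model(img, config)
    v2e = history[0].v2.data.sum(axis=-1)
    mask = v2e > 0.2 * v2e.max(initial=0.0)
    return history, mask, img


def bown_counts(history, mask, threshold: float = 0.1) -> list[float]:
    """Median active-hypothesis count per iteration (channels above
    ``threshold`` of the local channel maximum on boundary pixels)."""
    from .io import bown_hypothesis_count

    return [bown_hypothesis_count(s.bown, mask, threshold) for s in history]


def surviving_direction_inward_fraction(
    state: ModelState, mask: np.ndarray, center_v2: tuple[float, float]
) -> float:
    """Fraction of boundary pixels whose winning ownership direction points
    toward the shape interior (positive dot product with the inward ray)."""
    data = state.bown.data
    ys, xs = np.nonzero(mask)
    winners = np.argmax(data[ys, xs], axis=-1)
    phis = state.bown.phis[winners]
    ux, uy = np.cos(phis), np.sin(phis)
    cy, cx = center_v2
    ix, iy = cx - xs, cy - ys
    inward = ux * ix + uy * iy > 0
    return float(np.mean(inward)) if inward.size else 0.0
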