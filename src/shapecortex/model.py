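"""Recurrent orchestration of the model areas.

One feedforward sweep builds LGN -> V1 -> (1:3) V2 long-range / curvature /
corner / border-ownership -> (1:4) V4 -> IT.  Each further iteration applies
the modulatory feedback pathways with a one-iteration delay (V2 -> V1,
V4 -> V2 curvature, V2 orientation -> border ownership, IT -> border
ownership) and recomputes the areas in ascending order.  Feedback can only
amplify existing bottom-up activity: with every pathway disabled, all
iterations reproduce the feedforward state bitwise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import v1 as V1
from . import v2v3 as V2
from .cascade import modulate, transfer
from .fields import BOwnField, CurvatureField, OrientationField
from .it import ITParams, it_feedback_to_bown, it_response
from .v4 import V4Params, v4_curvature_response, v4_opponent_equilibria, v4_subfield_responses

__all__ = [
    "ModelConfig",
    "ModelState",
    "upsample",
    "feedback_v2_to_v1",
    "feedback_v4_to_v2curv",
    "bown_update",
    "run_feedforward",
    "run_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """All tunable constants of the model, one named field per parameter.

    Receptive-field widths tagged ``relative`` are fractions of the area's
    filter size.  Feedback toggles switch individual recurrent pathways.
    """

    # population sizes and schedule
    n_orientations: int = 8
    n_bown_directions: int = 4
    n_iterations: int = 6
    # LGN
    lgn_sigma: float = 1.0
    lgn_kappa: float = 1.5
    lgn_alpha: float = 2.17e-3
    lgn_beta: float = 2.17e-3
    # V1
    v1_filter_size: float = 13.0
    v1_sigma1: float = 0.23  # relative, along the contour
    v1_sigma2: float = 0.12  # relative, across
    v1_omega1: float = 3.0
    v1_alpha: float = 2.16e-6
    v1_beta: float = 1.0
    v1_k: float = 4.0
    # V2 long-range
    v2_subsampling: int = 3
    v2_filter_size: float = 41.0
    v2_sigma1: float = 0.21  # relative
    v2_sigma2: float = 0.02  # relative
    v2_sigma3: float = 0.10  # relative
    v2_omega_ex: float = 3.7
    v2_omega_inh: float = 2.5
    v2_gamma: float = 0.10
    v2_k: float = 1.0
    v2_alpha: float = 1.0
    v2_beta: float = 1.0
    lambda_v2_v1: float = 0.11
    # V2 curvature
    curv_omega_c: float = 15.0
    curv_sigma_dist: float = 40.0
    curv_sigma_ring: float = 2.0
    lambda_v4_v2: float = 0.15
    # V2/V3 corners
    corner_pool_sigma: float = 2.0
    # border ownership
    bown_k: float = 1.0
    bown_h_tonic: float = 0.01
    bown_lambda_it: float = 50.0
    bown_dt: float = 0.2
    bown_euler_steps: int = 3
    bown_comp_alpha: float = 0.2
    bown_comp_beta: float = 1.0
    bown_comp_steps: int = 5
    # V4
    v4_subsampling: int = 4
    v4_filter_size: float = 31.0
    v4_alpha4: float = 0.01
    v4_sigma4: float = 0.43  # relative, cross-axial
    v4_sigma4b: float = 1.35  # relative, axial
    v4_omega: float = -1.0
    v4_k: float = 4.0  # output transfer exponent (unset in the source; V1's reused)
    v4_use_corner_input: bool = True
    # IT
    it_omega: float = 17.0
    it_sigma: float = 0.43
    it_sigma_radial: float = 29.0
    it_k: float = 3.0
    it_alpha: float = 5.49e-5
    it_beta: float = 1.0
    # feedback toggles
    fb_v2_v1: bool = True
    fb_v4_v2: bool = True
    fb_v2_bown: bool = True
    fb_it_bown: bool = True
    # numerics
    border_mode: str = "reflect"
    rng_seed: int = 0

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    # -------------------------------------------------------- derived bits
    def v2_params(self) -> V2.V2Params:
        return V2.V2Params(
            filter_size=self.v2_filter_size,
            sigma1=self.v2_sigma1,
            sigma2=self.v2_sigma2,
            sigma3=self.v2_sigma3,
            omega_ex=self.v2_omega_ex,
            omega_inh=self.v2_omega_inh,
            gamma=self.v2_gamma,
            k=self.v2_k,
            alpha=self.v2_alpha,
            beta=self.v2_beta,
            grid_scale=self.v2_subsampling,
        )

    @property
    def curv_sigma_dist_v2(self) -> float:
        """Distance-falloff width converted from image to V2-grid pixels."""
        return self.curv_sigma_dist / self.v2_subsampling

    def v4_params(self) -> V4Params:
        return V4Params(
            alpha4=self.v4_alpha4,
            sigma4=self.v4_sigma4,
            sigma4b=self.v4_sigma4b,
            omegaV4=self.v4_omega,
            filter_size=self.v4_filter_size,
            scale=self.v4_subsampling,
        )

    def it_params(self) -> ITParams:
        return ITParams(
            omega_it=self.it_omega,
            sigma_it=self.it_sigma,
            sigma_radial=self.it_sigma_radial,
            k_it=self.it_k,
            alpha_norm=self.it_alpha,
            beta_norm=self.it_beta,
        )

    @property
    def v1_sigma1_px(self) -> float:
        return self.v1_sigma1 * self.v1_filter_size

    @property
    def v1_sigma2_px(self) -> float:
        return self.v1_sigma2 * self.v1_filter_size


@dataclass
class ModelState:
    """Per-iteration snapshot of all area responses (native resolutions)."""

    iteration: int
    v1: OrientationField
    v2: OrientationField
    v2curv: CurvatureField
    corners: OrientationField
    bown: BOwnField
    v4: OrientationField
    v4_left: np.ndarray
    v4_right: np.ndarray
    it: np.ndarray

    def check_finite(self) -> None:
        named = {
            "V1": self.v1.data,
            "V2": self.v2.data,
            "V2curv": self.v2curv.data,
            "V2/V3 corners": self.corners.data,
            "BOwn": self.bown.data,
            "V4": self.v4.data,
            "IT": self.it,
        }
        for area, arr in named.items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite activation in area {area} at iteration "
                    f"{self.iteration}"
                )


def upsample(fld: np.ndarray, factor: int, target_shape=None) -> np.ndarray:
    """Nearest-neighbor expansion, optionally cropped to ``target_shape``.

    Inverse of block-average subsampling on constant fields:
    upsample(subsample(c)) == c.
    """
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    fld = np.asarray(fld, dtype=float)
    out = np.repeat(np.repeat(fld, factor, axis=0), factor, axis=1)
    if target_shape is not None:
        out = out[: target_shape[0], : target_shape[1]]
    return out


def _resample(fld: np.ndarray, from_factor: int, to_factor: int, image_shape) -> np.ndarray:
    """Move a channel stack between area grids via the image-resolution grid."""
    full = upsample(fld, from_factor, image_shape)
    return V2.subsample(full, to_factor)


def feedback_v2_to_v1(
    v1_drive: np.ndarray, v2_longrange: OrientationField, config: ModelConfig
) -> tuple[np.ndarray, OrientationField]:
    """Modulate the V1 drive by like-oriented V2 activity and re-derive the
    complex output.

    The V2 long-range field is expanded to the V1 grid and normalized to a
    unit maximum (its own re-normalization constants are free parameters;
    a bounded feedback signal keeps the per-iteration gain at most
    ``(1 + lambda)^k``).  The returned drive carries the accumulated
    modulation, so the recurrent loop amplifies contextually supported
    orientations a little further on every iteration while the shared
    normalization pool damps the unmodulated ones.
    """
    h, w = v1_drive.shape[:2]
    fb = upsample(v2_longrange.data, config.v2_subsampling, (h, w))
    if fb.shape != v1_drive.shape:
        raise ValueError(
            f"feedback shape {fb.shape} does not match V1 {v1_drive.shape}"
        )
    peak = fb.max(initial=0.0)
    if peak > 1e-12:
        fb = fb / peak
    new_drive = modulate(v1_drive, fb, config.lambda_v2_v1)
    field = V1.v1_from_linear(
        new_drive, k=config.v1_k, alpha=config.v1_alpha, beta=config.v1_beta
    )
    return new_drive, field


def feedback_v4_to_v2curv(
    v2curv: CurvatureField,
    v4_left: np.ndarray,
    v4_right: np.ndarray,
    config: ModelConfig,
    image_shape=None,
) -> CurvatureField:
    """Gain-enhance curvature channels whose sign and orientation match
    active V4 cells.  ``v4_left/right`` are the rectified opponent
    equilibria on the V4 grid."""
    h, w = v2curv.data.shape[:2]
    if image_shape is None:
        image_shape = (h * config.v2_subsampling, w * config.v2_subsampling)
    fb = np.stack(
        [
            _resample(v4_left, config.v4_subsampling, config.v2_subsampling, image_shape),
            _resample(v4_right, config.v4_subsampling, config.v2_subsampling, image_shape),
        ],
        axis=-1,
    )[: h, : w]
    # bounded feedback signal: peak gain is (1 + lambda) per iteration
    peak = fb.max(initial=0.0)
    if peak > 1e-12:
        fb = fb / peak
    out = modulate(v2curv.data, fb, config.lambda_v4_v2)
    return CurvatureField(out, omega_c=v2curv.omega_c)


def _bown_drive_raw(
    v2_longrange: OrientationField,
    it_fb: np.ndarray | None,
    config: ModelConfig,
    orientation_selective: bool,
) -> np.ndarray:
    """(h, w, 4) drive of eq.-style border-ownership dynamics.

    The tonic term is proportional to local contour energy, so the drive is
    gated: it vanishes wherever there is no bottom-up contrast.  The whole
    drive is rescaled to a unit maximum, which keeps the mixed
    normalization/competition dynamics on a common activation scale
    without changing any channel ratio.
    """
    energy = transfer(v2_longrange.data, config.bown_k).mean(axis=-1)
    peak = energy.max(initial=0.0)
    # numerically-silent fields stay silent (no renormalization of noise)
    if peak < 1e-12:
        return np.zeros(energy.shape + (config.n_bown_directions,))
    e_norm = energy / peak
    if orientation_selective:
        drive = V2.bown_drive(v2_longrange, config.bown_k)
        dpeak = drive.max(initial=0.0)
        if dpeak > 1e-12:
            drive = drive / dpeak
    else:
        drive = np.zeros(energy.shape + (config.n_bown_directions,))
    drive = drive + config.bown_h_tonic * e_norm[..., None]
    if it_fb is not None:
        drive = drive * (1.0 + config.bown_lambda_it * it_fb)
    peak = drive.max(initial=0.0)
    if peak > 1e-12:
        drive = drive / peak
    return drive


def bown_update(
    bown: BOwnField,
    v2_longrange: OrientationField,
    it_map: np.ndarray | None,
    config: ModelConfig,
) -> BOwnField:
    """One model-iteration update of the border-ownership population.

    Euler steps of the normalization dynamics (drive minus self-shunting
    against the 4-channel pool) followed by mutual competition between the
    opposing-direction pairs (0, 2) and (1, 3).
    """
    it_fb = None
    if config.fb_it_bown and it_map is not None:
        it_fb = it_feedback_to_bown(it_map, config.it_params())
    drive = _bown_drive_raw(
        v2_longrange, it_fb, config, orientation_selective=config.fb_v2_bown
    )
    B = bown.data.copy()
    dt = config.bown_dt
    for _ in range(config.bown_euler_steps):
        pool = B.sum(axis=-1, keepdims=True)
        B = np.maximum(0.0, B + dt * (-B + drive - B * pool))
    # mutual competition across all direction pairs: each hypothesis is
    # inhibited by the summed activity of the others, so the dominant
    # direction eventually takes all the net energy (restricting this to
    # opposing pairs leaves two flanking winners wherever the true inward
    # direction falls between the four channel axes)
    for _ in range(config.bown_comp_steps):
        others = B.sum(axis=-1, keepdims=True) - B
        B2 = B + dt * (
            -config.bown_comp_alpha * B
            + drive * (1.0 - B)
            - config.bown_comp_beta * others
        )
        if not np.all(np.isfinite(B2)):
            raise FloatingPointError("border-ownership competition diverged")
        B = np.maximum(0.0, B2)
    return BOwnField(B, h_tonic=config.bown_h_tonic)


def _forward_areas(v1_field, config, image_shape, prev=None):
    """Compute the V2 family, V4 and IT from a V1 complex field.

    ``prev`` is the previous iteration's state used for the one-step
    delayed feedback pathways (or None for the pure feedforward sweep).
    """
    v1_v2 = OrientationField(V2.subsample(v1_field.data, config.v2_subsampling),
                             resolution_scale=config.v2_subsampling)
    v2lr = V2.v2_longrange(v1_v2, config.v2_params(), config.border_mode)
    curv = V2.v2_curvature(
        v1_v2, config.curv_omega_c, config.curv_sigma_dist,
        config.curv_sigma_ring, config.border_mode,
    )
    if prev is not None and config.fb_v4_v2:
        curv = feedback_v4_to_v2curv(
            curv, prev.v4_left, prev.v4_right, config, image_shape
        )
    corners = V2.v2v3_corner(v1_v2, config.corner_pool_sigma, config.border_mode)

    # border ownership: isotropic onset, then normalization + competition
    if prev is None:
        bown = _init_bown(v2lr, config)
    elif config.fb_v2_bown or config.fb_it_bown:
        bown = bown_update(prev.bown, v2lr, prev.it, config)
    else:
        bown = prev.bown

    # V4 on its own grid; the curvature drive is normalized to a unit
    # maximum so the opponent decay constant alpha4 acts as a fixed
    # fraction of the strongest available evidence
    curv_data = curv.data
    peak = curv_data.max(initial=0.0)
    if peak > 0:
        curv_data = curv_data / peak
    curv_v4 = CurvatureField(
        _resample(curv_data, config.v2_subsampling, config.v4_subsampling, image_shape),
        omega_c=curv.omega_c,
    )
    extra = None
    if config.v4_use_corner_input and peak > 0:
        # corners share the curvature drive's scale so that a corner-free
        # scene cannot have its corner noise blown up to unit amplitude
        extra = _resample(
            corners.data / peak, config.v2_subsampling, config.v4_subsampling,
            image_shape,
        )
    A, Bf = v4_subfield_responses(curv_v4, config.v4_params(), extra, config.border_mode)
    v4_left, v4_right = v4_opponent_equilibria(A.data, Bf.data, config.v4_alpha4)
    # expansive output transfer sharpens the bounded opponent contrast
    v4_left = transfer(v4_left, config.v4_k)
    v4_right = transfer(v4_right, config.v4_k)
    v4resp = v4_curvature_response(A, Bf, config.v4_alpha4)
    v4resp = OrientationField(
        transfer(v4resp.data, config.v4_k), resolution_scale=config.v4_subsampling
    )

    it_map = it_response(bown, config.it_params())
    return v1_v2, v2lr, curv, corners, bown, v4resp, v4_left, v4_right, it_map


def _init_bown(v2lr: OrientationField, config: ModelConfig) -> BOwnField:
    """Onset state: every direction carries the (normalized) isotropic
    contour-energy drive, so all four hypotheses start equal."""
    drive = _bown_drive_raw(v2lr, None, config, orientation_selective=False)
    return BOwnField(drive, h_tonic=config.bown_h_tonic)


def _min_image_size(config: ModelConfig) -> int:
    return 2 * int(np.ceil(config.v1_filter_size / 2)) + 1


def run_feedforward(I: np.ndarray, config: ModelConfig = ModelConfig()) -> ModelState:
    """One pure feedforward sweep (iteration 0, no feedback)."""
    I = np.asarray(I, dtype=float)
    if I.ndim != 2:
        raise ValueError("input image must be 2-D grayscale")
    if min(I.shape) < _min_image_size(config):
        raise ValueError(
            f"image {I.shape} smaller than the V1 filter "
            f"({_min_image_size(config)} px)"
        )
    on_off = V1.lgn_response(
        I, config.lgn_sigma, config.lgn_kappa, config.lgn_alpha,
        config.lgn_beta, config.border_mode,
    )
    simple = V1.v1_simple_bank(
        on_off, config.n_orientations, config.v1_sigma1_px,
        config.v1_sigma2_px, config.v1_omega1, config.border_mode,
    )
    linear = V1.v1_linear(simple)
    v1_field = V1.v1_from_linear(
        linear, k=config.v1_k, alpha=config.v1_alpha, beta=config.v1_beta
    )
    (_, v2lr, curv, corners, bown, v4resp, v4l, v4r, it_map) = _forward_areas(
        v1_field, config, I.shape, prev=None
    )
    state = ModelState(0, v1_field, v2lr, curv, corners, bown, v4resp, v4l, v4r, it_map)
    state.check_finite()
    state._v1_linear = linear  # cached stimulus drive for the recurrent loop
    return state


def run_model(
    I: np.ndarray, config: ModelConfig = ModelConfig()
) -> list[ModelState]:
    """Full recurrent run: feedforward sweep plus n_iterations feedback
    iterations; returns the per-iteration state history (index = iteration).

    Deterministic: identical input and config give a bitwise-identical
    history.
    """
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    I = np.asarray(I, dtype=float)
    state = run_feedforward(I, config)
    drive = state._v1_linear
    history = [state]
    for t in range(1, config.n_iterations + 1):
        if config.fb_v2_v1:
            drive, v1_field = feedback_v2_to_v1(drive, history[-1].v2, config)
        else:
            v1_field = history[-1].v1
        (_, v2lr, curv, corners, bown, v4resp, v4l, v4r, it_map) = _forward_areas(
            v1_field, config, I.shape, prev=history[-1]
        )
        state = ModelState(t, v1_field, v2lr, curv, corners, bown, v4resp, v4l, v4r, it_map)
        state.check_finite()
        history.append(state)
    return history
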