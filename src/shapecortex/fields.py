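"""Population-coded response fields of the model areas.

All fields are retinotopic: the first two axes are (row, col) on the area's
own grid (V1 at image resolution, V2/V3 at 1:3, V4 at 1:4), further axes
index feature channels.  Activations are non-negative firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["N_ORIENT", "N_BOWN", "orientations", "bown_directions",
           "OrientationField", "CurvatureField", "BOwnField"]

#: number of orientation channels (axes modulo pi), step pi/8
N_ORIENT = 8
#: number of border-ownership direction channels, step pi/2
N_BOWN = 4


def orientations(n: int = N_ORIENT) -> np.ndarray:
    """Channel orientations theta_i = i * pi / n."""
    return np.arange(n) * np.pi / n


def bown_directions(n: int = N_BOWN) -> np.ndarray:
    """Ownership directions phi_d = d * 2*pi / n, pointing toward the
    claimed figure side."""
    return np.arange(n) * 2.0 * np.pi / n


def _check_nonneg(data: np.ndarray, name: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.min(initial=0.0) < 0:
        raise ValueError(f"{name} activations must be non-negative")
    return data


@dataclass
class OrientationField:
    """(h, w, N) population over N orientation channels theta_i = i*pi/N."""

    data: np.ndarray
    resolution_scale: int = 1

    def __post_init__(self) -> None:
        self.data = _check_nonneg(self.data, "orientation field")
        if self.data.ndim != 3:
            raise ValueError("orientation field must be (h, w, N)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def theta_step(self) -> float:
        return np.pi / self.n_channels

    @property
    def thetas(self) -> np.ndarray:
        return orientations(self.n_channels)


@dataclass
class CurvatureField:
    """(h, w, N, 2) population over tangent orientation x curvature sign.

    Sign index 0 is 'left' (center of the osculating circle on the left of
    the tangent axis), 1 is 'right'; ``omega_c`` is the tuning radius in
    the field's own (V2) pixels.
    """

    data: np.ndarray
    omega_c: float = 15.0

    def __post_init__(self) -> None:
        self.data = _check_nonneg(self.data, "curvature field")
        if self.data.ndim != 4 or self.data.shape[3] != 2:
            raise ValueError("curvature field must be (h, w, N, 2)")


@dataclass
class BOwnField:
    """(h, w, 4) border-ownership population.

    Channel d points along phi_d = d * pi/2 toward the claimed figure side;
    opposing pairs are (0, 2) and (1, 3).
    """

    data: np.ndarray
    h_tonic: float = 0.0

    def __post_init__(self) -> None:
        self.data = _check_nonneg(self.data, "border-ownership field")
        if self.data.ndim != 3 or self.data.shape[2] != N_BOWN:
            raise ValueError(f"border-ownership field must be (h, w, {N_BOWN})")

    @property
    def phis(self) -> np.ndarray:
        return bown_directions()
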