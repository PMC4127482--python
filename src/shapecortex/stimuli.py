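"""Deterministic synthetic-stimulus renderer.

All probe images (bars, edges, arcs, circles, squares, polygons, Kanizsa
figures, noisy blobs) are rasterized by pure arithmetic on a 4x supersampled
grid and block-averaged down, giving anti-aliased, platform-independent
renders.  Luminance convention: mid-gray background (0.5) with dark (0.1)
or bright (0.9) figures, which avoids border artifacts under reflected
padding.  Noise is added after rendering from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StimulusSpec", "render", "arc_radius_sweep"]

_SUPERSAMPLE = 4

KINDS = ("bar", "edge", "arc", "circle", "disc", "square", "polygon",
         "kanizsa", "blob-with-noise")


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry of one synthetic probe image.

    All lengths are pixels on the output canvas; ``orientation`` follows the
    package convention (counter-clockwise from the horizontal axis, so a bar
    at pi/2 is vertical).  Arcs carry a signed radius: a negative sign
    mirrors the arc about the tangent at its start (curvature direction).
    """

    kind: str = "bar"
    canvas: tuple[int, int] = (128, 128)  # (height, width)
    center: tuple[float, float] | None = None  # (x, y); canvas center if None
    radius: float = 40.0
    orientation: float = 0.0
    line_width: float = 2.0
    length: float = 60.0
    opening_angle: float = np.pi
    start_angle: float = 0.0
    side: float = 60.0
    vertices: tuple[tuple[float, float], ...] = ()
    pacman_radius: float = 20.0
    fill: bool = False
    background: float = 0.5
    foreground: float = 0.1
    noise_std: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.canvas
        return (w / 2.0, h / 2.0)


def _grid(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.canvas
    ss = _SUPERSAMPLE
    ys = (np.arange(h * ss) + 0.5) / ss
    xs = (np.arange(w * ss) + 0.5) / ss
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    cx, cy = spec.center_xy
    return X - cx, Y - cy


def _check_fits(spec: StimulusSpec, extent: float) -> None:
    cx, cy = spec.center_xy
    h, w = spec.canvas
    if cx - extent < 0 or cy - extent < 0 or cx + extent > w or cy + extent > h:
        raise ValueError(
            f"{spec.kind} of extent {extent:.1f} at ({cx:.1f}, {cy:.1f}) "
            f"does not fit on a {w}x{h} canvas"
        )


def _check_arc_fits(spec: StimulusSpec) -> None:
    """Arcs need only their own sector on-canvas, not the full circle."""
    r = abs(spec.radius)
    sign = 1.0 if spec.radius >= 0 else -1.0
    cx, cy = spec.center_xy
    h, w = spec.canvas
    margin = spec.line_width / 2
    angles = spec.start_angle + np.linspace(0.0, spec.opening_angle, 64)
    xs = cx + r * np.cos(angles)
    ys = cy + sign * r * np.sin(angles)
    if (
        xs.min() < margin
        or ys.min() < margin
        or xs.max() > w - margin
        or ys.max() > h - margin
    ):
        raise ValueError(
            f"arc of radius {r:.1f} at ({cx:.1f}, {cy:.1f}) does not fit on "
            f"a {w}x{h} canvas"
        )


def _mask(spec: StimulusSpec) -> np.ndarray:
    X, Y = _grid(spec)
    k = spec.kind
    if k == "edge":
        nx, ny = np.cos(spec.orientation + np.pi / 2), np.sin(
            spec.orientation + np.pi / 2
        )
        return (X * nx + Y * ny > 0).astype(float)
    if k == "bar":
        # bars may run edge-to-edge (an endless line); only the center must
        # lie on the canvas
        cx, cy = spec.center_xy
        h, w = spec.canvas
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValueError("bar center off canvas")
        ux, uy = np.cos(spec.orientation), np.sin(spec.orientation)
        along = X * ux + Y * uy
        perp = -X * uy + Y * ux
        return (
            (np.abs(along) <= spec.length / 2) & (np.abs(perp) <= spec.line_width / 2)
        ).astype(float)
    if k in ("circle", "disc", "blob-with-noise"):
        r = abs(spec.radius)
        _check_fits(spec, r + spec.line_width / 2)
        rr = np.hypot(X, Y)
        if k == "circle":
            return (np.abs(rr - r) <= spec.line_width / 2).astype(float)
        return (rr <= r).astype(float)
    if k == "arc":
        r = abs(spec.radius)
        _check_arc_fits(spec)
        sign = 1.0 if spec.radius >= 0 else -1.0
        rr = np.hypot(X, sign * Y)
        ang = np.mod(np.arctan2(sign * Y, X) - spec.start_angle, 2 * np.pi)
        on_ring = np.abs(rr - r) <= spec.line_width / 2
        in_sector = ang <= spec.opening_angle
        return (on_ring & in_sector).astype(float)
    if k == "square":
        _check_fits(spec, spec.side / 2 + spec.line_width / 2)
        cheb = np.maximum(np.abs(X), np.abs(Y))
        if spec.fill:
            return (cheb <= spec.side / 2).astype(float)
        return (np.abs(cheb - spec.side / 2) <= spec.line_width / 2).astype(float)
    if k == "polygon":
        if len(spec.vertices) < 2:
            raise ValueError("polygon needs at least two vertices")
        cx, cy = spec.center_xy
        d = np.full(X.shape, np.inf)
        verts = list(spec.vertices)
        for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
            ax, ay = x0 - cx, y0 - cy
            bx, by = x1 - cx, y1 - cy
            ex, ey = bx - ax, by - ay
            ee = ex * ex + ey * ey
            t = np.clip(((X - ax) * ex + (Y - ay) * ey) / max(ee, 1e-12), 0.0, 1.0)
            d = np.minimum(d, np.hypot(X - ax - t * ex, Y - ay - t * ey))
        return (d <= spec.line_width / 2).astype(float)
    if k == "kanizsa":
        _check_fits(spec, spec.side / 2 + spec.pacman_radius)
        half = spec.side / 2
        inside_square = (np.abs(X) < half) & (np.abs(Y) < half)
        m = np.zeros(X.shape, dtype=bool)
        for sx in (-1, 1):
            for sy in (-1, 1):
                m |= np.hypot(X - sx * half, Y - sy * half) <= spec.pacman_radius
        return (m & ~inside_square).astype(float)
    raise ValueError(f"unknown stimulus kind {k!r}")  # pragma: no cover


def render(spec: StimulusSpec) -> np.ndarray:
    """Render an anti-aliased grayscale image in [0, 1]."""
    mask = _mask(spec)
    ss = _SUPERSAMPLE
    h, w = spec.canvas
    mask = mask.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = spec.background + (spec.foreground - spec.background) * mask
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def arc_radius_sweep(
    radii: list[float] | np.ndarray, base_spec: StimulusSpec
) -> list[np.ndarray]:
    """Render one image per radius, identical otherwise (order preserving)."""
    if np.any(np.asarray(radii, dtype=float) <= 0):
        raise ValueError("sweep radii must be positive")
    return [render(replace(base_spec, radius=float(r))) for r in radii]
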