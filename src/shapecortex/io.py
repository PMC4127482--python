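"""Export of response maps, run summaries and tuning curves.

Raw multi-channel activations are written as a zip of binary arrays
(NumPy ``.npz``) with a JSON sidecar naming the axes of every array, so a
reload is bit-identical.  PNG visualizations are normalized per map (the
peak is recorded in the sidecar) and are comparable only within one map.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .fields import BOwnField, CurvatureField, OrientationField
from .model import ModelConfig, ModelState

__all__ = [
    "save_image",
    "load_image",
    "export_state",
    "load_state_arrays",
    "export_tuning_curve",
    "run_summary",
    "bown_hypothesis_count",
]

_AXES = {
    "v1": ["y", "x", "orientation"],
    "v2": ["y", "x", "orientation"],
    "v2curv": ["y", "x", "orientation", "sign"],
    "corners": ["y", "x", "orientation"],
    "bown": ["y", "x", "direction"],
    "v4": ["y", "x", "orientation"],
    "it": ["y", "x"],
}

FORMAT_VERSION = 1


def save_image(path, img: np.ndarray, bits: int = 8) -> None:
    """Write a [0, 1] grayscale image as 8- or 16-bit PNG/PGM."""
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bits == 8:
        arr = np.round(img * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bit depth must be 8 or 16")
    iio.imwrite(path, arr)


def load_image(path) -> np.ndarray:
    """Read an image file as [0, 1] luminance (color reduced to mean)."""
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    peak = 65535.0 if arr.max(initial=0) > 255 else 255.0
    return arr / peak


def _state_arrays(state: ModelState) -> dict[str, np.ndarray]:
    return {
        "v1": state.v1.data,
        "v2": state.v2.data,
        "v2curv": state.v2curv.data,
        "corners": state.corners.data,
        "bown": state.bown.data,
        "v4": state.v4.data,
        "it": state.it,
    }


def export_state(
    state: ModelState,
    out_dir,
    areas: list[str] | None = None,
    write_png: bool = True,
) -> list[Path]:
    """Write raw arrays (npz + JSON sidecar) and channel-max PNGs for one
    iteration snapshot; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = _state_arrays(state)
    if areas is not None:
        unknown = set(areas) - set(arrays)
        if unknown:
            raise ValueError(f"unknown areas: {sorted(unknown)}")
        arrays = {k: v for k, v in arrays.items() if k in areas}
    tag = f"iter{state.iteration:03d}"
    written: list[Path] = []
    npz_path = out_dir / f"maps_{tag}.npz"
    np.savez(npz_path, **arrays)
    written.append(npz_path)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "iteration": state.iteration,
        "arrays": {
            name: {
                "axes": _AXES[name],
                "shape": list(arr.shape),
                "png_peak": float(arr.max(initial=0.0)),
            }
            for name, arr in arrays.items()
        },
    }
    sc_path = out_dir / f"maps_{tag}.json"
    sc_path.write_text(json.dumps(sidecar, indent=2))
    written.append(sc_path)
    if write_png:
        for name, arr in arrays.items():
            vis = arr if arr.ndim == 2 else arr.max(axis=tuple(range(2, arr.ndim)))
            peak = vis.max(initial=0.0)
            if peak > 0:
                vis = vis / peak
            png = out_dir / f"{name}_{tag}.png"
            save_image(png, vis)
            written.append(png)
    return written


def load_state_arrays(npz_path) -> dict[str, np.ndarray]:
    """Reload exported raw arrays bit-identically."""
    with np.load(npz_path) as data:
        return {k: data[k].copy() for k in data.files}


def export_tuning_curve(cell_spec: dict, sweep_results, path) -> Path:
    """Write a (stimulus_radius, response) CSV for one cell.

    ``sweep_results`` is a sequence of (radius, response) pairs; the header
    records the cell parameters and the arg-max radius.
    """
    rows = [(float(r), float(v)) for r, v in sweep_results]
    if not rows:
        raise ValueError("empty tuning sweep")
    best = max(rows, key=lambda rv: rv[1])[0]
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        desc = ", ".join(f"{k}={v}" for k, v in cell_spec.items())
        writer.writerow([f"# cell: {desc}; argmax_radius={best:g}"])
        writer.writerow(["stimulus_radius", "response"])
        writer.writerows(rows)
    return path


def bown_hypothesis_count(
    bown: BOwnField, boundary_mask: np.ndarray, threshold: float = 0.1
) -> float:
    """Median number of ownership channels above ``threshold`` of the local
    channel maximum, over the boundary pixels."""
    data = bown.data[boundary_mask]
    local_max = data.max(axis=-1, keepdims=True)
    active = (data > threshold * local_max) & (local_max > 0)
    counts = active.sum(axis=-1)
    counts = counts[local_max[..., 0] > 0]
    return float(np.median(counts)) if counts.size else 0.0


def run_summary(
    history: list[ModelState], config: ModelConfig, boundary_mask: np.ndarray | None = None
) -> dict:
    """JSON-serializable run summary: config hash, grid sizes, per-area
    activation statistics and ownership hypothesis counts per iteration."""
    cfg_yaml = config.to_yaml()
    summary = {
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
        "n_iterations": len(history) - 1,
        "grid_sizes": {
            name: list(arr.shape[:2])
            for name, arr in _state_arrays(history[0]).items()
        },
        "iterations": [],
    }
    for state in history:
        entry = {"iteration": state.iteration, "areas": {}}
        for name, arr in _state_arrays(state).items():
            entry["areas"][name] = {
                "min": float(arr.min(initial=0.0)),
                "mean": float(arr.mean()),
                "max": float(arr.max(initial=0.0)),
            }
        if boundary_mask is not None:
            entry["bown_hypotheses"] = bown_hypothesis_count(state.bown, boundary_mask)
        summary["iterations"].append(entry)
    return summary
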