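# shapecortex

A recurrent, retinotopic model of 2-D shape representation in the ventral
visual stream, for computational neuroscientists and vision researchers who
want an executable account of how oriented contrast, contour grouping,
curvature, corners, border ownership and figure-ground assignment can arise
from a hierarchy of interacting model areas (LGN/V1 → V2/V3 → V4 → IT) with
modulatory top-down feedback.

## The model in brief

Every model area applies the same columnar cascade to its input:

1. linear filtering with kernels built from rotated anisotropic Gaussians
   `G(x; θ, σ₁, σ₂, μ)`, followed by half-wave rectification `⌈R⌉⁺`;
2. modulatory feedback `R ← R·(1 + λ·net_fb)` — feedback can amplify
   existing activity but never create it;
3. a power-law transfer `f(R) = R^k` and shunting normalization
   `R_norm = β f(R) / (α + Ī)` against the mean `Ī` of the local feature
   population, which bounds responses and lets modulated channels damp
   unmodulated ones.

On top of this cascade: V1 simple/complex cells give an 8-channel
orientation population; V2 long-range cells combine two collinear
subfields multiplicatively (an AND gate that bridges gaps and produces
illusory-contour responses, e.g. on the Kanizsa square); V2 curvature
cells integrate tangential responses along an osculating ring of radius
ω_c (left/right of the tangent, 16 channels); V2/V3 corner cells multiply
orthogonal orientations; V4 cells compare the two curvature signs through
an opponent shunting pair, `|A−B|/(2(α₄+A+B))`, silent on straight
contours; IT cells pool inward-pointing border-ownership evidence on an
annulus and feed it back to resolve the four ownership hypotheses down to
the one pointing at the figure. Details, parameter tables and numerical
choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from shapecortex.experiments import (curvature_tuning_curve,
                                     bown_disambiguation_run, bown_counts)
from shapecortex.model import ModelConfig

cfg = ModelConfig()

# probe a V2 curvature cell tuned to radius 20 (V2-grid px) with circles
curve = curvature_tuning_curve(20.0, [12, 16, 20, 24, 28], cfg)
for r, v in curve:
    print(f"{r:6.0f}  {v:8.2f}")

# border-ownership disambiguation on a disc
history, mask, _ = bown_disambiguation_run(n_iterations=8)
print(bown_counts(history, mask))
```

prints

```
    12     75.31
    16     96.15
    20    183.16
    24    111.76
    28     83.27
[4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
```

The tuning curve peaks at stimulus radius 20 — the cell's preferred
radius (60 px at image resolution, since V2 subsamples 1:3). The
ownership trace shows the median number of active direction hypotheses
per boundary pixel: four equally likely directions at stimulus onset
collapse to the single inward-pointing direction once orientation drive,
IT context feedback and mutual competition act (run the intermediate
two-hypothesis stage by disabling IT feedback:
`ModelConfig(fb_it_bown=False)`).

## Command line

```bash
shapecortex run --stimulus kanizsa --iterations 8 --export v1,v2,bown --out out/
shapecortex render --stimulus circle --out circle.png
```

`run` writes per-area, per-iteration response maps (`.npz` raw arrays with
a JSON axis sidecar, plus channel-max PNG visualizations) and a
`summary.json` with the config hash, grid sizes, per-area activation
statistics and ownership hypothesis counts. `--no-feedback` or
`--feedback v2v1,v4v2,v2bown,itbown` select recurrent pathways; with all
feedback off, every iteration reproduces the feedforward sweep bitwise.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the preferred radii of two model curvature
cells (tuning radii 20 and 25 V2 px): it renders anti-aliased arc stimuli
over integer radius sweeps (8–30 and 10–40), runs each through the
LGN → V1 → V2-curvature pathway, and reports the arg-max of every
response-vs-radius curve as JSON.
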