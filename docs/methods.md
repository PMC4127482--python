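# Methods

`shapecortex` implements a recurrent, retinotopic model of 2-D shape
processing in the ventral visual stream. A grayscale image is transformed
into population responses of model areas LGN/V1, V2/V3, V4 and IT, linked
by a feedforward sweep and modulatory feedback loops. This note records the
model, its assumptions, the numerical choices, and what the synthetic
stimuli do and do not establish.

## The columnar cascade

Every area applies the same three-stage cascade to its input:

1. **Linear filtering** with a kernel built from rotated anisotropic
   Gaussians, `G(x; θ, σ₁, σ₂, μ)`, sampled on the integer pixel grid and
   followed by half-wave rectification `⌈R⌉⁺ = max(0, R)`.
2. **Modulatory feedback** `R ← R · (1 + λ · net_fb)`. Feedback is strictly
   multiplicative: it can amplify existing activity but a unit with zero
   bottom-up drive stays silent under any feedback, and zero feedback
   leaves the signal untouched. Pathway strengths λ: V2→V1 0.11,
   V4→V2-curvature 0.15, IT→border-ownership 50.
3. **Power-law transfer and shunting normalization**:
   `f(R) = R^k`, then `R_norm = β·f(R) / (α + Ī)` where `Ī` is the mean of
   `f(R)` over the feature population at the same retinotopic location
   (channels only — no spatial pooling). Normalization preserves the
   channel ranking and bounds responses; an Euler-integrated dynamic form
   (`∂t R = −αR + βf(R) − R·Ī`) is provided and converges to the closed
   form (verified to 1e-6 in the tests).

Orientation convention: θ is an axis (mod π) measured counter-clockwise
from the horizontal image axis; the θ = π/2 channel prefers vertical
contours. Populations: 8 orientations (step π/8), 16 curvature channels
(8 tangents × 2 signs), 4 ownership directions (step π/2).

## Areas

**LGN.** Balanced difference-of-Gaussians (center σ = 1 px, surround
κσ = 1.5 px, each lobe unit mass) split into rectified on/off channels,
normalized against each other (α = β = 2.17e-3).

**V1.** Odd-symmetric simple cells: two opposite-sign Gaussian lobes
elongated along the preferred orientation (σ₁ ≈ 3.0 px, σ₂ ≈ 1.6 px from
the relative widths 0.23/0.12 of a 13-px filter), displaced ±ω₁ = 3 px
across the contour, at two contrast polarities. Complex cells sum the two
rectified polarity responses (hence exact polarity invariance), pool over
a small isotropic neighborhood (σ = 2 px; this bridges the response null
on the centerline of thin lines), then k = 4 transfer and normalization
with α = 2.16e-6. The lobes have unit peak amplitude, not unit mass: the
response scale then grows with the integration area, which places contour
responses above α (pool engaged, competitive damping active) and kernel
sidelobes below it (noise linearized and relatively suppressed).

**V2 long-range grouping (1:3 grid).** Two elongated excitatory subfields
displaced ±ω_ex = 3.7 V2 px along the preferred axis pool like-oriented V1
input and combine as a geometric mean — an AND gate: both flanks must be
driven, which bridges contour gaps (illusory contours) and silences cells
beyond line ends. Two isotropic pools at ±ω_inh = 2.5 V2 px on the
orthogonal axis subtract γ = 0.1 times the all-orientation activity,
suppressing fragments in clutter. Kernel widths are fractions
(0.21/0.02/0.10) of the 41-px (image units) filter size, converted to the
V2 grid. Normalization uses α = 1, β = 1 (constants not tabulated in the
source model): α sits between contour-level drive and off-contour noise,
so weak junk is damped instead of ratio-amplified.

**V2 curvature.** A cell with tangent orientation θ and sign s integrates
oriented input along the ring of radius ω_c around the osculating-circle
center `c = x₀ ± ω_c n̂(θ)`. Weights: distance falloff `exp(−d²/σ₁²)`
(σ₁ = 40 V2 px), a Gaussian ring `exp(−(‖x−c‖−ω_c)²/σ₂²)` (σ₂ = 2 V2 px),
and tangent alignment `⌈cos 2(θⱼ − τ(x))⌉⁺` with τ the ring's local
tangent. The ring integral is gated multiplicatively by the cell's own
tangent-orientation response at x₀ (`gate_local`, default on): without the
gate a cell fires whenever its ring grazes any remote contour, which
smears curvature maps ~2ω_c off every contour and floods the V4 opponency.
Radius tuning arises from ring overlap: a matched closed contour supports
the whole ring, a mismatched one only the tangency neighborhood.

**V2/V3 corners.** Rectified product of each orientation channel with its
orthogonal channel, pooled over a Gaussian surround (σ = 2 V2 px). The
plain product has a known selectivity floor: on a straight edge the two
symmetric oblique channels yield ~10–30% of the junction product, so
corners are the strongest peaks but not 100× the edge level.

**Border ownership.** Four direction hypotheses per location, driven by
contour orientations perpendicular to each direction (smooth `sin²`
falloff across the 8-orientation population). At stimulus onset all four
hypotheses carry the isotropic contour energy. Each model iteration runs
(i) Euler steps of the normalization dynamics
`∂t B = −B + drive − B·ΣB` with
`drive ∝ (V2_⊥ + h_tonic·E)(1 + λ₂·IT_fb)` rescaled to unit maximum
(β and h_tonic are not tabulated; ratios and hypothesis counts are
scale-invariant, h_tonic = 0.01 gated by contour energy E), and (ii)
mutual competition `∂t B_a = −αB_a + A(1−B_a) − β Σ_{b≠a} B_b`
(α = 0.2, β = 1, dt = 0.2, 5 steps/iteration). Competition spans all
direction pairs: restricting it to opposing pairs leaves two flanking
winners wherever the true inward direction falls between the four channel
axes, and a unique ownership assignment can then never form on oblique
boundary segments.

**V4 (1:4 grid).** Opponent curvature pools: A integrates left-sign, B
right-sign curvature input through elongated Gaussian subfields
(σ across 0.43, along 1.35, fractions of the 31-px filter converted to
the V4 grid) displaced ±ω^V4 = −1 V4 px along the orientation. The
opponent shunting pair `∂t R = −α₄R + (1−R)A − (1+R)B` is solved at
equilibrium and combined to `|A−B| / (2(α₄ + A + B))`, α₄ = 0.01 —
zero for straight contours that feed both signs equally, saturating in
contrast. The curvature drive is normalized to unit maximum so α₄ acts as
a fixed fraction of the strongest evidence; the congruent corner input
shares that scale and enters both pools through a centered kernel (so it
cannot unbalance the opponency by itself). The bounded opponent contrast
is passed through the cascade's expansive transfer with k = 4 (no V4
exponent is tabulated; V1's is reused), which separates genuine curvature
(contrast ≈ 0.25+) from the residual flank contrast of straight lines
(≈ 0.06) by two orders of magnitude.

**IT.** A figure-ground cell at x₀ pools ownership activity on a Gaussian
annulus (radius ω_IT = 17, radial width 29, V2-grid px), each boundary
point weighted by the rectified cosine between its ownership direction and
the ray back toward x₀. Weights are normalized to unit total mass — the
pooled value is a weighted average, which keeps the output scale
independent of annulus size and lets the tabulated normalization
(k = 3, α = 5.49e-5) separate figure from ground instead of saturating.
Zero padding at the image border: the outside world supplies no ownership
evidence.

## Recurrence

Iteration t uses iteration t−1's higher-area state (one-step delayed
feedback): V1 is re-derived from the modulated drive, then the V2 family,
then V4, then IT. The V2→V1 and V4→V2 feedback signals are normalized to
unit maximum (bounded per-iteration gain (1+λ)^k), and the V1 modulation
compounds on the previous iteration's drive — a genuine recurrent loop
whose dominance ratio grows gradually over many iterations rather than
jumping to a fixed point. With all pathways disabled, every iteration
reproduces the feedforward sweep bit for bit. Default 6 iterations
(8–12 for full ownership convergence).

## Synthetic stimuli

All probe images are rasterized by pure arithmetic at 4× supersampling and
block-averaged (anti-aliased, platform-independent): bars/endless lines,
step edges, arcs and circles with signed radius, squares and polygons
(outline or filled), Kanizsa figures (four pac-man inducers), and seeded
additive Gaussian noise. Luminance convention: background 0.5, dark
figures 0.1, bright 0.9 — a mid-gray background avoids border artifacts
under reflected padding. The generator emulates the geometry of
psychophysics-style probes only; it does not emulate natural-image
statistics, texture, occlusion layering or photometric noise, so a green
test establishes the mechanism on clean geometry, not performance on
photographs.

Reference experiments built on these stimuli:

- **Curvature tuning**: a cell tuned to ω_c, fixed on the rim of rendered
  circles at its horizontal-tangent point, probed over integer radii
  (V2-grid units). The response curve peaks at the matching radius for
  ω_c ∈ {15, 20, 25}.
- **Ownership disambiguation**: a 128×128 disc (radius 55 px ≈ ω_IT on the
  V2 grid). The median per-boundary-pixel count of hypotheses above 10% of
  the local channel maximum reads 4 at onset, 2 with orientation drive
  only, and 1 with IT feedback and competition; the surviving direction
  points inward at ≥ 99% of boundary pixels.

## Numerical choices and limitations

- Kernels truncate at 3·max(σ) (≲0.3% mass); convolution via
  `scipy.ndimage` for exactness-critical paths and FFT (with symmetric
  padding matching `ndimage`'s reflect) for large integration fields; FFT
  roundoff is clamped before multiplicative combinations.
- Border handling defaults to reflection; IT pooling and its feedback use
  zero padding (no evidence outside the image).
- Peak-normalized feedback signals treat numerically silent fields
  (< 1e-12) as exactly silent, so a blank image yields zero in every area
  at every iteration.
- Arg-max ties (dominant orientation) break to the lowest channel index.
- The model runs one spatial scale per area (the V4 filter size is a
  single configurable constant; a multi-scale bank is future work);
  texture-defined boundaries, motion, and spiking dynamics are out of
  scope.
- Full-resolution (321×481) runs are supported but the shipped experiments
  use 64–201 px canvases to keep runtimes in seconds; grid arithmetic for
  the reference size is checked directly on the resampling operations.
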