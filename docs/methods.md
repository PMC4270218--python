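# Methods

## The stimulus model

Every stimulus is the composition of two surfaces sampled per output pixel
by inverse mapping (shader-style: the color of a pixel is a function of its
coordinates, so no holes can appear):

1. the **figure value** v = f(F⁻¹ p), where f is an analytic scalar field in
   [0, 1] and F the figure's planar transform at time t;
2. the **carrier/mask sample** c = C(M⁻¹ q), a random-dot raster looked up
   nearest-neighbor (dots stay binary) under the carrier transform M.

For stereo stimuli, v maps linearly to a horizontal disparity
d = d_max·(v − zero_plane) (uncrossed convention: larger values lie behind
the display plane), split symmetrically between the eyes; the left eye reads
the carrier view at p + (d/2, 0), the right at p − (d/2, 0), and the views
land in the red and cyan channels respectively. For color stimuli, v indexes
an isoluminant red–green colormap and the mask's opaque dots paint black
over it. For contrast-modulated stimuli the carrier's contrast about the
mean level is multiplied by v; for luminance stimuli v is the gray level
under a black- or white-dot mask.

Coordinates: origin at the image center, x rightward, y downward, angles
clockwise on screen, lengths in pixels.

### Figure fields and their symmetries

| field | value | exact symmetry |
| --- | --- | --- |
| sector wheel (n) | (1 + cos n(θ − φ))/2 | rotation by 2π/n |
| flat sectors (n) | [cos n(θ − φ) ≥ 0] | rotation by 2π/n |
| ring stack (a, r) | (1 + cos 2π·log_r(ρ/a))/2 | scaling by r |
| spiral bundle (n, b) | (1 + cos n·ψ)/2, ψ = θ ± ln(ρ/a)/b | rotation Δθ ≡ scaling e^{bΔθ} |
| grating (λ) | (1 + cos 2πu/λ)/2 | translation by λ |

The angular interpretation of the wheel's "sinusoidal depth profile" (a
cosine in polar angle, peaking at sector centers) is a design choice — it is
the one that makes the n-fold rotation symmetry exact; a radial sinusoid
would not loop. Likewise the ring profile is sinusoidal in log-radius so
that scaling by the common ratio is an exact symmetry, which is what lets a
"continuous" expansion wrap: the compositor keeps the scale of both the
rings and the dot texture wrapped into [1, r), restoring the initial display
each time the pattern has advanced one ring position. Frames at scale s and
s·r are pixel-identical outside the masked annuli (the occluded innermost
ring and everything beyond the outermost visible ring hide the wrap seam).

Sector wheels carry a small masked hub (default 5% of the frame's short
side; 15% for spiral bundles) because the angular profile's spatial
frequency diverges at the pole — the core is unrenderable at pixel scale and
serves as the fixation region. Masked pixels render black and are excluded
from all quantitative checks.

### Motion schedules

Each surface's motion is a time-parameterized planar transform:

* rotation ω (deg/s), scaling σ (factor per second, scale(t) = σᵗ),
  translation v (px/s) — all with optional back-and-forth reversal
  (triangle-wave time integration: constant speed, instantaneous reversal,
  default period 5 s);
* pure shear diag(s(t), 1/s(t)) with s oscillating log-sinusoidally between
  1 and the axis factor at the cycle frequency — det ≡ 1, so area is
  conserved at every instant;
* spiraling = rotation ∘ scaling about a common center.

Rate conventions of the parameter presets: rotation rates in deg/s; scaling
rates in percent per second (117.6 ⇒ σ = 1.176); stereo shear rates as the
percent horizontal extent at the peak of a 0.2 Hz cycle (120/83); color
shear rates in percent per second on a 0.1 Hz cycle, so 108.2 compounds to
1.082⁵ ≈ 148% over the 5 s half-cycle — the source texts give ~146% for the
same condition and 108.2 %/s in the parameter table; the presets follow the
table and this note records the ~2% inconsistency. The ring ratio r = 1.5 is
implied by the published scaling rate: at 117.6 %/s the rings advance
exactly two ring positions over the 5 s half-cycle (1.176⁵ = 1.5²).

### Carriers

Dots are square cells (no anti-aliasing) drawn as independent Bernoulli(0.5)
variables from a seeded PCG64 stream (uniform texture) or a splitmix64 hash
of the cell index (eccentricity texture) — both bit-reproducible across
platforms. The eccentricity texture, used for looming stimuli, grows its
cell size as base·(1 + e/e_ref)^β with β = 1 by default, implemented as
concentric bands of square-cell grids on a geometric size progression:
approximately scale-invariant statistics with isotropic, blocky dots.
Defaults base = 2 px, e_ref = 300 px at 720p; e_ref trades exact scale
invariance against decodability by the verification stereo matcher (the
power law is the model; its scale constant is a free parameter). Flicker
masks either regenerate the raster every frame (true dynamic noise;
inter-frame dot correlation ≈ 0) or jitter one base raster by a small random
similarity transform per frame (≤ 1 dot shift, ≤ 2°, ±2% scale), imitating
the cheaper real-time implementation.

### Stereo rendering precision

The carrier's own transform is sampled nearest-neighbor, but the horizontal
eye shift is applied with linear interpolation along x. Rounding the
disparity to whole pixels instead would put a one-pixel staircase inside
nearly every correlation window of the decoder and floors the round-trip
error at ≈ 0.58 px RMS; sub-pixel application brings it to 0.2–0.45 px. The
disparity amplitude defaults to d_max = 8 px at 1280×720 (the amplitude is
not constrained by the source material).

## Verification instruments

**Disparity decoding** is windowed normalized cross-correlation over integer
shifts in ±(d_max + 2) px with parabolic sub-pixel interpolation at the
peak (suppressed when the peak correlation is exactly 1, where it would only
add noise). The preset round-trip check uses a 17×17 window and a second,
coarse-to-fine pass: the right view is warped by a 5×5-median-smoothed copy
of the first-pass field and re-matched over ±2 px. The second pass removes
the bias a single pass picks up from the disparity gradient across the
window; the large window accommodates the coarse peripheral dots of the
eccentricity carrier. Border columns within the search range and
textureless windows are flagged and excluded. Round-trip RMS against the
applied disparity is verified < 0.5 px for every tabulated stereo condition
at 1280×720 and three time points chosen at full schedule excursion (t = 0,
duration/4, 0.92·duration; the reversal and shear cycles pass through the
identity at half-duration, which would make the middle sample trivial).

**Isoluminance** uses Rec. 709 luma in linear light. The default palette is
red (1, 0, 0) and green (0, 0.2126/0.7152, 0), equated exactly under the
default coefficients; rendering is linear throughout and sRGB-encoded only
at file write, so every convex mixture has identical luma and the frame-wide
luma CV over unmasked pixels is at numerical precision (the verified bound
is 0.5%). Real displays require per-monitor calibration; palette endpoints
and luma coefficients are configurable.

**Similarity registration** is a brute-force search over rotation × scale
grids minimizing masked MSE of bilinear warps (ties broken toward the
smaller |angle|) — robust at desk scale, no log-polar phase correlation
needed. Its headline use is the spiral rotation↔scaling equivalence: with
pitch b = 2·ln(3.5)/π a 350% scaling equals a 90° rotation. Because a
12-arm bundle is also invariant under 30° rotations, a single registration
of the fully scaled frame determines the equivalent rotation only modulo
30° (all multiples of 30° tie at the global minimum, interpolation noise
apart — the suite asserts that 90° is in that tie set). The equivalence
angle is therefore measured by continuity, as the motion is perceived: the
scaling is factored into six sub-scalings of 3.5^(1/6) each, each sub-step's
rotation is found by brute force on a 0.5° grid inside one symmetry period,
and the increments are summed. The measurement yields 90.0°.

## Problem sizes and defaults

Export defaults are 1280×720 at 30 fps (round frame counts; the original
videos used 29.7/25 fps), 10 s runs, disparity 8 px, dot density 0.5
everywhere. Verification renders use the full 1280×720 for stereo round
trips, 512×512 for the spiral-equivalence measurement, and smaller rasters
for unit-level checks. All randomness flows from a single integer seed per
configuration; a written manifest (full resolved config, per-frame
transforms, per-frame SHA-256) is sufficient to re-render a PNG sequence
bit-identically.

## What the synthetic stimuli do and do not show

The renderings reproduce the *constructed* properties of the published
stimuli — geometry, symmetry, disparity content, isoluminance, dot
statistics — and the verification suite proves those properties hold in the
emitted frames. They do not, and cannot, reproduce the perceptual findings
themselves (whether an observer experiences standstill or capture), monitor
gamma or chromatic calibration, human isoluminance settings, vergence, or
chromatic aberration in the eye. Passing tests therefore certify the
stimulus generator, not the illusions.

## Known limitations

* The eccentricity texture's band structure makes dot size a step function
  of eccentricity rather than a smooth power law (the median-size trend is
  monotone, which is what is asserted).
* The block-matching decoder is specialized to the package's own rendered
  pairs (horizontal shifts of a common carrier); it is not a general stereo
  matcher for natural images.
* MP4 export is best-effort via imageio's encoder and carries no bit-exact
  contract; PNG is canonical.
* Shear and spiral motions are planar; disparity amplitude never changes
  over time (no motion-in-depth from interocular velocity differences).
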