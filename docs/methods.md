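# Methods

This note records the models, defaults, and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate about
real data.

## Dynamic profile

A raw burst is a T × H × W stack (defaults T = 512 frames at 100 Hz) recorded
with the reference piezo at rest. Each pixel trace is mean-removed and
transformed with a single rectangular-window periodogram — no taper, no Welch
averaging — which is the simplest estimator consistent with per-voxel power
spectrum analysis. The normalisation is chosen so the power summed over the
positive-frequency bins equals the population variance of the mean-removed
trace (`P_k = 2|X_k|²/T²`, halved at the Nyquist bin); the test suite asserts
this Parseval identity to 1e-8.

Spectral features per pixel:

* mean frequency `f̄ = Σ f·P(f) / Σ P(f)`;
* bandwidth = power-weighted standard deviation of frequency;
* amplitude = population standard deviation over every stride-1 window of 50
  frames, then averaged over windows (sliding, not disjoint, windows).

A pixel with zero residual power ("silent") reports 0 for all three and is
flagged.

HSV mapping (all display constants are configurable; none have canonical
values, so these are documented defaults, not reconstructions of any
particular instrument's rendering):

* Hue: the mean frequency is normalised linearly over `hue_freq_range`
  (default 0 to Nyquist = 50 Hz) and mapped onto the 240°→0° arc, i.e. pure
  blue for the slowest pixels to red for the fastest, never wrapping through
  magenta so the ordering stays unambiguous.
* Saturation: `S = clamp(1 − bandwidth / bandwidth_scale, 0, 1)` with
  `bandwidth_scale = frame_rate/4` by default — bounded and monotone in the
  inverse bandwidth over the range of interest.
* Value: amplitude divided by its 99.5th percentile over the frame, clamped
  to [0, 1]. Percentile clipping keeps a few hot pixels from crushing the
  display scale.

Static FFOCT returns `|i₊ − i₋|/2` from a π-shifted pair: the coherent
amplitude is displayed, not the signed phase. Plane matching maximises the
zero-normalised cross-correlation coefficient at zero lateral lag (plane
selection only); ties break to the lowest index and zero-variance candidate
planes are excluded.

## SAVE profiler

Pipeline order: threshold → interpolate → rotate → ROI mask → area/width →
closure → fit.

* **Thresholding.** Multi-Otsu with `n_classes` classes (default 3); only the
  first (lowest) threshold is kept, separating the scratch from cells and
  their interstices. Thresholds are computed on the first and last frames and
  interpolated linearly through the stack to absorb slow intensity drift.
  On the synthetic stacks the tests use 4 classes because those images have
  four genuine intensity populations (signal-free scratch, dark inter-cell
  borders, dim cells, bright cells); with 3 classes the first level merges
  scratch and borders. The protocol degrades when the wound nearly vanishes
  by the final frame — the dark class becomes too small for the last-frame
  threshold to find — so acquisitions should end while the wound is still a
  few pixels wide.
* **Rotation.** The user-drawn scratch line is mapped to the image column
  axis, choosing the smaller-magnitude rotation when vertical-up-to-sign;
  intensity frames use bilinear, boolean frames nearest-neighbour
  interpolation. The result is cropped to the largest centred axis-aligned
  rectangle free of rotation fill (the valid region of a rotated rectangle is
  centrally symmetric and convex, so the centred rectangle is maximal).
* **ROI.** A simple polygon in the rotated frame, drawn on the first frame
  for closing wounds and on the last for expanding ones, applied to every
  frame. Wound pixels are `(intensity < threshold) ∧ ROI`. No morphological
  cleanup by default; optional small-object removal is off.
* **Widths and closure.** Width per row is the wound-pixel count in that row
  (the scratch is vertical after rotation); min/mean/max are taken over rows
  intersecting the ROI. Closure is `(area(0) − area(t))/area(0) × 100`,
  negative for expansion.
* **Kinetics.** The excess width `y(t) = w̄(t) − closing_limit` (limit
  default 1.5 µm, the middle of the 1–2 µm inter-cell interstice band) is
  fitted with `a·e^{bt} + c·e^{dt}` by deterministic multi-start
  Levenberg–Marquardt: amplitude splits {0.9, 0.5, 0.1} of the initial
  excess and rates {−1, −0.1, −0.01}/T (mirrored to positive when the trace
  is increasing), 27–75 starts, fitting in µm against minutes. Solutions
  whose fastest rate changes a term by more than e³⁰ over the observed window
  are rejected as unidentifiable (they exploit floating-point headroom with
  vanishing-amplitude exploding terms), and among solutions within 0.1 % of
  the best cost the one with the gentlest kinetics wins — keeping every
  quantity derived from the fitted curve stable.
* **Derived quantities** (no canonical formulas exist for either, so these
  are the package's documented definitions): the *characteristic time* is
  the first time at which the fitted excess has decayed to 1/e of its
  initial value — exactly the time constant in the single-exponential limit;
  the *average closing speed* is the initial excess divided by the first
  time the fitted excess falls below the closing limit (the width comes
  within one interstice-width of its plateau), converted to µm/h. If that
  never happens within the acquisition, the mean slope of the fitted width
  over the observed interval is reported and the result is flagged "not
  closed".

Widths are fitted in micrometres; the time axis is minutes with the
configured frame interval (default 1 min/frame).

## Optical flow

Preprocessing: per-frame median filter (default 3 px, suppressing camera line
noise) then non-overlapping temporal block means (default 8 frames),
multiplying the effective frame interval accordingly. Horn–Schunck uses the
original forward-difference cube derivative estimators and the weighted
8-neighbour averaging kernel, zero initialisation, and a fixed iteration
count (default 200; the final mean update norm is reported as a convergence
diagnostic). Before the derivatives, the joint brightness range of the two
frames is normalised to [0, 255]; this calibrates the smoothness weight α
(default 1.0) against a standard image scale and makes the flow exactly
invariant under global intensity offset and rescaling.

Per-pixel velocities are averaged over all consecutive pairs and converted to
µm/h via `pixel_size · 60 / (frame_interval · block_avg)`. Summaries exclude
pixels below the 2 µm/h noise floor — applied to statistics as well as
display, to avoid noise-floor bias — and optionally pixels inside the wound
mask, whose content is noise-dominated. Fronts are split by the side of a
user-supplied vertical wound-axis column; each front's speed is the mean
magnitude of its side and the total closure speed is twice the mean per-front
speed. Quiver export samples one arrow per decimation block with length
proportional to speed.

Horn–Schunck assumes sub-pixel displacements. The analysis parameters should
keep the expected per-pair front displacement at or below ~0.5 px: with
1 µm/px sampling, 1 min frames and fronts up to 8 µm/h, 4-frame blocks
(rather than the default 8) satisfy this, and the cross-method tests use
exactly that configuration. When the per-front speed sits at the 2 µm/h
floor, the floor truncates the lower half of the estimate distribution and
biases the mean upward — an inherent limitation of flooring summaries near
the floor, visible in the slowest test scenario.

## Synthetic data

The wound simulator composites a seeded Voronoi mosaic (dark inter-cell
borders ~2 px wide, per-cell brightness in 0.5–0.85, multiplicative border
factor 0.35, additive speckle, then a 1 px Gaussian point-spread blur that
keeps the texture band-limited, emulating diffraction-limited optics) with a
uniformly dark scratch band (level 0.05 — in D-FFOCT the scratch is
essentially signal-free, while interstices retain partial signal). The sheets
on either side translate rigidly with their border via sub-pixel
interpolation, so optical flow observes the same motion that segmentation
measures. The band is composited with a hard mask after the blur, keeping the
ground-truth masks pixel-exact pre-noise. Additive Gaussian noise (default
σ = 5 % of the unit range) is applied last, then the frame is clipped to
[0, 1].

Border kinetics come in two modes: constant speeds in µm/h per border
(motion stops at the closing limit; the total closing speed is exactly the
sum of the border speeds, giving a well-defined ground truth for recovery
tests) or exponential rates in 1/min (each half-width decays toward
closing_limit/2 — symmetric rates make the mean width a single exponential,
asymmetric rates a true double exponential). The retraction scenario closes
until `retract_onset`, then expands linearly at the border-speed magnitude;
the expansion scenario grows linearly throughout. Default geometry presets
mirror the observed regimes: small (15 µm) wounds close, medium (60 µm)
attempt and retract, large (120 µm) expand. Defaults: 256 px frames, 60
frames at 1 min, initial width 15 µm, total speed 16 µm/h, 5 % noise.

The burst simulator fills mask-defined regions with independent per-pixel
traces: unit-variance Gaussian noise band-pass filtered to
`[f_c − Δf/2, f_c + Δf/2]` and scaled by the amplitude, or a pure
random-phase tone (variance-normalised) when Δf = 0.

What the simulator does *not* emulate: cell proliferation and individual
migration, filipodia, photorealistic organelle texture, intensity drift or
bleaching, interferometric fringe artefacts, and occlusion effects at the
advancing front beyond simple texture replacement. Passing recovery tests
therefore demonstrate correctness of the measurement chain under controlled
kinetics and noise, not performance on every artefact of real acquisitions.

## Test and verification sizes

The recovery tests run on 128–256 px frames with 16–60 frames per stack,
speeds 4–16 µm/h and noise up to 10 % of range; spectral tests use 512-frame
bursts at 100 Hz on small (≤ 16×16) frames. A slight (3°) scratch tilt is
used in quantitative recovery runs: a perfectly axis-aligned noiseless band
yields integer-quantised widths, whereas real scratches are never exactly
aligned, and the tilt restores sub-pixel-smooth mean-width traces.
`scripts/acceptance.py` re-runs the main measurements at these sizes from a
single seed.

## Known limitations

* The bi-exponential model is phenomenological; for traces that are nearly
  linear over the window the fitted (a, b, c, d) are individually poorly
  determined even though the fitted curve — and everything derived from it —
  is stable.
* The first-Otsu-level segmentation assumes the scratch is the darkest
  population in both the first and last frames; nearly-closed final frames
  violate this.
* Flow speeds are biased near the 2 µm/h reporting floor, and the
  Horn–Schunck estimate degrades once per-pair displacements exceed about
  one pixel; choose `block_avg` accordingly.
* Plane matching selects among acquired planes only; no lateral registration
  or sub-plane interpolation is performed.
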