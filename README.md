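# dffoct — scratch-assay quantification for dynamic full-field OCT

Dynamic full-field optical coherence tomography (D-FFOCT) images live cell
cultures label-free: with the interferometer's reference arm at rest, the only
temporal modulation of a pixel comes from sub-cellular motion (largely
mitochondria and other organelles), so the *spectrum* of each pixel's
fluctuation becomes a contrast channel. This package implements the
computational stack for studying wound healing in retinal pigment epithelium
(RPE) scratch assays imaged this way:

* **Dynamic profile** (`dffoct.dynamics`) — renders a raw burst (512 frames at
  100 Hz, typically) as an HSV image: Hue = power-weighted mean fluctuation
  frequency (blue = slow, red = fast), Saturation = inverse frequency
  bandwidth (narrow-band signals give vivid colours), Value = running standard
  deviation over a 50-frame moving window, averaged. Static FFOCT amplitude
  from π-phase-shifted pairs and axial plane matching by cross-correlation are
  included.
* **SAVE profiler** (`dffoct.profiler`) — scratch-assay velocity evolution:
  multi-Otsu segmentation of the wound (first threshold level, interpolated
  linearly between first and last frame), rotation of the stack so the
  user-drawn scratch line is vertical, ROI masking, per-frame area and
  row-wise width statistics, wound closure
  `(area(0) − area(t)) / area(0) × 100`, and a bi-exponential fit
  `w(t) = limit + a·e^{bt} + c·e^{dt}` of the mean width from which a
  characteristic time (first 1/e decay of the excess width) and an average
  closing speed (µm/h) are derived.
* **Optical flow** (`dffoct.flow`) — an independent cross-check: classical
  Horn–Schunck dense flow after median filtering and temporal block
  averaging, summarised per wound front; the total closure speed is twice the
  mean per-front speed, since two opposing fronts advance simultaneously.
* **Synthetic data** (`dffoct.simulate`) — ground-truthed generators: a
  Voronoi-textured epithelial sheet cut by a scratch whose borders close,
  retract, or expand with known kinetics, and raw bursts with controlled
  per-region spectral content. Every pipeline stage is testable without
  external data.

## Worked example

Simulate a small closing scratch (initial width 15 µm, borders closing at
8 µm/h each, 5 % noise), then quantify it with both methods and merge:

```sh
dffoct simulate --preset small-close --seed 7 --n-frames 30 \
    --image-size 192 --pixel-size 1.0 --out demo/sim
# config: pixel_size 1.0 um/px, 4 threshold classes, 4-frame flow blocks
dffoct scratch --input demo/sim/stack.tif --roi demo/sim/geometry.json \
    --config demo/cfg.yaml --out demo/scr
dffoct flow --input demo/sim/stack.tif --axis-col 96 \
    --config demo/cfg.yaml --out demo/flw
dffoct report --scratch-dir demo/scr --flow-dir demo/flw --out demo/report.json
```

The `scratch` step prints the kinetics fit:

```
Bi-exponential wound-width fit: w(t) = limit + a*exp(b*t) + c*exp(d*t)
  a = 143.284 um      b = -0.00557904 1/min
  c = -129.854 um      d = -0.0041944 1/min
  closing limit       = 1.5 um
  characteristic time = 39.37 min
  average speed       = 13.51 um/h
  closed within acquisition: False (speed over observed interval)
  converged = True   residual RMS = 0.05281 um
```

and the merged report compares the two independent speed estimates:

```json
{
  "save_profiler_speed_um_h": 13.51,
  "optical_flow_total_speed_um_h": 14.96,
  "characteristic_time_min": 39.37,
  "final_closure_pct": 43.38
}
```

The simulated ground-truth total closing speed is 16 µm/h: the
segmentation-based estimate (13.5 µm/h) and the flow-based estimate
(15.0 µm/h) agree with it and with each other within the expected tolerance
of these methods, mirroring how the two analyses corroborate each other on
real acquisitions. The wound had not fully closed within the 30-minute
window, so the reported speed is the mean shrinkage rate of the fitted width
over the observed interval and `closure` reaches 43 % by the final frame.

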