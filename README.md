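# phstrip

Readout pipeline for colorimetric pH indicator strips photographed in a
light box next to two printed reference color grids.

The pipeline works entirely in CIE 1976 u'v' chromaticity:

1. **ROI detection** (`phstrip.roi`) — median filtering, Canny edges with
   morphological closing, rectangular contour extraction, labeling of the
   two 6x18 reference rectangles and the four strip patches, principal-axis
   placement of the 216 + 4 sampling positions, windowed color retrieval.
2. **Color adaptation** (`phstrip.adaptation`) — a 20-parameter third-order
   bivariate polynomial mapping between u'v' color sets, fitted per output
   channel by least-absolute-deviation IRLS (20 iterations, residual clamp
   0.01).
3. **Calibration** (`phstrip.calibration`) — from 15 comparison-chart
   captures (one per integer pH 0–14), every capture is adapted into the
   pivot (pH 7) frame; the four adapted patch colors per index are
   interpolated over pH with a cubic smoothing spline
   (`sum (y - f)^2 + lambda * int f''^2`, `lambda = 3/7`) onto a 0.1 grid.
   The stored product is the pivot reference grid plus 4 curves x 141
   points, serialized as JSON.
4. **Measurement** (`phstrip.matching`) — a new capture is adapted onto the
   pivot reference colors and the pH is the grid point minimizing the
   summed L1 u'v' distance of the four adapted patch colors to the stored
   curves. `summarize_replicates` reproduces the published replicate
   statistics convention (mean absolute error; population standard
   deviation; exact-decimal half-up rounding to 2 decimals).
5. **Synthetic scenes** (`phstrip.synthetic`) — renders light-box scenes
   with known ground truth: seeded palettes, a smooth per-patch
   color-vs-pH strip model, camera color distortion in the same polynomial
   family, brightness gain, affine geometry jitter, and pixel noise. All
   tests run against these renders; no captured images are required.

## CLI

```sh
# render a full synthetic suite: 15 charts (ph00.png..ph14.png) + scenes
phstrip make-suite --out suite/ --seed 0 --n-measure 4

# build calibration data from the chart images
phstrip calibrate suite/ph*.png --out calibration.json

# measure one capture (prints the pH to one decimal)
phstrip measure suite/measure00.png --calibration calibration.json --out report.json

# aggregate four replicate reports into an Avg|Err|/StdDev row
phstrip replicates rep*.json --ideal 7.0

# inspect detection: overlay image + layout JSON
phstrip detect suite/ph07.png --overlay overlay.png --layout layout.json

# render a single scene with a ground-truth sidecar
phstrip simulate --out scene.png --ph 6.3 --seed 5 --distort --noise-sigma 2
```

All commands accept `--config run.json` holding the IRLS, spline, and
detection settings (unknown keys are rejected; the config digest is logged
into every output).

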