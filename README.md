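# cellcarve

Content-aware resizing of stained blood-smear micrographs that shrinks an
image while leaving white-blood-cell (WBC) nuclei geometrically
undistorted. The pipeline:

1. **Saliency** (`cellcarve.saliency`) — center-surround contrast of
   CIE-Lab color opponency, one-level Haar wavelet orientation bands, and
   HSI saturation at two window scales (default 11/13 px at 800×600),
   fused with weights 0.6 / 0.2 / 0.2 into a saliency map.
2. **Attention** (`cellcarve.attention`) — Otsu thresholding,
   morphological closing, removal of regions under 3% of the image,
   per-region bounding boxes, and inscribed **elliptical attention
   windows (EAWs)** with a Euclidean distance-transform strength ramp.
3. **SSM** (`cellcarve.ssm`) — the Saliency Strength Map: smoothed
   average of saliency and EAW strength, normalized to 0–255; the
   carving energy.
4. **Carving** (`cellcarve.carve`) — forward-energy seam carving driven
   by the SSM, with automatic target sizing from the EAW extents and a
   gradient-magnitude baseline energy for comparison. The DP uses a
   numba kernel when available, with an exact numpy fallback.
5. **Metrics** (`cellcarve.metrics`) — MSE/PSNR and the per-nucleus
   Ratio of Distortion (fraction of original nucleus pixels lost),
   registered exactly through the seam log.
6. **Synthetic smears** (`cellcarve.synthetic`) — seeded generator of
   smear-like images (purple textured nuclei, pink red-cell clutter,
   pale field) with exact ground-truth masks.

## CLI

```sh
# make a synthetic smear with ground truth
cellcarve synth --seed 4 -o smear.png --truth truth.json

# carve to the automatic nucleus-preserving target
cellcarve resize smear.png -o small.png --auto \
    --save-ssm ssm.png --save-eaws eaws.json --save-seams seams.json

# baseline comparison at an explicit size (WxH)
cellcarve resize smear.png -o base.png --energy gradient --target 640x480

# per-nucleus PSNR / Ratio-of-Distortion report
cellcarve eval smear.png small.png --masks truth.json \
    --seamlog seams.json --report report.json

# export intermediates only
cellcarve ssm smear.png --save-ssm ssm.png --save-eaws eaws.json
```

Exit codes: 0 success, 2 invalid input/config, 3 no EAWs under `--auto`.
Configuration (weights, filter scales, closing radius, smoothing sigma,
margin, target policy…) is a YAML file passed via `--config`; see
`cellcarve.config.PipelineConfig` for keys and defaults. Size-dependent
parameters scale linearly with the input relative to the 800×600
reference.

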