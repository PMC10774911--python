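# ulmkit

Ultrasound localization microscopy (ULM) reconstructs microvascular
structure and measures intravascular flow by localizing and tracking
microbubbles across thousands of contrast-enhanced ultrasound (CEUS)
frames.  The catch: a 1–5 μm bubble images as a trace hundreds of microns
wide (for a 5.5 MHz scanner, wavelength λ = 280 μm and traces of 0.5–1 mm),
so every downstream quantity — vessel separation, velocity profiles, vessel
radii — hinges on estimating each trace's center far below the pixel size.

`ulmkit` is a toolkit for that problem, aimed at researchers developing or
benchmarking ULM localizers.  It provides:

* **Synthetic CEUS generation** — the forward model `y = k ⊗ x + n`
  (point scatterers, spatially varying elongated PSFs, speckle background)
  with ground truth, plus parallel-line and parabolic-vessel motion
  scenarios;
* **Blind deconvolution** — alternating minimization of
  `‖x⊗k − y‖² + γ‖k‖² + α₁‖x‖₀ + α₂‖∇x‖₀` by half-quadratic splitting,
  estimating the PSF per 80 × 80-pixel interrogation window and extracting
  sub-pixel centers on the λ/14 grid;
* **SupBD-net** — a supervised residual super-resolution network
  (ConvBlocks → 4 ResBlocks → global skip → stride-3 transposed
  convolution → sigmoid) mapping a native window to a 3×-resolved
  center-likelihood map, implemented in pure numpy with hand-verified
  backprop;
* **SelfBD-net** — self-supervised adaptation to unknown PSFs: a k-net
  deforms a Gaussian disk into the local kernel by minimizing raw-frame
  losses on intensity, gradient, and Hessian channels with tanh-L0
  sparsity surrogates, then the localizer's tail layers are refined;
* **Tracking** — constant-velocity Kalman + Hungarian assignment with an
  overlapping-trace correction that repairs tracks broken when two traces
  merge into one detection;
* **Vessel metrology** — trajectory heatmaps, multi-Gaussian line profiling
  (location error `E_l`, width `ε_l`), ghost-line classification
  (`0.10·AF + 0.038·ID − 4.64 < 0` → negligible), velocity-profile errors
  `E_u`, and radius estimation from parabolic zero crossings.

See `docs/methods.md` for the models, conventions, and numerical choices.

## A worked example

```python
import numpy as np
from ulmkit import GridSpec, NoiseSpec, make_psf, random_bubbles, synthesize_frame
from ulmkit.blind_deconv import BDConfig, bd_extract_centers, bd_threshold, deconvolve_frame
from ulmkit.localization import localization_error

grid = GridSpec()                      # 80 x 80 px of 60 um, lambda = 280 um
psf = make_psf(500, 276)               # FWHM 500 x 276 um, aspect ratio 1.81
rng = np.random.default_rng(0)

bubbles = random_bubbles(0.5, grid, rng)            # 0.5 bubbles per mm^2
frame, truth = synthesize_frame(bubbles, psf, NoiseSpec(0.16), grid, rng)

scatter = deconvolve_frame(frame, psf, BDConfig())
centers = bd_extract_centers(scatter, grid, threshold=bd_threshold(frame[None]),
                             frame_image=frame)
report = localization_error(truth, centers, gate_um=psf.fwhm_minor_um / 2)
print(len(truth), len(centers), round(report.E_c_um, 1))
```

prints (for this seed)

```
13 13 44.9
```

— 13 bubbles placed, 13 detected, and a mean center error `E_c` of 44.9 μm
(0.16 λ) from a single noisy frame whose traces are ~500 μm wide; this
one frame happens to contain two overlapping pairs, which dominate the
mean (averaged over hundreds of frames the error settles near 0.1 λ, the
expected blind-deconvolution level at this concentration and noise).  The `examples/` directory walks through each
capability the same way: frame synthesis, blind deconvolution, supervised
training, self-supervised PSF adaptation, macro-vessel velocimetry, and
micro-vessel line separation; each script prints the numbers it computes
and says what they mean.

A thin CLI mirrors the common paths:

```bash
ulmkit simulate frames --out frames.tif --n-frames 50 --seed 1
ulmkit bd centers frames.tif --out centers.csv
ulmkit track centers.csv --out tracks.csv
```

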