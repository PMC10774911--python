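# Methods

`ulmkit` implements the computational core of ultrasound localization
microscopy (ULM): given contrast-enhanced ultrasound (CEUS) frames in which
each microbubble appears as a trace two orders of magnitude larger than the
bubble itself, estimate bubble centers at sub-wavelength precision, link
them into tracks, and extract vascular metrology from the tracks.  Because
ground truth is unobtainable in vivo, the package also generates the
synthetic benchmark on which every method is scored.

## Forward model and synthetic data

A frame is modeled as `y = k ⊗ x + n`: point scatterers `x` convolved with
a spatially varying point-spread function `k`, plus background noise `n`.
The geometry follows a 5.5 MHz clinical transducer: wavelength λ = 280 μm,
native pixel 60 μm (λ/4.6), 80 × 80-pixel interrogation windows
(4.8 × 4.8 mm²), 48 frames/s.  Scatterers are placed on a synthesis grid of
6 μm (one-tenth native, comparable to the bubble diameter), convolved with
the PSF sampled on that grid, and bicubically downsampled to native
resolution.  Localizer outputs live on a λ/14 grid (20 μm, three times
native).

Assumptions: the PSF is constant within an interrogation window; bubble
peak intensity (drawn uniformly in [0.6, 1]) is constant during a bubble's
transit; intensities clip to [0, 1] after noise addition.

**PSF family.**  Experimentally estimated kernels depend on the scanner and
are not distributed; the package uses rotated anisotropic Gaussians,
optionally with an asymmetric low-level tail toward depth
(`gaussian_with_tails`), parameterized by their FWHM axes.  The five-kernel
evaluation ladder spans FWHM 263–561 μm with aspect ratios 1.10–1.91,
bracketing the perpendicular FWHM lengths (263, 500, 561 μm) and the
AR-1.81 kernel characteristic of clinical traces.  Training kernels are
augmented by rotations in [−20°, +20°] and resize factors in [0.8, 2].

**Noise.**  Per-pixel exponential speckles blurred by a Gaussian of
σ = 1 native pixel and rescaled so the field maximum equals the prescribed
peak level (0.10/0.15/0.20/0.25 in training, 0.15 most frequent; 0–0.24 in
evaluation).  The exponential law reproduces the monotonically decaying
intensity histogram of sampled CEUS backgrounds; it is a parametric
stand-in for empirical noise PDFs, which are scanner-specific.

**Motion scenarios.**  Micro-vessel scenes translate bubbles at 5 mm/s
along two parallel lines 18–360 μm apart, with independent Poisson arrivals
per line (default one arrival per 40 frames — the real arrival histories
are scanner recordings and not available).  Macro-vessel scenes propagate
bubbles through a straight tube of radius R ∈ [120, 720] μm with the
parabolic profile `U_ref(r) = U_max (1 − (r/R)²)`, `U_max` = 5 cm/s; each
bubble keeps its radial coordinate, mean along-axis spacing is 330 μm, and
a bubble leaving the window re-enters upstream with a fresh intensity,
which keeps the radial occupancy uniform.

**Reference maps.**  Training targets mark the superres pixel containing
each true center (half-open floor convention) with 1, blurred by a 5 × 5
Gaussian whose central weight is 1 (σ = 1 superres pixel — the width is a
package choice) so every isolated blob peaks at exactly 1.

What the generator does *not* emulate: tissue motion, depth-dependent
attenuation, PSFs varying within a window, bubble disruption/ensemble
decay, and scanner post-processing nonlinearity.  Results on this benchmark
bound what the algorithms can do when their model assumptions hold; they do
not certify performance on data violating them.

## Blind deconvolution

Within a window the estimate minimizes
`‖x⊗k − y‖₂² + γ‖k‖₂² + α₁‖x‖₀ + α₂‖∇x‖₀`
(γ = 2, α₁ = α₂ = 4·10⁻³).  The scatter-map sub-problem uses
half-quadratic splitting: auxiliary variables for `x` and `∇x` are
hard-thresholded and the remaining quadratic is solved exactly in the
Fourier domain, with penalties doubling over 10 levels (the level count
sets the solver's pair-separation limit; 10 levels place it at ~0.9–1.0
FWHM, the classical blind-deconvolution limit).  The kernel sub-problem is
a ridge-regularized Wiener solve, exact in closed form.  Alternating steps
are safeguarded — a step is accepted only if the objective does not
increase — so the cost history is non-increasing by construction.  Frames
are edge-padded by the kernel half-width before the periodic solves.

Centers are extracted from the deconvolved map after bicubic interpolation
to λ/14.  The detection threshold is 1.5× the histogram mode of the
temporally averaged frame intensity; because that statistic lives on the
image-brightness scale while the deconvolved map concentrates energy, the
map is first rescaled to the frame's peak brightness (the "enhanced image"
convention).  Super-threshold blobs holding several distinct maxima
(minimum peak distance 5 superres pixels, peak floor 20% of the map maximum
to reject the ~2% solver ringing) are split by watershed before
intensity-weighted centroids are taken — two bubbles separated by about one
FWHM deconvolve to touching blobs with two peaks, and without splitting the
separability reported for blind deconvolution is unreachable.

## Supervised localizer (SupBD-net)

A residual super-resolution network maps the 80 × 80 window to the
240 × 240 center map: two ConvBlocks (conv → instance norm → leaky ReLU,
slope 0.2), four ResBlocks, a global skip from the second ConvBlock, a
stride-3 transposed convolution, and a final 9 × 9 convolution with a
sigmoid.  First/last kernels are 9 × 9, inner kernels 3 × 3, 64 feature
channels by default.  Instance normalization (not batch norm) removes
per-frame intensity/noise statistics so the network learns
instance-invariant trace-to-center structure.  The loss is pixelwise MSE
against the blurred reference maps.  Training: Adam, minibatch 16, lr 10⁻³
decayed ×0.1 every 5 epochs, early stop after 5 non-improving validation
epochs, best-validated parameters restored, 70/30 split.

The network stack (convolutions, instance norm, transposed convolution,
Adam) is implemented in numpy with explicit backward passes, verified
against central-difference gradients.  The transposed convolution uses
kernel = stride = 3 (non-overlapping learned 3 × 3 upsampling blocks).

*Scaled-down caveat.*  The reference configuration trains on 250,000 pairs
for ~10⁵ optimizer steps.  The configurations exercised in this
repository's tests train thousands of pairs for minutes of CPU; they
demonstrate the machinery (loss descent, early stopping, checkpointing,
inference) and reach qualitatively correct center maps, but their
localization accuracy remains far from the full-scale figure — see the
test-scale notes below.  For scaled runs the lr-decay interval should grow
with the inverse dataset size (epochs are short); the training API exposes
it.

## Self-supervised adaptation (SelfBD-net)

For unknown trace morphologies a k-net (same backbone, three ResBlocks,
7 × 7 kernels, no upscaling or squashing) deforms a fixed Gaussian disk
(σ = 5 native pixels, unit peak) into the local kernel.  The losses use
only raw frames:

* `L_y`: L2 differences of intensity, central-difference gradient, and all
  four second-difference Hessian terms between the reconstruction
  (`x̃ ⊗ upsample(k̃)` downsampled to native) and the frame, weighted
  1/5/25 — the gradient channel has the highest SNR under speckle noise,
  and the Hessian encodes trace shape;
* `R_x = 4·10⁻³ (‖tanh 5x̃‖₁ + ‖tanh 5∇x̃‖₁)` (forward differences), a
  differentiable surrogate of the L0 counting norms;
* `R_k = 2‖k̃‖₂²`.

Step 1 freezes the x-net: eight randomly selected frames (fixed for the
whole adaptation) are pushed through it and sparsified — per 8-connected
super-0.5 cluster only the brightest pixel survives, ties resolved in
row-major order — and the k-net trains on `L_y + R_k` until successive
kernel estimates change by an RMS below 10⁻⁶.  Because a randomly
initialized network does not emit a disk, the k-net is first pre-fitted to
reproduce the disk itself (until 5% relative RMS), which makes "deforming
the disk" literal and stabilizes the subsequent optimization; the
best-loss kernel iterate is returned.  Step 2 freezes the k-net and updates
only the x-net layers after the global residual addition, minibatches of 8,
validated every 5 iterations on 8 held-out frames, lr 10⁻⁴ decayed ×0.1 on
stalls at most three times, best-validated parameters kept.

The bicubic up/down-sampling inside the loss is implemented as explicit
separable linear operators (Keys kernel, antialiased when decimating) so
their adjoints — needed for the hand-written gradients — are exact; the
finite-difference stencils wrap periodically for the same reason.  The
normalization of k̃ to unit peak before the forward model treats the peak
value as a constant in the gradient.

## Localization and separability metrics

`E_c`: every detection contributes its distance to the nearest true center,
and every true center left unmatched contributes its distance to the
nearest detection — so a falsely detected pair counts both members.  `η`:
percentage of detections not matched one-to-one (Hungarian assignment)
within a gate of half the local minor FWHM; the denominator is the
detection count.  `D*`: center distance normalized by the PSF FWHM along
the connecting line (elliptical chord).  `Q`: Pearson correlation of
centroid-aligned kernel images.  SNR channels compare intensity, gradient
magnitude, and the two Hessian eigenvalue magnitudes between clean and
noisy frames; identical inputs are flagged infinite.

## Tracking

Constant-velocity Kalman filtering with globally optimal (Hungarian) gated
assignment; unmatched detections open tracks, tracks coast up to 2 frames
(gate 150 μm by default; both config-exposed, as the reference tracker's
internals are unpublished).  At 5 cm/s and 48 fps the per-frame
displacement (~1 mm) exceeds the 330 μm bubble spacing, and pure
nearest-distance assignment aliases onto neighboring bubbles; the tracker
therefore accepts an optional flow predictor used only to initialize new
tracks' velocity states.  Macro-vessel benchmarks pass the prescribed
parabola; on real data an ensemble-correlation estimate would play this
role.  Reported velocities always come from the detected positions.

**Overlap correction.**  When two traces overlap, the localizer returns a
single center which one track claims while the other coasts or dies,
biasing near-wall velocities high.  The correction finds detections claimed
by one track while a second track expected a detection within its gate,
removes the shared sample, and re-fills it for every re-acquired track by
piecewise-cubic interpolation of each coordinate against time ("piecewise
cubic in time" is the 1D trajectory analog of bicubic image interpolation;
for locally linear motion the fill is exact).  Tracks that never re-acquire
are truncated before the event.

## Vessel metrology

Trajectory heatmaps count distinct track traversals per superres pixel.
Cross-line profiles are fitted with sums of Gaussians (one component per
local maximum of the σ = 1 px smoothed profile); `E_l` is the distance of a
fitted peak from the true line, `ε_l = 2σ` of the component.  Area
fractions `AF` come from component areas (normalized to 100%); the index of
detection `ID` is the linewise mean over linewise standard deviation at the
fitted position, normalized to 100 over lines — continuous lines score
high, dim or intermittent ghosts low.  The shipped ghost rule
`0.10 AF + 0.038 ID − 4.64 < 0 → negligible` takes AF and ID on those 0–100
scales (the printed constants are only dimensionally consistent with
percent-like magnitudes); `fit_ghost_boundary` refits a maximum-margin line
for users on other scales.  Separation outcomes are graded five ways:
unseparated (single peak, or trough above 95% of the primary), overlapped,
non-negligible/negligible ghost (three peaks, routed by the rule), and
fully separated (trough below 5% of the primary — the floor is a package
choice).

Velocity profiles bin per-sample speeds (central differences in time) by
radial coordinate in 20 μm bins.  `E_u` follows the binned-mean definition
`|(U_m − U_ref)/U_ref|`, with the reference evaluated at the samples' own
radii so bin discretization does not register as error; random localization
scatter largely cancels in the mean, so its magnitude is reported
separately (`E_u_scatter`), and it is this scatter that the misplacement
proxy `|dU_ref/dr · E_c / U_ref|` models.  Radius estimates fit
`a(1 − (r/R_m)²)` by least squares (linear in `(1, r²)`) and report the
zero crossing; empty edge bins are trimmed so the parabola is fitted to the
occupied cross-section.  A Gaussian fit to the track-count profile is
provided for comparison only — its σ is not a consistent multiple of the
radius, which is why the parabolic zero crossing is the default.  Power-law
relations (e.g. `E_l/D_l` vs `L_p/D_l`) are fitted as lines in log–log
space.

## Numerical and test-scale choices

* All randomness flows through `numpy.random.default_rng` seeded per run;
  every generator is bit-reproducible under a fixed seed.
* Half-open pixel convention everywhere: pixel `i` covers
  `[iΔ, (i+1)Δ)`, center `(i+0.5)Δ`; positions are microns from the
  top-left corner, axis 0 = depth.
* Ties in sparsification resolve to the first maximum in row-major order.
* The acceptance benchmarks run blind deconvolution on ~660 two-bubble
  trials (≥500 pooled at D* ≥ 1.05) and ~220 multi-bubble frames; the test
  suite uses further-reduced trial counts per check (set in each test) so
  the whole suite completes in minutes.  Network training inside the test
  suite uses small windows (12–32 native pixels), 6–16 feature channels,
  and hundreds to thousands of pairs — sizes chosen to exercise the full
  code path at desk scale, not to reproduce full-scale accuracy.

## Known limitations

* The supervised localizer's headline accuracy requires full-scale
  training; desk-scale runs underfit (see the scaled-down caveat above).
* The k-net recovers kernel orientation and elongation reliably at small
  scale, but correlations above ~0.98 require the full-window, full-budget
  configuration.
* Straight vessels only; curved or branching geometry, in-vivo motion, and
  scanner-specific preprocessing are out of scope.
* The blind-deconvolution weights are fixed at the values above; they are
  not re-tuned per dataset.
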