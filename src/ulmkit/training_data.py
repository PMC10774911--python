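"""Synthetic training pairs for the supervised localizer.

Each pair is a native-resolution noisy frame and its blurred center map at
three times the resolution.  Augmentation covers the variability of real
CEUS data: bubble concentrations uniform in [0.1, 1.0] mm^-2, peak
intensities in [0.6, 1], PSF rotations in [-20, +20] degrees, PSF resize
factors in [0.8, 2], and peak noise levels drawn from {0.10, 0.15, 0.20,
0.25} with 0.15 the most frequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec
from .noise import NoiseSpec
from .psf import PSFModel, make_psf
from .scene import make_reference_map, random_bubbles, synthesize_frame

NOISE_PEAKS = (0.10, 0.15, 0.20, 0.25)
NOISE_PEAK_PROBS = (0.2, 0.4, 0.2, 0.2)


@dataclass(frozen=True)
class TrainingRanges:
    """Sampling ranges for the training-set generator."""

    concentration_mm2: tuple[float, float] = (0.1, 1.0)
    intensity: tuple[float, float] = (0.6, 1.0)
    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    resize: tuple[float, float] = (0.8, 2.0)
    noise_peaks: tuple[float, ...] = NOISE_PEAKS
    noise_probs: tuple[float, ...] = NOISE_PEAK_PROBS


@dataclass
class TrainingSet:
    """Arrays of (input, reference) pairs plus the sampled parameters."""

    inputs: np.ndarray  # (n, W, W) float32
    references: np.ndarray  # (n, 3W, 3W) float32
    params: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.inputs)


def default_psf_pool() -> list[PSFModel]:
    """Training PSF pool: moderate Gaussian kernels before augmentation.

    Resize factors of 0.8-2 applied to these base kernels span FWHMs of
    about 200-700 um, bracketing the trace sizes of the evaluation ladder.
    """
    return [
        make_psf(260.0, 240.0, 0.0),
        make_psf(300.0, 240.0, 0.0),
        make_psf(340.0, 250.0, 0.0, family="gaussian_with_tails"),
    ]


def build_training_set(
    n_pairs: int,
    ranges: TrainingRanges | None = None,
    seed: int | None = None,
    psf_pool: list[PSFModel] | None = None,
    grid: GridSpec | None = None,
) -> TrainingSet:
    """Generate ``n_pairs`` (80 x 80 input, 240 x 240 reference) pairs.

    Deterministic under a fixed seed.  ``grid`` may shrink the window for
    fully convolutional training on smaller crops.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ranges = ranges or TrainingRanges()
    grid = grid or GridSpec()
    psf_pool = psf_pool if psf_pool is not None else default_psf_pool()
    if not psf_pool:
        raise ValueError("empty PSF pool")
    rng = np.random.default_rng(seed)

    inputs = np.empty((n_pairs, grid.window, grid.window), dtype=np.float32)
    refs = np.empty(
        (n_pairs, grid.window * grid.superres_factor, grid.window * grid.superres_factor),
        dtype=np.float32,
    )
    params: list[dict] = []
    for i in range(n_pairs):
        conc = rng.uniform(*ranges.concentration_mm2)
        base = psf_pool[rng.integers(len(psf_pool))]
        rot = rng.uniform(*ranges.rotation_deg)
        resize = rng.uniform(*ranges.resize)
        # keep the resized kernel resolvable on the native grid
        min_fwhm = 2.0 * grid.native_pixel_um
        resize = max(resize, (min_fwhm + 1e-6) / base.fwhm_minor_um)
        psf = make_psf(
            base.fwhm_major_um * resize,
            base.fwhm_minor_um * resize,
            base.orientation_deg + rot,
            family=base.family,
            grid=grid,
        )
        peak = float(rng.choice(ranges.noise_peaks, p=ranges.noise_probs))
        bubbles = random_bubbles(conc, grid, rng, intensity_range=ranges.intensity)
        frame, truth = synthesize_frame(bubbles, psf, NoiseSpec(peak_level=peak), grid, rng)
        inputs[i] = frame
        refs[i] = make_reference_map(truth, grid)
        params.append(
            {
                "concentration_mm2": conc,
                "rotation_deg": rot,
                "resize": resize,
                "noise_peak": peak,
                "n_bubbles": int(len(truth)),
            }
        )
    return TrainingSet(inputs=inputs, references=refs, params=params)
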