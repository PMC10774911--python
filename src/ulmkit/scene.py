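"""Forward model: render bubble scenes into synthetic CEUS frames.

A frame is ``y = k (*) x + n``: point scatterers ``x`` placed on the
synthesis grid (one-tenth of the native pixel, comparable to the bubble
diameter), convolved with the local PSF ``k`` upsampled to the same grid,
bicubically downsampled to native resolution, with speckle noise ``n``
added and the result clipped to [0, 1].

Bubble lists are ``(n, 3)`` float arrays with columns
``depth_um, lateral_um, intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .grids import GridSpec
from .noise import NoiseSpec, make_noise
from .psf import PSFModel

BUBBLE_COLUMNS = ("depth_um", "lateral_um", "intensity")


def as_bubbles(arr) -> np.ndarray:
    """Coerce to an (n, 3) float array of (depth_um, lateral_um, intensity)."""
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        return np.zeros((0, 3))
    arr = np.atleast_2d(arr)
    if arr.shape[1] == 2:  # default to unit intensity
        arr = np.hstack([arr, np.ones((len(arr), 1))])
    if arr.shape[1] != 3:
        raise ValueError("bubbles must have columns (depth_um, lateral_um, intensity)")
    return arr


def random_bubbles(
    concentration_mm2: float,
    grid: GridSpec,
    rng: np.random.Generator,
    intensity_range: tuple[float, float] = (0.6, 1.0),
    margin_um: float = 0.0,
) -> np.ndarray:
    """Poisson-distributed bubbles over the window at a given concentration."""
    n = rng.poisson(concentration_mm2 * grid.window_area_mm2)
    lo, hi = margin_um, grid.window_um - margin_um
    pos = rng.uniform(lo, hi, size=(n, 2))
    inten = rng.uniform(*intensity_range, size=(n, 1))
    return np.hstack([pos, inten])


def scatter_map(bubbles: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Point-scatterer map ``x`` on the synthesis grid (delta per bubble)."""
    bubbles = as_bubbles(bubbles)
    x = np.zeros(grid.synthesis_shape)
    delta = grid.synthesis_pixel_um
    for d, l, inten in bubbles:
        i, j = int(d // delta), int(l // delta)
        if not (0 <= i < x.shape[0] and 0 <= j < x.shape[1]):
            raise ValueError(f"bubble at ({d}, {l}) um lies outside the window")
        x[i, j] += inten
    return x


def _add_kernel(canvas: np.ndarray, kernel: np.ndarray, ci: int, cj: int, amp: float) -> None:
    """Accumulate ``amp * kernel`` centered at (ci, cj), cropping at edges."""
    kh, kw = kernel.shape
    hi, hj = kh // 2, kw // 2
    i0, i1 = ci - hi, ci - hi + kh
    j0, j1 = cj - hj, cj - hj + kw
    si0, sj0 = max(i0, 0), max(j0, 0)
    si1, sj1 = min(i1, canvas.shape[0]), min(j1, canvas.shape[1])
    if si0 >= si1 or sj0 >= sj1:
        return
    canvas[si0:si1, sj0:sj1] += amp * kernel[si0 - i0 : si1 - i0, sj0 - j0 : sj1 - j0]


def synthesize_frame(
    bubbles,
    psf: PSFModel,
    noise: NoiseSpec | None,
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one native-resolution frame; returns ``(frame, truth)``.

    ``truth`` is the validated bubble array (exact sub-pixel positions).
    An empty bubble list yields a pure-noise frame.
    """
    grid = grid or GridSpec()
    bubbles = as_bubbles(bubbles)
    delta = grid.synthesis_pixel_um
    hi = np.zeros(grid.synthesis_shape)
    for d, l, inten in bubbles:
        i, j = int(d // delta), int(l // delta)
        if not (0 <= i < hi.shape[0] and 0 <= j < hi.shape[1]):
            raise ValueError(f"bubble at ({d}, {l}) um lies outside the window")
        _add_kernel(hi, psf.kernel_hi, i, j, inten)
    frame = resize(
        hi, (grid.window, grid.window), order=3, anti_aliasing=False,
        preserve_range=True, clip=False,
    )
    if noise is not None and noise.peak_level > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        frame = frame + make_noise(noise, frame.shape, rng)
    return np.clip(frame, 0.0, 1.0), bubbles


def truth_map(bubbles, grid: GridSpec | None = None) -> np.ndarray:
    """Center map at synthesis resolution: bubble intensity at its pixel."""
    grid = grid or GridSpec()
    return scatter_map(bubbles, grid)


# 5x5 Gaussian used to blur reference maps; normalized so the central
# weight is 1, making every isolated blob peak at exactly 1.
_REF_SIGMA = 1.0
_w = np.exp(-0.5 * (np.arange(-2, 3) / _REF_SIGMA) ** 2)
REFERENCE_BLUR = np.outer(_w, _w)
REFERENCE_BLUR /= REFERENCE_BLUR.max()


def make_reference_map(bubbles, grid: GridSpec | None = None) -> np.ndarray:
    """Blurred center map at super resolution (240 x 240 for an 80 window).

    Pixels containing true centers (half-open floor convention) are set to
    1, the map is blurred by a 5 x 5 Gaussian whose central weight is 1, and
    clipped so every blob peaks at 1.
    """
    grid = grid or GridSpec()
    bubbles = as_bubbles(bubbles)
    ref = np.zeros(grid.superres_shape)
    delta = grid.superres_pixel_um
    for d, l, _ in bubbles:
        i, j = int(d // delta), int(l // delta)
        if not (0 <= i < ref.shape[0] and 0 <= j < ref.shape[1]):
            raise ValueError(f"center at ({d}, {l}) um lies outside the window")
        ref[i, j] = 1.0
    ref = ndimage.convolve(ref, REFERENCE_BLUR, mode="constant")
    return np.clip(ref, 0.0, 1.0)


@dataclass
class SceneSequence:
    """Time-resolved ground truth plus lazily rendered frames.

    ``bubbles_per_frame[t]`` is the bubble array at frame ``t``.  Frames are
    rendered on demand so long simulations stay cheap to hold in memory.
    """

    bubbles_per_frame: list[np.ndarray]
    psf: PSFModel
    noise: NoiseSpec | None
    grid: GridSpec
    seed: int | None = None
    _frames: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.bubbles_per_frame)

    def render_frame(self, t: int, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            base = 0 if self.seed is None else self.seed
            rng = np.random.default_rng((base, t))
        frame, _ = synthesize_frame(
            self.bubbles_per_frame[t], self.psf, self.noise, self.grid, rng
        )
        return frame

    @property
    def frames(self) -> np.ndarray:
        """All frames, rendered once and cached (float32)."""
        if self._frames is None:
            self._frames = np.stack(
                [self.render_frame(t) for t in range(len(self))]
            ).astype(np.float32)
        return self._frames

    def truth_map(self, t: int) -> np.ndarray:
        return truth_map(self.bubbles_per_frame[t], self.grid)

    def reference_map(self, t: int) -> np.ndarray:
        return make_reference_map(self.bubbles_per_frame[t], self.grid)

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth centers as a tidy frame/depth/lateral/intensity table."""
        rows = []
        for t, bubbles in enumerate(self.bubbles_per_frame):
            for d, l, inten in bubbles:
                rows.append((t, d, l, inten))
        return pd.DataFrame(rows, columns=["frame", *BUBBLE_COLUMNS])
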