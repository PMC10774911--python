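import itertools

import numpy as np
import pytest

from ulmkit.blind_deconv import (
    BDConfig,
    bd_extract_centers,
    bd_objective,
    bd_threshold,
    deconvolve_frame,
    estimate_psf_window,
    _pad_for_kernel,
    _psf2otf,
)
from ulmkit.grids import GridSpec
from ulmkit.localization import psf_quality
from ulmkit.noise import NoiseSpec
from ulmkit.psf import make_psf
from ulmkit.scene import random_bubbles, synthesize_frame


@pytest.fixture(scope="module")
def cfg():
    return BDConfig()


class TestDeconvolveFrame:
    def test_zero_frame_gives_zero_map(self, psf, small_grid, cfg):
        x = deconvolve_frame(np.zeros((40, 40)), psf, cfg)
        assert not x.any()

    def test_delta_recovers_compact_cluster(self, psf, small_grid, cfg):
        """y = k (*) delta inverts to a cluster at the delta's pixel."""
        pos = 1215.0  # native pixel 20 center
        frame, _ = synthesize_frame([[pos, pos, 1.0]], psf, None, small_grid)
        x = deconvolve_frame(frame, psf, cfg)
        assert x.max() > 0
        i, j = np.unravel_index(x.argmax(), x.shape)
        assert abs(i - 20) <= 1 and abs(j - 20) <= 1
        # sparse: a single compact cluster, not a diffuse cloud
        assert (x > 0).mean() < 0.05

    def test_sparsity_at_typical_concentration(self, psf, grid, cfg, rng):
        bubbles = random_bubbles(0.5, grid, rng)
        frame, _ = synthesize_frame(bubbles, psf, None, grid, rng)
        x = deconvolve_frame(frame, psf, cfg)
        assert (x == 0).mean() >= 0.95

    def test_pair_beyond_one_fwhm_splits(self, psf, grid, cfg):
        """Two bubbles > 1 FWHM apart yield two distinct clusters."""
        c = 2400.0
        sep = 1.3 * psf.fwhm_major_um
        frame, _ = synthesize_frame(
            [[c, c - sep / 2, 1.0], [c, c + sep / 2, 1.0]], psf, None, grid
        )
        x = deconvolve_frame(frame, psf, cfg)
        ds = bd_extract_centers(x, grid, threshold=0.1 * x.max(), frame_image=frame)
        assert len(ds) == 2

    def test_kernel_larger_than_frame_rejected(self, psf, cfg):
        with pytest.raises(ValueError, match="larger"):
            deconvolve_frame(np.zeros((8, 8)), psf, cfg)

    def test_shift_equivariance(self, psf, grid, cfg):
        """Translating the frame by one native pixel translates the
        extracted centers by 60 um."""
        b = [[2400.0, 2400.0, 1.0]]
        f0, _ = synthesize_frame(b, psf, None, grid)
        f1 = np.roll(f0, 1, axis=1)
        d0 = bd_extract_centers(deconvolve_frame(f0, psf, cfg), grid, threshold=0.01, frame_image=f0)
        d1 = bd_extract_centers(deconvolve_frame(f1, psf, cfg), grid, threshold=0.01, frame_image=f1)
        shift = d1.positions_um[0] - d0.positions_um[0]
        assert shift[0] == pytest.approx(0.0, abs=20.0)
        assert shift[1] == pytest.approx(60.0, abs=20.0)


class TestToyOracle:
    def test_support_matches_exhaustive_search(self, cfg):
        """On a 16x16 toy with <= 2 scatterers the solver's support matches
        brute-force search over scatterer positions (data term only)."""
        grid16 = GridSpec(window=16)
        kernel = make_psf(200, 150, 0, grid=grid16)
        truth_px = [(5, 4), (11, 10)]
        frame = np.zeros((16, 16))
        ypad, (ph, pw) = _pad_for_kernel(frame, kernel.kernel_native.shape)
        K = _psf2otf(kernel.kernel_native, ypad.shape)

        def render(pixels):
            x = np.zeros_like(ypad)
            for i, j in pixels:
                x[ph + i, pw + j] = 1.0
            return np.fft.irfft2(K * np.fft.rfft2(x), s=ypad.shape)

        y = render(truth_px)
        frame = y[ph : ph + 16, pw : pw + 16]

        # oracle: best pair of scatterer pixels by residual, coarse grid
        candidates = list(itertools.product(range(1, 16, 2), range(1, 16, 2)))
        best, best_res = None, np.inf
        for pair in itertools.combinations(candidates, 2):
            res = np.sum((render(pair) - y) ** 2)
            if res < best_res:
                best, best_res = pair, res

        x = deconvolve_frame(frame, kernel, cfg)
        ds = bd_extract_centers(x, grid16, threshold=0.2 * x.max(), frame_image=frame)
        assert len(ds) == 2
        solver_px = sorted(tuple(np.round(p / 60 - 0.5).astype(int)) for p in ds.positions_um)
        # the oracle grid is coarse (step 2): agree within one candidate step
        for s, o in zip(solver_px, sorted(best)):
            assert abs(s[0] - o[0]) <= 2 and abs(s[1] - o[1]) <= 2


class TestEstimatePsf:
    def test_objective_monotone_nonincreasing(self, psf, grid, rng):
        frames = []
        for _ in range(4):
            b = random_bubbles(0.3, grid, rng)
            f, _ = synthesize_frame(b, psf, None, grid, rng)
            frames.append(f)
        _, history = estimate_psf_window(np.array(frames), BDConfig(max_outer=5), grid)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_known_gaussian_psf_recovered(self, grid, rng):
        """Frames synthesized with a known kernel invert to a correlated
        estimate (Q >= 0.95, noise-free)."""
        true_psf = make_psf(400, 276, 0)
        frames = []
        for _ in range(6):
            b = random_bubbles(0.3, grid, rng)
            f, _ = synthesize_frame(b, true_psf, None, grid, rng)
            frames.append(f)
        est, _ = estimate_psf_window(np.array(frames), BDConfig(max_outer=4), grid)
        assert psf_quality(true_psf, est) >= 0.95

    def test_mirror_symmetric_input_gives_symmetric_estimate(self, grid, rng):
        true_psf = make_psf(400, 300, 0)  # symmetric about both axes
        frames = []
        for _ in range(6):
            b = random_bubbles(0.3, grid, rng)
            f, _ = synthesize_frame(b, true_psf, None, grid, rng)
            frames.append(f)
        est, _ = estimate_psf_window(np.array(frames), BDConfig(max_outer=4), grid)
        k = est.kernel_native
        asym = np.abs(k - k[:, ::-1]).max()
        assert asym < 0.25  # symmetric within solver tolerance

    def test_all_zero_frames_rejected(self, grid):
        with pytest.raises(ValueError, match="signal"):
            estimate_psf_window(np.zeros((3, 80, 80)), BDConfig(), grid)


class TestExtractCenters:
    def test_empty_map_gives_empty_set(self, grid):
        ds = bd_extract_centers(np.zeros((80, 80)), grid, threshold=0.1)
        assert len(ds) == 0

    def test_blob_below_threshold_removed(self, grid):
        x = np.zeros((80, 80))
        x[40, 40] = 0.05
        ds = bd_extract_centers(x, grid, threshold=0.2)
        assert len(ds) == 0

    def test_single_trace_centroid_accuracy(self, psf, grid, cfg, rng):
        """Noise-free isolated bubbles localize within 0.06 lambda."""
        errors = []
        for _ in range(5):
            pos = rng.uniform(1500, 3000, size=2)
            frame, _ = synthesize_frame([[pos[0], pos[1], 1.0]], psf, None, grid)
            x = deconvolve_frame(frame, psf, cfg)
            ds = bd_extract_centers(x, grid, threshold=0.01, frame_image=frame)
            errors.append(np.linalg.norm(ds.positions_um - pos, axis=1).min())
        assert np.mean(errors) <= 0.06 * grid.wavelength_um

    def test_threshold_from_frame_histogram(self, rng):
        frames = rng.exponential(0.04, size=(10, 64, 64))
        thr = bd_threshold(frames)
        assert thr > 0
        assert bd_threshold(np.zeros((3, 32, 32))) == 0.0


def test_config_validation():
    with pytest.raises(ValueError):
        BDConfig(gamma=-1.0)
    with pytest.raises(ValueError):
        BDConfig(overlap=0.7)


def test_objective_counts_l0_terms(cfg):
    x = np.zeros((32, 32))
    x[10, 10] = 1.0
    k = np.zeros((5, 5))
    k[2, 2] = 1.0
    y = x.copy()
    # perfect reconstruction: only regularizers contribute
    obj = bd_objective(x, k, y, cfg)
    expected = cfg.gamma * 1.0 + cfg.alpha1 * 1 + cfg.alpha2 * 3  # 1 px, 3 grad edges
    assert obj == pytest.approx(expected, abs=1e-9)


def test_psf_field_tiles_windows(grid, rng):
    """A frame stack wider than one window yields one PSF per tile."""
    from ulmkit.blind_deconv import estimate_psf_field

    psf = make_psf(300, 250, 0)
    frames = []
    for _ in range(3):
        b = random_bubbles(0.4, grid, rng)
        f, _ = synthesize_frame(b, psf, None, grid, rng)
        frames.append(f)
    field = estimate_psf_field(np.array(frames), BDConfig(max_outer=2), grid)
    assert (0, 0) in field.windows
    est = field.nearest(40, 40)
    assert est.kernel_native.max() == 1.0
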