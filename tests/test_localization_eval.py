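import numpy as np
import pytest

from ulmkit.detections import DetectionSet
from ulmkit.localization import (
    PairTrial,
    is_separated,
    localization_error,
    normalized_separation,
    pool_reports,
    psf_quality,
    separation_stats,
    snr_channels,
)
from ulmkit.noise import NoiseSpec, make_noise
from ulmkit.psf import make_psf
from ulmkit.scene import synthesize_frame


def _ds(points):
    points = np.asarray(points, dtype=float)
    return DetectionSet(points, np.ones(len(points)))


class TestLocalizationError:
    def test_perfect_detections_zero_error(self):
        truth = [[100.0, 100.0], [500.0, 700.0]]
        rep = localization_error(truth, _ds(truth), gate_um=100)
        assert rep.E_c_um == 0.0
        assert rep.eta_pct == 0.0

    def test_missed_bubble_counts_distance_to_nearest(self):
        """truth {(0,0),(100,0)}, one detection at (0,0): E_c = 50."""
        rep = localization_error([[0.0, 0.0], [100.0, 0.0]], _ds([[0.0, 0.0]]), gate_um=50)
        assert rep.E_c_um == pytest.approx(50.0)

    def test_false_pair_counts_both_distances(self):
        """truth {(0,0)}, detections at (-10,0) and (10,0): E_c = 10,
        eta = 50% (only one detection can match one-to-one)."""
        rep = localization_error([[0.0, 0.0]], _ds([[-10.0, 0.0], [10.0, 0.0]]), gate_um=50)
        assert rep.E_c_um == pytest.approx(10.0)
        assert rep.eta_pct == pytest.approx(50.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            localization_error(np.zeros((0, 2)), _ds([[0.0, 0.0]]), gate_um=50)

    def test_translation_invariance(self, rng):
        truth = rng.uniform(0, 1000, (5, 2))
        dets = truth + rng.normal(0, 10, (5, 2))
        r1 = localization_error(truth, _ds(dets), gate_um=100)
        r2 = localization_error(truth + 500.0, _ds(dets + 500.0), gate_um=100)
        assert r1.E_c_um == pytest.approx(r2.E_c_um)

    def test_dilation_scales_error_linearly(self, rng):
        truth = rng.uniform(100, 900, (5, 2))
        dets = truth + rng.normal(0, 10, (5, 2))
        r1 = localization_error(truth, _ds(dets), gate_um=1000)
        r2 = localization_error(truth * 2, _ds(dets * 2), gate_um=2000)
        assert r2.E_c_um == pytest.approx(2 * r1.E_c_um)

    def test_pooling_weights_by_contributions(self):
        r1 = localization_error([[0.0, 0.0]], _ds([[3.0, 0.0]]), gate_um=50)
        r2 = localization_error([[0.0, 0.0]], _ds([[9.0, 0.0]]), gate_um=50)
        pooled = pool_reports([r1, r2])
        assert pooled.E_c_um == pytest.approx(6.0)


class TestNormalizedSeparation:
    def test_one_fwhm_separation_is_unity(self, round_psf):
        assert normalized_separation([0, 0], [0, 400], round_psf) == pytest.approx(1.0)

    def test_half_fwhm_is_half(self, round_psf):
        assert normalized_separation([0, 0], [0, 200], round_psf) == pytest.approx(0.5)

    def test_anisotropy_changes_d_star_with_direction(self, psf):
        d_major = normalized_separation([0, 0], [0, 200], psf)  # along lateral
        d_minor = normalized_separation([0, 0], [200, 0], psf)  # along depth
        assert d_minor > d_major

    def test_coincident_centers_rejected(self, psf):
        with pytest.raises(ValueError):
            normalized_separation([1.0, 2.0], [1.0, 2.0], psf)


class TestSeparationStats:
    def test_all_separated_gives_zero_everywhere(self):
        trials = [PairTrial(D_star=d, separated=True) for d in np.linspace(0.5, 2, 50)]
        table = separation_stats(trials, np.array([0.5, 1.0, 1.5, 2.0]))
        filled = table[~table["empty"]]
        assert (filled["unseparated_pct"] == 0).all()

    def test_empty_bin_flagged(self):
        trials = [PairTrial(D_star=0.6, separated=False)]
        table = separation_stats(trials, np.array([0.5, 1.0, 1.5]))
        assert bool(table.iloc[1]["empty"])
        assert not bool(table.iloc[0]["empty"])

    def test_is_separated_requires_unique_assignment(self):
        truth = np.array([[0.0, 0.0], [0.0, 300.0]])
        both_near_first = _ds([[5.0, 0.0], [12.0, 0.0]])
        assert not is_separated(truth, both_near_first, gate_um=100)
        one_each = _ds([[5.0, 0.0], [0.0, 295.0]])
        assert is_separated(truth, one_each, gate_um=100)


class TestPsfQuality:
    def test_identical_kernels_correlate_perfectly(self, psf):
        assert psf_quality(psf, psf) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, psf, round_psf):
        assert psf_quality(psf, round_psf) == pytest.approx(psf_quality(round_psf, psf), abs=0.02)

    def test_different_kernels_correlate_below_one(self, psf):
        other = make_psf(300, 240, 30.0)
        q = psf_quality(psf, other)
        assert -1.0 <= q < 1.0


class TestSnrChannels:
    def test_identical_images_flagged_infinite(self, rng):
        img = rng.random((32, 32))
        out = snr_channels(img, img)
        assert all(np.isinf(v) for v in out.values())

    def test_doubling_noise_halves_intensity_snr(self, rng):
        clean = rng.random((64, 64))
        noise = rng.normal(0, 0.05, clean.shape)
        s1 = snr_channels(clean, clean + noise)["intensity"]
        s2 = snr_channels(clean, clean + 2 * noise)["intensity"]
        assert s1 / s2 == pytest.approx(2.0, rel=1e-6)

    def test_gradient_snr_highest_on_speckle_frames(self, psf, small_grid, rng):
        """On CEUS-like frames with blurred speckle noise the gradient
        channel is the least corrupted."""
        bubbles = [[1200.0, 1200.0, 1.0], [700.0, 1700.0, 0.8]]
        clean, _ = synthesize_frame(bubbles, psf, None, small_grid)
        noisy = np.clip(clean + make_noise(NoiseSpec(0.16), clean.shape, rng), 0, 1)
        out = snr_channels(clean, noisy)
        assert out["gradient"] > out["intensity"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            snr_channels(np.zeros((4, 4)), np.zeros((5, 5)))


def test_merge_window_detections_deduplicates_by_weight():
    from ulmkit.detections import merge_window_detections

    a = DetectionSet(np.array([[100.0, 100.0], [500.0, 500.0]]), np.array([2.0, 1.0]))
    b = DetectionSet(np.array([[110.0, 108.0]]), np.array([0.5]))  # within 30 um
    merged = merge_window_detections([a, b], radius_um=30.0)
    assert len(merged) == 2
    assert merged.weights.max() == 2.0  # the heavier duplicate wins
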