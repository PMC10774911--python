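"""Localization accuracy and bubble-pair separability metrics.

* ``E_c`` -- mean distance between prescribed and detected bubble centers.
  For each true center the distance to the closest detection is counted;
  when one true center attracts several detections (a falsely detected
  pair), every such detection's distance contributes.
* ``eta`` -- percentage of detections not matched one-to-one to a true
  center within a gate (default half the local PSF FWHM).
* ``D*`` -- center distance normalized by the PSF FWHM along the
  connecting line; the natural variable for separability curves.
* ``Q``  -- Pearson correlation between true and estimated PSF images.
* SNR channels -- intensity, gradient magnitude, and the two Hessian
  eigenvalue magnitudes; the gradient channel is the least corrupted by
  speckle noise, which motivates gradient terms in self-supervised losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .detections import DetectionSet
from .psf import PSFModel


@dataclass
class LocalizationReport:
    """E_c (um and wavelength fractions), its spread, and eta (%)."""

    E_c_um: float
    E_c_std_um: float
    eta_pct: float
    n_truth: int
    n_detections: int
    distances_um: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    def E_c_lambda(self, wavelength_um: float = 280.0) -> float:
        return self.E_c_um / wavelength_um


def localization_error(
    truth_um: np.ndarray,
    detections: DetectionSet | np.ndarray,
    gate_um: float,
    meta: dict | None = None,
) -> LocalizationReport:
    """Score one frame's detections against ground truth.

    ``truth_um`` is (n, 2) or (n, 3) (intensity column ignored).  Error
    contributions: every detection contributes its distance to the nearest
    true center, and every true center left without an assigned detection
    contributes its distance to the nearest detection.  ``eta`` is the
    percentage of detections that cannot be matched one-to-one to a true
    center within ``gate_um``.
    """
    truth = np.asarray(truth_um, dtype=float)
    if truth.size == 0:
        raise ValueError("empty truth set")
    truth = np.atleast_2d(truth)[:, :2]
    pos = (
        detections.positions_um
        if isinstance(detections, DetectionSet)
        else np.asarray(detections, dtype=float).reshape(-1, 2)
    )
    if len(pos) == 0:
        return LocalizationReport(
            E_c_um=float("nan"),
            E_c_std_um=float("nan"),
            eta_pct=0.0,
            n_truth=len(truth),
            n_detections=0,
            meta=meta or {},
        )
    dmat = np.linalg.norm(truth[:, None, :] - pos[None, :, :], axis=2)

    nearest_truth = dmat.argmin(axis=0)
    contributions = [dmat[nearest_truth[j], j] for j in range(len(pos))]
    for i in set(range(len(truth))) - set(nearest_truth.tolist()):
        contributions.append(dmat[i].min())
    contributions = np.asarray(contributions)

    # one-to-one matching within the gate for the false-detection rate
    gated = np.where(dmat <= gate_um, dmat, 1e12)
    rows, cols = linear_sum_assignment(gated)
    matched = np.sum(gated[rows, cols] < 1e11)
    eta = 100.0 * (len(pos) - matched) / len(pos)

    return LocalizationReport(
        E_c_um=float(contributions.mean()),
        E_c_std_um=float(contributions.std()),
        eta_pct=float(eta),
        n_truth=len(truth),
        n_detections=len(pos),
        distances_um=contributions,
        meta=meta or {},
    )


def pool_reports(reports: list[LocalizationReport]) -> LocalizationReport:
    """Pool per-frame reports into one (distance-weighted) summary."""
    chunks = [r.distances_um for r in reports if len(r.distances_um)]
    dists = np.concatenate(chunks) if chunks else np.array([np.nan])
    n_det = sum(r.n_detections for r in reports)
    n_matched = sum(
        r.n_detections * (1 - r.eta_pct / 100.0) for r in reports if r.n_detections
    )
    eta = 100.0 * (n_det - n_matched) / n_det if n_det else 0.0
    return LocalizationReport(
        E_c_um=float(dists.mean()),
        E_c_std_um=float(dists.std()),
        eta_pct=float(eta),
        n_truth=sum(r.n_truth for r in reports),
        n_detections=n_det,
        distances_um=dists,
    )


def normalized_separation(c1, c2, psf: PSFModel) -> float:
    """D*: center distance over the PSF FWHM along the connecting line."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    delta = c2 - c1
    dist = np.linalg.norm(delta)
    if dist == 0:
        raise ValueError("coincident centers")
    direction_deg = np.rad2deg(np.arctan2(delta[0], delta[1]))
    return dist / psf.L_p(direction_deg)


@dataclass
class PairTrial:
    """One two-bubble trial labeled separated or not."""

    D_star: float
    separated: bool


def is_separated(
    truth_pair: np.ndarray, detections: DetectionSet, gate_um: float
) -> bool:
    """Two detections, each uniquely assignable to its own true center."""
    if len(detections) < 2:
        return False
    pos = detections.positions_um
    dmat = np.linalg.norm(
        np.asarray(truth_pair, dtype=float)[:, None, :2] - pos[None, :, :], axis=2
    )
    gated = np.where(dmat <= gate_um, dmat, 1e12)
    rows, cols = linear_sum_assignment(gated[:, : len(pos)])
    return bool(np.sum(gated[rows, cols] < 1e11) == 2)


def separation_stats(
    trials: list[PairTrial],
    bin_edges: np.ndarray,
    confidence: float = 0.95,
) -> "pd.DataFrame":
    """Unseparated percentage per D* bin with binomial confidence intervals."""
    import pandas as pd
    from statsmodels.stats.proportion import proportion_confint

    d = np.array([t.D_star for t in trials])
    sep = np.array([t.separated for t in trials])
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (d >= lo) & (d < hi)
        n = int(mask.sum())
        if n == 0:
            rows.append((0.5 * (lo + hi), n, np.nan, np.nan, np.nan, True))
            continue
        fails = int((~sep[mask]).sum())
        ci_lo, ci_hi = proportion_confint(fails, n, alpha=1 - confidence, method="beta")
        rows.append((0.5 * (lo + hi), n, 100.0 * fails / n, 100 * ci_lo, 100 * ci_hi, False))
    return pd.DataFrame(
        rows,
        columns=["D_star", "n", "unseparated_pct", "ci_low_pct", "ci_high_pct", "empty"],
    )


def psf_quality(true_psf: PSFModel, est_psf: PSFModel) -> float:
    """Pearson correlation Q between co-registered kernel intensities.

    The estimated kernel is resampled to the true kernel's grid and the two
    are aligned by intensity centroid before correlating.
    """
    a = true_psf.kernel_native
    b = est_psf.kernel_native
    scale = est_psf.native_pixel_um / true_psf.native_pixel_um
    if abs(scale - 1.0) > 1e-9:
        b = ndimage.zoom(b, scale, order=3)
        b = np.clip(b, 0.0, None)
    # align centroids by shifting b onto a's frame
    ca = np.array(ndimage.center_of_mass(a))
    cb = np.array(ndimage.center_of_mass(b))
    half = np.minimum(np.array(a.shape), np.array(b.shape)) // 2
    ia, ib = [], []
    for axis in range(2):
        sa = int(round(ca[axis]))
        sb = int(round(cb[axis]))
        h = int(
            min(half[axis], sa, sb, a.shape[axis] - 1 - sa, b.shape[axis] - 1 - sb)
        )
        ia.append(slice(sa - h, sa + h + 1))
        ib.append(slice(sb - h, sb + h + 1))
    aa = a[tuple(ia)].ravel()
    bb = b[tuple(ib)].ravel()
    if aa.std() == 0 or bb.std() == 0:
        raise ValueError("constant image: correlation undefined")
    return float(pearsonr(aa, bb)[0])


def _hessian_eigs(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel eigenvalues of the finite-difference Hessian (|e1| >= |e2|)."""
    hvv = np.gradient(np.gradient(img, axis=0), axis=0)
    hll = np.gradient(np.gradient(img, axis=1), axis=1)
    hvl = np.gradient(np.gradient(img, axis=0), axis=1)
    tr = hvv + hll
    det = hvv * hll - hvl**2
    disc = np.sqrt(np.clip((tr / 2.0) ** 2 - det, 0.0, None))
    e1 = tr / 2.0 + disc
    e2 = tr / 2.0 - disc
    a1, a2 = np.abs(e1), np.abs(e2)
    big = np.maximum(a1, a2)
    small = np.minimum(a1, a2)
    return big, small


def _channels(img: np.ndarray) -> dict[str, np.ndarray]:
    gv = np.gradient(img, axis=0)
    gl = np.gradient(img, axis=1)
    e1, e2 = _hessian_eigs(img)
    return {
        "intensity": img,
        "gradient": np.hypot(gv, gl),
        "hessian_e1": e1,
        "hessian_e2": e2,
    }


def snr_channels(clean: np.ndarray, noisy: np.ndarray) -> dict[str, float]:
    """SNR of intensity, gradient magnitude, and Hessian eigenvalue images.

    SNR = RMS of the clean channel over the RMS of the channel difference;
    identical inputs report ``inf`` (flagged by the caller as noise-free).
    """
    if clean.shape != noisy.shape:
        raise ValueError("shape mismatch")
    out = {}
    for name, ch_clean in _channels(clean).items():
        ch_noisy = _channels(noisy)[name]
        num = np.sqrt(np.mean(ch_clean**2))
        den = np.sqrt(np.mean((ch_noisy - ch_clean) ** 2))
        out[name] = float("inf") if den == 0 else float(num / den)
    return out
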