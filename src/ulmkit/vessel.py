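"""Vessel-level metrology from bubble trajectories.

Micro-vessels: trajectory heatmaps are profiled across the vessel axis and
fitted with sums of Gaussians; each fitted line reports its location error
``E_l``, width ``eps_l = 2 sigma``, area fraction ``AF`` (% of total fitted
area) and index of detection ``ID`` (peak linewise mean over linewise
standard deviation, normalized to 100 over lines).  A linear rule in
(AF, ID),

    0.10 AF + 0.038 ID - 4.64  < 0   ->  negligible ghost line,

classifies the spurious middle line that appears when overlapping traces
of two parallel vessels localize to their midpoint; the same hyperplane
can be refitted from labeled data with a maximum-margin classifier.

Macro-vessels: per-track speeds binned by radial position give the
measured profile ``U_m(r)`` and relative error ``E_u(r)``; the vessel
radius is estimated from the zero crossing of a parabolic fit to either
the velocity profile or the track-count profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grids import GridSpec
from .tracking import Track

#: ghost-line decision rule coefficients on the (AF, ID) percent scales
GHOST_BOUNDARY = (0.10, 0.038, -4.64)

SEPARATION_CATEGORIES = (
    "unseparated",
    "overlapped",
    "nonnegligible_ghost",
    "negligible_ghost",
    "fully_separated",
)


def heatmap(
    tracks: list[Track],
    grid: GridSpec | None = None,
    pitch_um: float | None = None,
) -> np.ndarray:
    """Per-superres-pixel count of distinct track traversals.

    Each track contributes at most one count to a pixel regardless of how
    many of its samples fall there, so slow bubbles do not over-weight.
    Successive samples are joined by dense linear interpolation to avoid
    gaps at high speed.
    """
    grid = grid or GridSpec()
    pitch = pitch_um or grid.superres_pixel_um
    n = int(round(grid.window_um / pitch))
    counts = np.zeros((n, n))
    for tr in tracks:
        if not tr.frames:
            continue
        pos = np.array(tr.positions_um)
        pts = [pos[0]]
        for a, b in zip(pos[:-1], pos[1:]):
            steps = max(1, int(np.ceil(np.linalg.norm(b - a) / (0.5 * pitch))))
            for s in range(1, steps + 1):
                pts.append(a + (b - a) * s / steps)
        idx = np.floor(np.array(pts) / pitch).astype(int)
        idx = idx[(idx[:, 0] >= 0) & (idx[:, 0] < n) & (idx[:, 1] >= 0) & (idx[:, 1] < n)]
        if len(idx):
            flat = np.unique(idx[:, 0] * n + idx[:, 1])
            counts.ravel()[flat] += 1.0
    return counts


# ---------------------------------------------------------------------------
# line profiling


@dataclass
class LineFit:
    position_um: float
    amplitude: float
    sigma_um: float
    E_l_um: float | None = None  # |fitted peak - true line position|
    eps_l_um: float = 0.0  # 2 sigma
    AF_pct: float = 0.0
    ID: float = 0.0
    is_ghost: bool | None = None
    category: str | None = None


@dataclass
class LineReport:
    fits: list[LineFit]
    profile: np.ndarray
    axis_um: np.ndarray
    converged: bool = True

    def primary(self) -> list[LineFit]:
        return sorted(self.fits, key=lambda f: -f.amplitude)


def _multi_gauss(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return out


def line_profile_fit(
    heat: np.ndarray,
    axis: int,
    grid: GridSpec | None = None,
    n_peaks_hint: int | None = None,
    true_positions_um: list[float] | None = None,
    smooth_sigma_px: float = 1.0,
) -> LineReport:
    """Fit the cross-line profile of a heatmap with a sum of Gaussians.

    ``axis`` is the axis the lines run along (0 = lines along depth);
    the profile is the mean over that axis.  One Gaussian component is
    used per local maximum of the lightly smoothed profile (or
    ``n_peaks_hint`` components when given).
    """
    grid = grid or GridSpec()
    pitch = grid.window_um / heat.shape[0]
    profile = heat.mean(axis=axis)
    coords = (np.arange(len(profile)) + 0.5) * pitch

    smoothed = ndimage.gaussian_filter1d(profile, smooth_sigma_px)
    interior = np.zeros(len(smoothed), dtype=bool)
    interior[1:-1] = (smoothed[1:-1] > smoothed[:-2]) & (smoothed[1:-1] >= smoothed[2:])
    interior &= smoothed > 0.05 * smoothed.max()
    peak_idx = np.flatnonzero(interior)
    if n_peaks_hint is not None and len(peak_idx) > n_peaks_hint:
        order = np.argsort(-smoothed[peak_idx])
        peak_idx = np.sort(peak_idx[order[:n_peaks_hint]])
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(smoothed))])

    p0 = []
    for i in peak_idx:
        p0.extend([profile[i], coords[i], 2.0 * pitch])
    try:
        popt, _ = optimize.curve_fit(
            _multi_gauss, coords, profile, p0=p0, maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt = np.array(p0)
        converged = False
    fits = []
    for i in range(0, len(popt), 3):
        a, mu, sigma = popt[i : i + 3]
        fits.append(
            LineFit(
                position_um=float(mu),
                amplitude=float(abs(a)),
                sigma_um=float(abs(sigma)),
                eps_l_um=float(2.0 * abs(sigma)),
            )
        )
    fits.sort(key=lambda f: f.position_um)
    if true_positions_um is not None:
        truths = np.asarray(true_positions_um, dtype=float)
        for f in fits:
            f.E_l_um = float(np.abs(truths - f.position_um).min())
    return LineReport(fits=fits, profile=profile, axis_um=coords, converged=converged)


def ghost_features(report: LineReport, heat: np.ndarray, axis: int) -> LineReport:
    """Attach area fractions and detection indices to fitted lines.

    ``AF`` is each component's fitted area as a percentage of the total;
    ``ID`` is the peak linewise mean over the linewise standard deviation
    at the fitted position, normalized so the strongest line scores 100.
    A continuous line has low variance along its length, hence a high ID;
    an intermittent ghost line of equal mean scores lower.
    """
    areas = np.array([f.amplitude * f.sigma_um for f in report.fits])
    total = areas.sum()
    if total > 0:
        for f, a in zip(report.fits, areas):
            f.AF_pct = float(100.0 * a / total)
    pitch = report.axis_um[1] - report.axis_um[0]
    mean_line = heat.mean(axis=axis)
    std_line = heat.std(axis=axis)
    raw_ids = []
    for f in report.fits:
        j = int(np.clip(round(f.position_um / pitch - 0.5), 0, len(mean_line) - 1))
        if std_line[j] == 0:
            raw_ids.append(np.inf)
        else:
            raw_ids.append(mean_line[j] / std_line[j])
    raw = np.array(raw_ids)
    finite_max = raw[np.isfinite(raw)].max() if np.isfinite(raw).any() else 1.0
    for f, r in zip(report.fits, raw):
        f.ID = 100.0 if not np.isfinite(r) else float(100.0 * r / max(finite_max, 1e-12))
    return report


def classify_ghost(AF_pct: float, ID: float) -> str:
    """Eq-of-line rule on the (AF, ID) percent scales.

    Scores on or above the boundary are non-negligible (the boundary
    itself is conservative: a line exactly on it is kept as a candidate
    vessel).
    """
    a, b, c = GHOST_BOUNDARY
    score = a * AF_pct + b * ID + c
    return "negligible" if score < 0 else "nonnegligible"


def fit_ghost_boundary(
    features: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Maximum-margin linear boundary between primary and ghost lines.

    ``features`` is (n, 2) of (AF, ID); ``labels`` is boolean (True =
    ghost).  Returns (w, b, margin): the decision line is w.z + b = 0 and
    the negative hyperplane (the shipped negligibility rule's analog) is
    w.z + b = -1.
    """
    from sklearn.svm import SVC

    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("need samples of both classes")
    clf = SVC(kernel="linear", C=1e6)
    clf.fit(np.asarray(features, dtype=float), labels.astype(int))
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    margin = 2.0 / np.linalg.norm(w)
    return w, b, margin


def classify_separation(
    report: LineReport,
    unseparated_trough: float = 0.95,
    separated_floor: float = 0.05,
) -> str:
    """Five-way separation category of a two-line scene.

    * one fitted peak, or a trough above 95% of the primary peak:
      ``unseparated``;
    * two peaks with the trough above the fully-separated floor:
      ``overlapped``;
    * three peaks: ghost line in the middle -- ``negligible_ghost`` or
      ``nonnegligible_ghost`` by the (AF, ID) rule;
    * two peaks with the trough below the floor: ``fully_separated``.
    """
    fits = report.fits
    if len(fits) <= 1:
        return "unseparated"
    profile, coords = report.profile, report.axis_um
    outer = sorted(fits, key=lambda f: -f.amplitude)[:2]
    lo, hi = sorted(f.position_um for f in outer)
    between = (coords > lo) & (coords < hi)
    primary = max(f.amplitude for f in outer)
    trough = profile[between].min() if between.any() else 0.0
    if trough >= unseparated_trough * primary:
        return "unseparated"
    if len(fits) >= 3:
        middle = sorted(fits, key=lambda f: f.position_um)[1]
        label = classify_ghost(middle.AF_pct, middle.ID)
        return "negligible_ghost" if label == "negligible" else "nonnegligible_ghost"
    if trough < separated_floor * primary:
        return "fully_separated"
    return "overlapped"


# ---------------------------------------------------------------------------
# macro-vessel velocimetry


@dataclass
class VesselReport:
    r_um: np.ndarray
    U_m: np.ndarray  # um/s
    U_ref: np.ndarray
    E_u: np.ndarray  # |binned mean / reference - 1|: systematic error
    E_u_scatter: np.ndarray | None = None  # mean |per-sample deviation|
    proxy: np.ndarray | None = None
    n_samples: np.ndarray | None = None
    R_m_um: float | None = None
    E_r: float | None = None


def track_point_speeds(
    tracks: list[Track], frame_interval_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample positions and speeds from central differences in time."""
    pts, speeds = [], []
    for tr in tracks:
        if len(tr.frames) < 3:
            continue
        f = np.array(tr.frames, dtype=float) * frame_interval_s
        p = np.array(tr.positions_um)
        v = np.gradient(p, f, axis=0)
        pts.append(p)
        speeds.append(np.linalg.norm(v, axis=1))
    if not pts:
        return np.zeros((0, 2)), np.zeros(0)
    return np.vstack(pts), np.concatenate(speeds)


def velocity_profile(
    tracks: list[Track],
    axis_position_um: float,
    R_um: float,
    U_max_um_s: float,
    orientation: str = "aligned",
    bin_width_um: float = 20.0,
    frame_interval_s: float = 1.0 / 48.0,
    E_c_um: float | None = None,
) -> VesselReport:
    """Binned measured speed vs radial position, with relative errors.

    ``E_u(r) = |(U_m - U_ref) / U_ref|`` where ``U_m`` is the binned mean
    speed and the reference is evaluated at each sample's own radius, so
    bin discretization does not masquerade as velocity error.  Random
    localization scatter largely cancels in the bin mean; its magnitude
    is reported separately as ``E_u_scatter`` (mean absolute per-sample
    deviation), which is the quantity the misplacement proxy
    ``|dU_ref/dr * E_c / U_ref|`` models.
    """
    pts, speeds = track_point_speeds(tracks, frame_interval_s)
    across = pts[:, 0] if orientation == "aligned" else pts[:, 1]
    r = across - axis_position_um
    u_ref_sample = U_max_um_s * np.clip(1.0 - (r / R_um) ** 2, 1e-9, None)
    rel_dev = (speeds - u_ref_sample) / u_ref_sample
    edges = np.arange(-R_um, R_um + bin_width_um, bin_width_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    U_m = np.full(len(centers), np.nan)
    E_u = np.full(len(centers), np.nan)
    scatter = np.full(len(centers), np.nan)
    n_samples = np.zeros(len(centers), dtype=int)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mask = (r >= lo) & (r < hi)
        n_samples[i] = mask.sum()
        if n_samples[i]:
            U_m[i] = speeds[mask].mean()
            E_u[i] = abs(speeds[mask].mean() / u_ref_sample[mask].mean() - 1.0)
            scatter[i] = np.abs(rel_dev[mask]).mean()
    U_ref = U_max_um_s * np.clip(1.0 - (centers / R_um) ** 2, 1e-9, None)
    proxy = None
    if E_c_um is not None:
        dUdr = np.abs(-2.0 * U_max_um_s * centers / R_um**2)
        proxy = dUdr * E_c_um / U_ref
    return VesselReport(
        r_um=centers,
        U_m=U_m,
        U_ref=U_ref,
        E_u=E_u,
        E_u_scatter=scatter,
        proxy=proxy,
        n_samples=n_samples,
    )


def track_count_profile(
    tracks: list[Track],
    axis_position_um: float,
    R_um: float,
    orientation: str = "aligned",
    bin_width_um: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Number of distinct tracks crossing each radial bin."""
    edges = np.arange(-1.2 * R_um, 1.2 * R_um + bin_width_um, bin_width_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    for tr in tracks:
        if not tr.frames:
            continue
        pos = np.array(tr.positions_um)
        across = pos[:, 0] if orientation == "aligned" else pos[:, 1]
        r = across - axis_position_um
        hit = np.unique(np.clip(np.digitize(r, edges) - 1, 0, len(centers) - 1))
        counts[hit] += 1
    return centers, counts


def estimate_radius(
    r_um: np.ndarray,
    profile: np.ndarray,
    R_true_um: float | None = None,
    method: str = "velocity_parabola",
) -> tuple[float, float | None]:
    """Vessel radius from a profile across the lumen.

    Parabolic methods fit ``a (1 - (r/R_m)^2)`` by least squares and
    return the zero crossing ``R_m``; the Gaussian method returns the
    fitted sigma (its mapping to a radius is not unique, which is why the
    parabolic zero crossing is the shipped default).  ``E_r`` is reported
    when the true radius is known.
    """
    mask = np.isfinite(profile)
    r, p = np.asarray(r_um, dtype=float)[mask], np.asarray(profile, dtype=float)[mask]
    # drop empty bins at the profile edges (outside the lumen): the
    # parabola should be fitted to the occupied cross-section
    occupied = np.flatnonzero(p > 0)
    if len(occupied) >= 3:
        r, p = r[occupied[0] : occupied[-1] + 1], p[occupied[0] : occupied[-1] + 1]
    if method in ("velocity_parabola", "trackcount_parabola"):
        # p = a - c r^2 with a, c > 0; R_m = sqrt(a / c)
        A = np.vstack([np.ones_like(r), -(r**2)]).T
        coef, *_ = np.linalg.lstsq(A, p, rcond=None)
        a, c = coef
        if a <= 0 or c <= 0:
            raise ValueError("concave-up fit: no zero crossing")
        R_m = float(np.sqrt(a / c))
    elif method == "trackcount_gaussian":
        a0 = p.max()
        popt, _ = optimize.curve_fit(
            lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
            r,
            p,
            p0=[a0, 0.0, max(r.max() / 2, 1.0)],
            maxfev=10000,
        )
        R_m = float(abs(popt[2]))  # one sigma; see docstring
    else:
        raise ValueError(f"unknown method {method!r}")
    E_r = None if R_true_um is None else float(abs(R_m - R_true_um) / R_true_um)
    return R_m, E_r


def power_law_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares power law ``y = c x^m`` in log-log space.

    Returns (coefficient, exponent, R^2 of the log-space line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit requires positive data")
    lx, ly = np.log(x), np.log(y)
    m, b = np.polyfit(lx, ly, 1)
    pred = m * lx + b
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(b)), float(m), float(r2)
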