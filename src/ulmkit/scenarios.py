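"""Motion scenarios: parallel micro-vessel lines and parabolic macro-vessels.

Two idealized geometries probe the resolution and velocimetry limits of a
localizer:

* two parallel lines separated by tens to hundreds of microns, traversed by
  bubbles at a typical microvascular speed of 5 mm/s;
* a straight tubular vessel with a parabolic (Poiseuille) velocity profile,
  ``U_ref(r) = U_max (1 - (r/R)^2)``, peaking at 5 cm/s on the axis.

Orientations are specified relative to the PSF major axis, which for the
default evaluation kernels lies along the lateral (horizontal) axis:
``aligned`` runs the vessel along lateral, ``perpendicular`` along depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec
from .noise import NoiseSpec
from .psf import PSFModel
from .scene import SceneSequence

LINE_SPACINGS_UM = (18.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0)


@dataclass(frozen=True)
class LineScenario:
    """Two parallel lines D_l apart traversed at constant speed."""

    D_l_um: float = 60.0
    orientation: str = "aligned"  # relative to the PSF major axis
    speed_um_s: float = 5000.0  # 5 mm/s, typical microvascular magnitude
    steps: int = 2500
    #: mean Poisson arrivals per frame per line
    arrival_rate: float = 1.0 / 40.0

    def __post_init__(self) -> None:
        if self.D_l_um <= 0:
            raise ValueError("line spacing must be positive")
        if self.orientation not in ("aligned", "perpendicular"):
            raise ValueError("orientation must be 'aligned' or 'perpendicular'")


@dataclass(frozen=True)
class VesselScenario:
    """Tubular vessel of radius R with a parabolic velocity profile."""

    R_um: float = 180.0
    U_max_um_s: float = 50000.0  # 5 cm/s at the centerline
    steps: int = 5000
    mean_spacing_um: float = 330.0
    orientation: str = "aligned"

    def __post_init__(self) -> None:
        if self.orientation not in ("aligned", "perpendicular"):
            raise ValueError("orientation must be 'aligned' or 'perpendicular'")

    def U_ref(self, r) -> np.ndarray:
        """Prescribed speed at radial coordinate ``r`` (zero at the wall)."""
        r = np.asarray(r, dtype=float)
        return self.U_max_um_s * np.clip(1.0 - (r / self.R_um) ** 2, 0.0, None)


def _axes_to_positions(along, across, orientation: str) -> np.ndarray:
    """Map (along-axis, across-axis) coordinates to (depth, lateral)."""
    along = np.asarray(along, dtype=float)
    across = np.asarray(across, dtype=float)
    if orientation == "aligned":  # vessel along the lateral axis
        return np.column_stack([across, along])
    return np.column_stack([along, across])


def simulate_lines(
    scenario: LineScenario,
    psf: PSFModel,
    noise: NoiseSpec | None,
    grid: GridSpec | None = None,
    seed: int | None = None,
) -> SceneSequence:
    """Advect bubbles along two parallel lines; returns per-frame truth.

    New bubbles enter each line independently by a Poisson arrival process
    and leave when they exit the window; intensities are drawn uniformly in
    [0.6, 1] and stay constant along a bubble's transit.
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    L = grid.window_um
    center = L / 2.0
    line_across = np.array([center - scenario.D_l_um / 2.0, center + scenario.D_l_um / 2.0])
    if line_across.min() < 0 or line_across.max() >= L:
        raise ValueError("lines fall outside the window")
    step_um = scenario.speed_um_s * grid.frame_interval_s

    # state per line: along-axis positions and intensities
    along = [np.zeros(0), np.zeros(0)]
    inten = [np.zeros(0), np.zeros(0)]
    bubbles_per_frame = []
    for _ in range(scenario.steps):
        frame_rows = []
        for li in range(2):
            n_new = rng.poisson(scenario.arrival_rate)
            if n_new:
                # arrivals spread over the step they enter during
                entry = rng.uniform(0.0, step_um, size=n_new)
                along[li] = np.concatenate([along[li], entry])
                inten[li] = np.concatenate([inten[li], rng.uniform(0.6, 1.0, size=n_new)])
            keep = along[li] < L
            along[li], inten[li] = along[li][keep], inten[li][keep]
            if len(along[li]):
                pos = _axes_to_positions(
                    along[li], np.full(len(along[li]), line_across[li]), scenario.orientation
                )
                frame_rows.append(np.column_stack([pos, inten[li]]))
            along[li] = along[li] + step_um
        bubbles_per_frame.append(
            np.vstack(frame_rows) if frame_rows else np.zeros((0, 3))
        )
    return SceneSequence(bubbles_per_frame, psf, noise, grid, seed=seed)


def simulate_vessel(
    scenario: VesselScenario,
    psf: PSFModel,
    noise: NoiseSpec | None,
    grid: GridSpec | None = None,
    seed: int | None = None,
) -> SceneSequence:
    """Propagate bubbles through a parabolic vessel; returns per-frame truth.

    Each bubble keeps its radial coordinate and advances at ``U_ref(r)``.
    The bubble count is fixed so the mean along-axis spacing stays near the
    prescribed value; a bubble leaving the window re-enters upstream with a
    fresh intensity, which keeps the radial occupancy uniform over the
    lumen.
    """
    grid = grid or GridSpec()
    if scenario.R_um < grid.native_pixel_um:
        raise ValueError("vessel radius below one native pixel")
    L = grid.window_um
    center = L / 2.0
    if center - scenario.R_um < 0 or center + scenario.R_um >= L:
        raise ValueError("vessel does not fit inside the window")
    rng = np.random.default_rng(seed)

    n = max(1, int(round(L / scenario.mean_spacing_um)) - 1)
    along = rng.uniform(0.0, L, size=n)
    radial = rng.uniform(-scenario.R_um, scenario.R_um, size=n)
    inten = rng.uniform(0.6, 1.0, size=n)
    dt = grid.frame_interval_s

    bubbles_per_frame = []
    for _ in range(scenario.steps):
        pos = _axes_to_positions(along, center + radial, scenario.orientation)
        bubbles_per_frame.append(np.column_stack([pos, inten]).copy())
        along = along + scenario.U_ref(radial) * dt
        wrapped = along >= L
        if wrapped.any():
            along[wrapped] -= L
            inten[wrapped] = rng.uniform(0.6, 1.0, size=wrapped.sum())
    return SceneSequence(bubbles_per_frame, psf, noise, grid, seed=seed)
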