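"""Sub-pixel detection sets and centroid extraction from center maps.

All localizers in the package (blind deconvolution and both networks)
reduce a center-likelihood map on the lambda/14 grid to intensity-weighted
centroids of connected super-threshold components; positions are reported
in microns with the pixel-center convention ``(index + 0.5) * pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed


@dataclass
class DetectionSet:
    """Detected centers for one frame: positions (n, 2) um and weights."""

    positions_um: np.ndarray
    weights: np.ndarray
    frame: int | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.positions_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "depth_um": self.positions_um[:, 0],
                "lateral_um": self.positions_um[:, 1],
                "weight": self.weights,
            }
        )


def detections_to_table(detsets: list[DetectionSet]) -> pd.DataFrame:
    """Stack per-frame detection sets into one tidy table."""
    frames = [ds.to_frame() for ds in detsets if len(ds)]
    if not frames:
        return pd.DataFrame(columns=["frame", "depth_um", "lateral_um", "weight"])
    return pd.concat(frames, ignore_index=True)


def extract_centers_from_map(
    center_map: np.ndarray,
    pitch_um: float,
    threshold: float,
    frame: int | None = None,
    split_peaks_min_distance: int | None = None,
) -> DetectionSet:
    """Weighted centroids of super-threshold components of a center map.

    With ``split_peaks_min_distance`` set (in pixels), connected components
    containing several local maxima at least that far apart are divided
    between the maxima by watershed before the centroids are computed, so
    two bubbles whose blobs touch but keep distinct peaks yield two
    detections.
    """
    mask = center_map > threshold
    if not mask.any():
        return DetectionSet(np.zeros((0, 2)), np.zeros(0), frame=frame)
    if split_peaks_min_distance is not None:
        # ignore deconvolution ringing: genuine bubble peaks sit far above
        # the ~2% sidelobe level of the sparse solver
        floor = max(threshold, 0.2 * float(center_map.max()))
        peaks = peak_local_max(
            center_map,
            min_distance=split_peaks_min_distance,
            threshold_abs=floor,
            exclude_border=False,
        )
        if len(peaks) == 0:
            return DetectionSet(np.zeros((0, 2)), np.zeros(0), frame=frame)
        markers = np.zeros(center_map.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-center_map, markers, mask=mask)
        n = len(peaks)
    else:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    index = np.arange(1, n + 1)
    weights = ndimage.sum_labels(center_map, labels, index)
    keep = weights > 0
    index, weights = index[keep], weights[keep]
    centroids = np.array(ndimage.center_of_mass(center_map, labels, index)).reshape(-1, 2)
    positions = (centroids + 0.5) * pitch_um
    return DetectionSet(positions, weights, frame=frame)


def merge_window_detections(
    detsets: list[DetectionSet],
    radius_um: float = 30.0,
) -> DetectionSet:
    """Deduplicate detections from overlapping windows.

    Non-maximum suppression by weight: a detection within ``radius_um`` of
    an already accepted, heavier detection is dropped.
    """
    if not detsets:
        return DetectionSet(np.zeros((0, 2)), np.zeros(0))
    pos = np.vstack([ds.positions_um for ds in detsets])
    w = np.concatenate([ds.weights for ds in detsets])
    frame = detsets[0].frame
    if len(pos) == 0:
        return DetectionSet(pos, w, frame=frame)
    order = np.argsort(-w)
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(pos[i] - pos[j]) > radius_um for j in kept):
            kept.append(i)
    kept_arr = np.array(sorted(kept))
    return DetectionSet(pos[kept_arr], w[kept_arr], frame=frame)
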