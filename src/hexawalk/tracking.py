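"""Marker recovery from image stacks.

Threshold-based clustering yields intensity-weighted blob centroids per
frame; a greedy nearest-neighbour assignment carries manually initialised
labels through the stack; combining image positions with the recorded
gantry (camera) positions reconstructs arena coordinates.

The greedy distance-ordered assignment is deliberately simple and can
mislabel crossing markers; for the dorsal marker layout used here the nine
markers stay well separated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .walker import Trial

__all__ = ["Detection", "MarkerTrackSet", "Calibration", "TrackingError",
           "detect_markers", "track_markers", "to_arena_coords"]


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class Detection:
    """A supra-threshold connected blob in one frame."""

    frame: int
    centroid_px: tuple[float, float]  # (x, y), x right, y down
    n_pixels: int


@dataclass
class MarkerTrackSet:
    """Per-label image-space tracks with explicit gap flags."""

    labels: list[str]
    positions_px: np.ndarray  # (n_frames, n_labels, 2); NaN where gap
    gaps: np.ndarray          # (n_frames, n_labels) bool

    @property
    def n_frames(self) -> int:
        return self.positions_px.shape[0]

    def fully_labelled_fraction(self) -> float:
        return float(np.mean(~self.gaps.any(axis=1)))


@dataclass(frozen=True)
class Calibration:
    """Image-to-arena mapping. Arena axes: x east, y north; image y runs
    down, hence the default y flip."""

    mm_per_px: float
    image_centre_px: tuple[float, float]
    flip_x: bool = False
    flip_y: bool = True

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise TrackingError("mm_per_px must be > 0")


def detect_markers(frame: np.ndarray, intensity_threshold: float = 100,
                   min_pixels: int = 4, frame_index: int = 0
                   ) -> list[Detection]:
    """Connected components of supra-threshold pixels, brightest-weighted.

    Returns intensity-weighted centroids of all components with at least
    ``min_pixels`` pixels, sorted by descending pixel count.
    """
    img = np.asarray(frame)
    if img.ndim != 2:
        raise TrackingError("detect_markers expects a 2-D grayscale image")
    mask = img > intensity_threshold
    lab = measure.label(mask, connectivity=2)
    dets = []
    for rp in measure.regionprops(lab, intensity_image=img.astype(float)):
        if rp.area < min_pixels:
            continue
        cy, cx = rp.centroid_weighted
        dets.append(Detection(frame=frame_index, centroid_px=(cx, cy),
                              n_pixels=int(rp.area)))
    dets.sort(key=lambda d: -d.n_pixels)
    return dets


def _greedy_assign(last_pos: dict[str, tuple[float, float]],
                   dets: list[Detection], max_jump_px: float
                   ) -> dict[str, Detection]:
    """Assign each label to the nearest unused detection within max_jump."""
    pairs = []
    for lab, (x, y) in last_pos.items():
        for j, d in enumerate(dets):
            dist = math.hypot(d.centroid_px[0] - x, d.centroid_px[1] - y)
            if dist <= max_jump_px:
                pairs.append((dist, lab, j))
    pairs.sort(key=lambda p: p[0])
    used_labels: set[str] = set()
    used_dets: set[int] = set()
    out = {}
    for dist, lab, j in pairs:
        if lab in used_labels or j in used_dets:
            continue
        out[lab] = dets[j]
        used_labels.add(lab)
        used_dets.add(j)
    return out


def track_markers(frames: np.ndarray, initial_labels: dict,
                  max_jump_px: float = 15.0, *,
                  intensity_threshold: float = 100, min_pixels: int = 4
                  ) -> MarkerTrackSet:
    """Nearest-neighbour tracking of manually initialised labels.

    ``initial_labels`` maps each label to its approximate (x, y) image
    position in frame 0; each must resolve to a distinct frame-0 detection
    within ``max_jump_px``. Labels that find no detection in a frame are
    flagged as gaps and retain their last position for the next search.
    """
    labels = list(initial_labels)
    n = len(frames)
    pos = np.full((n, len(labels), 2), np.nan)
    gaps = np.zeros((n, len(labels)), dtype=bool)

    dets0 = detect_markers(frames[0], intensity_threshold, min_pixels, 0)
    claimed: dict[int, str] = {}
    last: dict[str, tuple[float, float]] = {}
    for lab in labels:
        x, y = initial_labels[lab]
        best, best_d = None, np.inf
        for j, d in enumerate(dets0):
            dist = math.hypot(d.centroid_px[0] - x, d.centroid_px[1] - y)
            if dist < best_d:
                best, best_d = j, dist
        if best is None or best_d > max_jump_px:
            raise TrackingError(
                f"label {lab}: no frame-0 detection within {max_jump_px} px")
        if best in claimed:
            raise TrackingError(
                f"labels {claimed[best]} and {lab} initialised on the same "
                f"detection")
        claimed[best] = lab
        last[lab] = dets0[best].centroid_px
        pos[0, labels.index(lab)] = dets0[best].centroid_px

    for k in range(1, n):
        dets = detect_markers(frames[k], intensity_threshold, min_pixels, k)
        assigned = _greedy_assign(last, dets, max_jump_px)
        for i, lab in enumerate(labels):
            if lab in assigned:
                last[lab] = assigned[lab].centroid_px
                pos[k, i] = assigned[lab].centroid_px
            else:
                gaps[k, i] = True
    return MarkerTrackSet(labels=labels, positions_px=pos, gaps=gaps)


def _fill_gaps(series: np.ndarray, max_gap: int, label: str) -> np.ndarray:
    """Linear interpolation of NaN runs of length <= max_gap; longer runs
    (or runs touching the series ends) raise."""
    out = series.copy()
    isnan = np.isnan(series[:, 0])
    if not isnan.any():
        return out
    idx = np.arange(len(series))
    runs = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8),
                                                  [0]))))
    for start, stop in zip(runs[::2], runs[1::2]):
        length = stop - start
        if length > max_gap or start == 0 or stop == len(series):
            raise TrackingError(
                f"marker {label}: unfillable gap at frames "
                f"{start}..{stop - 1} (max fillable: {max_gap})")
    good = ~isnan
    for c in range(2):
        out[isnan, c] = np.interp(idx[isnan], idx[good], series[good, c])
    return out


def to_arena_coords(tracks: MarkerTrackSet, gantry: np.ndarray,
                    cal: Calibration, *, frame_rate_hz: float = 50.0,
                    max_gap_fill: int = 3, animal_id: str = "A01",
                    cohort: str = "tracked") -> Trial:
    """Combine image tracks with the gantry stream into arena coordinates.

    arena = camera position + mm_per_px * (centroid - image centre), with
    axis flips per the calibration. Gaps are filled by linear interpolation
    up to ``max_gap_fill`` frames; longer gaps raise an error naming the
    marker and frame range.
    """
    gantry = np.asarray(gantry, dtype=float)
    if gantry.shape != (tracks.n_frames, 2):
        raise TrackingError("gantry stream must cover all frames (n x 2)")
    cx, cy = cal.image_centre_px
    sx = -1.0 if cal.flip_x else 1.0
    sy = -1.0 if cal.flip_y else 1.0
    markers = {}
    for i, lab in enumerate(tracks.labels):
        px = tracks.positions_px[:, i, :]
        arena = np.stack([
            gantry[:, 0] + sx * cal.mm_per_px * (px[:, 0] - cx),
            gantry[:, 1] + sy * cal.mm_per_px * (px[:, 1] - cy)], axis=1)
        markers[lab] = _fill_gaps(arena, max_gap_fill, lab)
    times = np.arange(tracks.n_frames) / frame_rate_hz
    return Trial(animal_id=animal_id, cohort=cohort,
                 frame_rate_hz=frame_rate_hz, times_s=times, markers=markers)
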