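"""Idealised camera model: render marker blobs into 8-bit frames.

Emulates the recording geometry of the motion-capture setup: a gantry-
mounted camera follows the walking animal from above at 50 frames/s,
480 x 640 px, while linear position sensors log the camera's own arena
position per frame. Markers appear as Gaussian intensity blobs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .walker import Trial

__all__ = ["CameraModel", "RenderError", "render_frames", "project_to_image",
           "DEFAULT_CAMERA"]


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class CameraModel:
    """Projection and follow model of the overhead camera.

    Image convention: origin top-left, x right, y down. The camera centre
    tracks the root marker (T3), optionally with Gaussian follow noise
    emulating the manual gantry drive; its true position per frame is
    reported as the gantry stream.
    """

    mm_per_px: float = 0.25
    image_size: tuple[int, int] = (480, 640)  # (height, width)
    blob_sigma_px: float = 2.0
    follow_noise_mm: float = 0.0
    blob_peak: int = 255

    @property
    def image_centre_px(self) -> tuple[float, float]:
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)  # (x, y)


DEFAULT_CAMERA = CameraModel()


def _as_camera(camera) -> CameraModel:
    if isinstance(camera, CameraModel):
        return camera
    cam = dict(camera or {})
    if "image_size" in cam:
        cam["image_size"] = tuple(cam["image_size"])
    return CameraModel(**cam)


def project_to_image(xy_mm: np.ndarray, cam_xy_mm: np.ndarray,
                     camera: CameraModel) -> np.ndarray:
    """Arena (mm, y north) -> image (px, y down) given the camera position."""
    cx, cy = camera.image_centre_px
    px = cx + (xy_mm[..., 0] - cam_xy_mm[..., 0]) / camera.mm_per_px
    py = cy - (xy_mm[..., 1] - cam_xy_mm[..., 1]) / camera.mm_per_px
    return np.stack([px, py], axis=-1)


def render_frames(trial: Trial, camera=None,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale frame per time sample plus the gantry stream.

    Returns ``(stack, gantry)`` where ``stack`` is uint8 of shape
    ``(n_frames, height, width)`` and ``gantry`` is ``(n_frames, 2)`` with
    the camera arena position (mm) per frame. Blob centroids remain
    recoverable to sub-pixel accuracy by intensity-weighted detection.
    """
    cam = _as_camera(camera)
    rng = np.random.default_rng(seed)
    h, w = cam.image_size
    n = trial.n_frames

    gantry = np.array(trial.markers["T3"], dtype=float, copy=True)
    if cam.follow_noise_mm > 0.0:
        gantry += rng.normal(0.0, cam.follow_noise_mm, size=gantry.shape)

    stack = np.zeros((n, h, w), dtype=np.uint8)
    r = int(math.ceil(4.0 * cam.blob_sigma_px))
    labels = list(trial.markers)
    pos_px = {lab: project_to_image(trial.markers[lab], gantry, cam)
              for lab in labels}
    for k in range(n):
        acc = np.zeros((h, w), dtype=float)
        for lab in labels:
            px, py = pos_px[lab][k]
            if not (0.0 <= px <= w - 1 and 0.0 <= py <= h - 1):
                raise RenderError(
                    f"marker {lab} out of frame at frame {k}: "
                    f"({px:.1f}, {py:.1f}) px")
            x0, x1 = max(0, int(px) - r), min(w, int(px) + r + 1)
            y0, y1 = max(0, int(py) - r), min(h, int(py) + r + 1)
            ys, xs = np.mgrid[y0:y1, x0:x1]
            d2 = (xs - px) ** 2 + (ys - py) ** 2
            acc[y0:y1, x0:x1] += cam.blob_peak * np.exp(
                -d2 / (2.0 * cam.blob_sigma_px ** 2))
        stack[k] = np.clip(np.rint(acc), 0, 255).astype(np.uint8)
    return stack, gantry
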