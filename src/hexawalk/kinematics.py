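"""Body-centred kinematics: body frame, protraction angles, velocities.

Conventions (all interfaces in degrees, mm, seconds):

* the body-frame origin is the metathorax root marker T3; the heading is
  the direction from T3 to the prothorax marker T1 (0 deg = arena +x,
  90 deg = arena +y), unwrapped across frames;
* the protraction/retraction angle of a leg is the signed angle between
  the thoracic-to-femoral marker line and the body-axis perpendicular on
  that leg's side — 0 deg means the femur is orthogonal to the body axis,
  positive means it points forward, +90 deg is anterior-parallel;
* body velocities are forward Tx (mm/s), sideward Ty (mm/s, positive to
  the animal's left) and yaw Rot (deg/s, positive counter-clockwise),
  smoothed with a 60 ms sliding median (3 frames at 50 Hz).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import LEG_IDS, THORAX_OF_LEG
from .walker import Trial

__all__ = ["BodyFrameSeries", "AngleSeries", "VelocitySeries", "body_frame",
           "protraction_angles", "body_velocities", "sliding_median"]


class KinematicsError(ValueError):
    pass


@dataclass
class BodyFrameSeries:
    times_s: np.ndarray
    origin_mm: np.ndarray     # (n, 2) arena position of the root marker
    heading_deg: np.ndarray   # unwrapped


@dataclass
class AngleSeries:
    leg_id: str
    times_s: np.ndarray
    protraction_deg: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.protraction_deg):
            raise KinematicsError(f"{self.leg_id}: length mismatch")


@dataclass
class VelocitySeries:
    """Frame-pair velocities; times at the midpoints of frame pairs."""

    times_s: np.ndarray
    tx_mm_s: np.ndarray
    ty_mm_s: np.ndarray
    rot_deg_s: np.ndarray


def body_frame(trial: Trial, axis_fit: str = "chord") -> BodyFrameSeries:
    """Estimate the per-frame body frame from the thoracic markers.

    ``axis_fit='chord'`` (default) takes the heading straight from the
    T3->T1 marker chord; ``'fit'`` uses a total-least-squares line through
    all three thoracic markers (signed to agree with the chord).
    """
    for lab in ("T1", "T3"):
        if lab not in trial.markers:
            raise KinematicsError(f"thoracic marker {lab} missing")
    origin = trial.markers["T3"]
    chord = trial.markers["T1"] - origin
    norm = np.hypot(chord[:, 0], chord[:, 1])
    if np.any(norm < 1e-9):
        raise KinematicsError("coincident thoracic markers T1/T3")
    if axis_fit == "chord":
        heading = np.degrees(np.arctan2(chord[:, 1], chord[:, 0]))
    elif axis_fit == "fit":
        if "T2" not in trial.markers:
            raise KinematicsError("thoracic marker T2 missing")
        pts = np.stack([trial.markers[l] for l in ("T1", "T2", "T3")], axis=1)
        ctr = pts.mean(axis=1, keepdims=True)
        d = pts - ctr
        # principal axis of the 3-point scatter, per frame
        sxx = (d[:, :, 0] ** 2).sum(1)
        syy = (d[:, :, 1] ** 2).sum(1)
        sxy = (d[:, :, 0] * d[:, :, 1]).sum(1)
        theta = 0.5 * np.arctan2(2 * sxy, sxx - syy)
        axis = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        sign = np.sign((axis * chord).sum(1))
        sign[sign == 0] = 1.0
        axis *= sign[:, None]
        heading = np.degrees(np.arctan2(axis[:, 1], axis[:, 0]))
    else:
        raise KinematicsError(f"unknown axis_fit {axis_fit!r}")
    heading = np.degrees(np.unwrap(np.radians(heading)))
    return BodyFrameSeries(times_s=trial.times_s, origin_mm=origin,
                           heading_deg=heading)


def protraction_angles(trial: Trial, body: BodyFrameSeries
                       ) -> dict[str, AngleSeries]:
    """Protraction/retraction angle time course for each of the six legs.

    Front legs use the prothorax marker, middle legs the mesothorax marker,
    hind legs the metathorax root marker as the proximal reference.
    """
    h = np.radians(body.heading_deg)
    c, s = np.cos(h), np.sin(h)
    out = {}
    for leg_id in LEG_IDS:
        thorax = trial.markers[THORAX_OF_LEG[leg_id]]
        femur = trial.markers[leg_id]
        v = femur - thorax
        if np.any(np.hypot(v[:, 0], v[:, 1]) < 1e-9):
            raise KinematicsError(f"{leg_id}: zero-length femur vector")
        # rotate into the body frame (x anterior, y left)
        vb_x = c * v[:, 0] + s * v[:, 1]
        vb_y = -s * v[:, 0] + c * v[:, 1]
        side = 1.0 if leg_id.startswith("L") else -1.0
        ang = np.degrees(np.arctan2(vb_x, side * vb_y))
        out[leg_id] = AngleSeries(leg_id=leg_id, times_s=trial.times_s,
                                  protraction_deg=ang)
    return out


def sliding_median(series: np.ndarray, window: int) -> np.ndarray:
    """Sliding median with edge truncation; length-preserving.

    ``window`` must be odd; near the edges the window shrinks to whatever
    samples exist (e.g. the first output of a 3-window is the median of the
    first two samples).
    """
    if window < 1 or window % 2 == 0:
        raise KinematicsError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if window == 1 or len(x) <= 1:
        return x.copy()
    h = window // 2
    n = len(x)
    out = np.empty_like(x)
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view
        out[h:n - h] = np.median(sliding_window_view(x, window), axis=1)
        edge = h
    else:
        edge = n
    for i in range(min(edge, n)):
        out[i] = np.median(x[max(0, i - h):i + h + 1])
        out[n - 1 - i] = np.median(x[max(0, n - 1 - i - h):n - i + h])
    return out


def body_velocities(body: BodyFrameSeries, window_ms: float = 60.0
                    ) -> VelocitySeries:
    """Tx/Ty/Rot from frame-to-frame shifts, median-filtered.

    The displacement of the body origin between consecutive frames is
    projected onto the heading direction of the earlier frame (Tx) and its
    left normal (Ty); Rot is the heading increment over the frame interval.
    The filter window is ``round(window_ms * rate / 1000)`` forced odd.
    """
    if window_ms <= 0:
        raise KinematicsError("window_ms must be > 0")
    t = np.asarray(body.times_s, dtype=float)
    if len(t) < 2:
        raise KinematicsError("need at least 2 frames")
    dt = np.diff(t)
    disp = np.diff(body.origin_mm, axis=0)
    h = np.radians(body.heading_deg[:-1])
    c, s = np.cos(h), np.sin(h)
    tx = (c * disp[:, 0] + s * disp[:, 1]) / dt
    ty = (-s * disp[:, 0] + c * disp[:, 1]) / dt
    rot = np.diff(body.heading_deg) / dt
    rate = 1.0 / float(np.median(dt))
    window = int(round(window_ms * rate / 1000.0))
    window = max(window, 1)
    if window % 2 == 0:
        window += 1
    return VelocitySeries(
        times_s=(t[:-1] + t[1:]) / 2.0,
        tx_mm_s=sliding_median(tx, window),
        ty_mm_s=sliding_median(ty, window),
        rot_deg_s=sliding_median(rot, window))
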