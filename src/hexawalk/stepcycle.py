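"""Step-cycle segmentation from protraction-angle time courses.

Local maxima of the protraction angle are anterior extreme positions (AEP,
touch-down / stance onset); local minima are posterior extreme positions
(PEP, lift-off / swing onset). These movement-reversal estimates neglect
the small phase shift between the joint-angle reversal and true ground
contact — a known, deliberate bias shared with the standard kinematic
convention.

Numerical choices: the series is pre-filtered with a short sliding median
(default 5 samples, i.e. 100 ms at 50 Hz) before extremum extraction so
that frame-level angle noise does not seed spurious reversals; the event
angle is then refined by a quadratic fit to the *raw* series around the
detected index (reading the filtered series directly would flatten the
extremum, biasing AEPs down and PEPs up by the trajectory curvature
within the filter window; reading the raw sample alone inherits the
frame-clock quantisation on the steep stance side). Event times stay on
the frame clock.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .kinematics import AngleSeries, sliding_median

__all__ = ["StepEvent", "StepCycle", "detect_events", "step_cycles",
           "cycles_table"]

AEP = "AEP"
PEP = "PEP"


@dataclass(frozen=True)
class StepEvent:
    leg_id: str
    kind: str  # AEP | PEP
    time_s: float
    angle_deg: float


@dataclass(frozen=True)
class StepCycle:
    """One AEP -> PEP -> next-AEP triple with derived step parameters."""

    leg_id: str
    aep_time_s: float
    aep_deg: float
    pep_time_s: float
    pep_deg: float
    next_aep_time_s: float

    @property
    def period_s(self) -> float:
        return self.next_aep_time_s - self.aep_time_s

    @property
    def length_deg(self) -> float:
        return self.aep_deg - self.pep_deg

    @property
    def stance_s(self) -> float:
        return self.pep_time_s - self.aep_time_s

    @property
    def swing_s(self) -> float:
        return self.next_aep_time_s - self.pep_time_s


def _enforce_alternation(events: list[StepEvent]) -> list[StepEvent]:
    """Of two consecutive same-kind events keep the more extreme one."""
    out: list[StepEvent] = []
    for ev in events:
        if out and out[-1].kind == ev.kind:
            prev = out[-1]
            if ev.kind == AEP:
                keep = ev if ev.angle_deg > prev.angle_deg else prev
            else:
                keep = ev if ev.angle_deg < prev.angle_deg else prev
            out[-1] = keep
        else:
            out.append(ev)
    return out


def _vertex_angle(x: np.ndarray, i: int, halfwin: int = 2) -> float:
    """Value of the local quadratic fit to ``x`` around index ``i``,
    evaluated at the fitted vertex (clipped to the window)."""
    lo, hi = max(0, i - halfwin), min(len(x), i + halfwin + 1)
    if hi - lo < 3:
        return float(x[i])
    j = np.arange(lo, hi) - i
    a, b, c = np.polyfit(j, x[lo:hi], 2)
    if a == 0.0:
        return float(x[i])
    jv = float(np.clip(-b / (2.0 * a), -halfwin, halfwin))
    return float(a * jv * jv + b * jv + c)


def detect_events(series: AngleSeries, min_prominence_deg: float = 5.0,
                  min_separation_s: float = 0.1, *, smooth_window: int = 5,
                  angle_readout: str = "vertex") -> list[StepEvent]:
    """Extract alternating AEP/PEP events from an angle time course.

    Peaks and troughs must clear ``min_prominence_deg`` and be separated by
    ``min_separation_s`` from their same-kind neighbours. Leading/trailing
    partial events are retained; an empty list is returned for flat series.
    ``angle_readout`` selects the event-angle estimate: ``"vertex"``
    (quadratic refinement, default) or ``"raw"`` (sample at the index).
    """
    if angle_readout not in ("vertex", "raw"):
        raise ValueError(f"unknown angle_readout {angle_readout!r}")
    x = np.asarray(series.protraction_deg, dtype=float)
    t = np.asarray(series.times_s, dtype=float)
    if len(x) < 3:
        raise ValueError("series must contain at least 3 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    xs = sliding_median(x, smooth_window) if smooth_window > 1 else x
    distance = max(1, int(round(min_separation_s * fs)))

    events: list[StepEvent] = []
    for sign, kind in ((1.0, AEP), (-1.0, PEP)):
        idx, _ = find_peaks(sign * xs, prominence=min_prominence_deg,
                            distance=distance)
        for i in idx:
            ang = (_vertex_angle(x, i) if angle_readout == "vertex"
                   else float(x[i]))
            events.append(StepEvent(leg_id=series.leg_id, kind=kind,
                                    time_s=float(t[i]), angle_deg=ang))
    events.sort(key=lambda e: e.time_s)
    return _enforce_alternation(events)


def step_cycles(events: list[StepEvent]) -> list[StepCycle]:
    """Assemble complete cycles from an alternating event sequence.

    Each AEP followed by a PEP and a further AEP yields one cycle; partial
    cycles at either end are discarded.
    """
    for a, b in zip(events, events[1:]):
        if a.kind == b.kind:
            raise ValueError(
                f"events must alternate: consecutive {a.kind} at "
                f"{a.time_s:.3f}s and {b.time_s:.3f}s")
        if not b.time_s > a.time_s:
            raise ValueError("event times must be strictly increasing")
    cycles = []
    for a, p, na in zip(events, events[1:], events[2:]):
        if a.kind == AEP:
            cycles.append(StepCycle(
                leg_id=a.leg_id, aep_time_s=a.time_s, aep_deg=a.angle_deg,
                pep_time_s=p.time_s, pep_deg=p.angle_deg,
                next_aep_time_s=na.time_s))
    return cycles


def cycles_table(cycles: list[StepCycle]):
    """Step cycles as a DataFrame with unit-suffixed columns."""
    import pandas as pd

    return pd.DataFrame([{
        "leg_id": c.leg_id, "aep_time_s": c.aep_time_s,
        "aep_deg": c.aep_deg, "pep_time_s": c.pep_time_s,
        "pep_deg": c.pep_deg, "next_aep_time_s": c.next_aep_time_s,
        "period_s": c.period_s, "length_deg": c.length_deg,
        "stance_s": c.stance_s, "swing_s": c.swing_s} for c in cycles])
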