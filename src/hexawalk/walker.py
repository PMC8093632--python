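"""Synthetic six-leg walker with Cruse-rule coupling.

Each leg is a step-cycle oscillator alternating stance (linear angle ramp
from AEP down to PEP) and swing (cosine-eased return from PEP to AEP). Cycle
periods are drawn per cycle (intrinsic period plus Gaussian jitter). Two
coordination rules act on the scheduled transitions:

* rule 2: ``rule2_latency_s`` after a sender leg's touch-down, the receiver's
  remaining stance is shortened by ``rule2_strength`` of itself — advancing
  the receiver's lift-off toward the sender's touch-down;
* rule 1: while a sender leg is in swing, a rule-1 coupled receiver may not
  lift off; its lift-off is deferred to the sender's touch-down.

The simulated events (touch-downs and lift-offs, exact times) are returned
as ground truth alongside the rendered marker trajectories, so every stage
of the analysis pipeline can be validated against known parameter values.
"""
from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import (LEG_IDS, THORAX_OF_LEG, ConfigError, LegConfig,
                     WalkerConfig)

__all__ = ["Trial", "GroundTruth", "simulate_trial", "generate_cohort"]


@dataclass
class Trial:
    """One walking bout: 2-D arena-frame trajectories of the nine markers."""

    animal_id: str
    cohort: str
    frame_rate_hz: float
    times_s: np.ndarray
    markers: dict[str, np.ndarray]  # label -> (n_frames, 2) mm
    extra: object | None = None     # unknown CSV columns, preserved on IO

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for label, xy in self.markers.items():
            if len(xy) != n:
                raise ValueError(f"marker {label}: {len(xy)} samples for "
                                 f"{n} time stamps")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)


@dataclass
class GroundTruth:
    """Exact event times/angles and body pose underlying a simulated trial."""

    touch_down_times: dict[str, np.ndarray]
    touch_down_angles: dict[str, np.ndarray]
    lift_off_times: dict[str, np.ndarray]
    lift_off_angles: dict[str, np.ndarray]
    pose_times_s: np.ndarray
    pose_xy_mm: np.ndarray        # (n, 2) arena position of body origin (T3)
    pose_heading_deg: np.ndarray  # unwrapped

    def realized_periods(self, leg_id: str) -> np.ndarray:
        """AEP-to-AEP intervals of one leg within the trial window."""
        return np.diff(self.touch_down_times[leg_id])

    def to_json(self) -> str:
        def arr(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}
        return json.dumps({
            "touch_down_times": arr(self.touch_down_times),
            "touch_down_angles": arr(self.touch_down_angles),
            "lift_off_times": arr(self.lift_off_times),
            "lift_off_angles": arr(self.lift_off_angles),
            "pose_times_s": self.pose_times_s.tolist(),
            "pose_xy_mm": self.pose_xy_mm.tolist(),
            "pose_heading_deg": self.pose_heading_deg.tolist(),
        })


# event priorities: at equal times, touch-downs act before coupling pulses,
# which act before lift-offs (so a deferred lift-off sees the new stance)
_P_AEP, _P_RULE2, _P_PEP = 0, 1, 2


def _simulate_events(config: WalkerConfig, duration_s: float,
                     rng: np.random.Generator):
    """Run the event-driven oscillator network.

    Returns per-leg alternating event lists covering a window that starts
    before t=0 (legs begin mid-cycle) and extends past ``duration_s``.
    """
    legs = config.legs
    rule2 = [e for e in config.edges if e.rule2_strength > 0.0]
    rule2_by_sender: dict[str, list] = {}
    for e in rule2:
        rule2_by_sender.setdefault(e.sender, []).append(e)
    rule1_senders: dict[str, list[str]] = {}
    for e in config.edges:
        if e.rule1_enabled:
            rule1_senders.setdefault(e.receiver, []).append(e.sender)

    phase = {}        # leg -> "stance" | "swing"
    pep_time = {}     # scheduled lift-off while in stance
    aep_time = {}     # scheduled touch-down while in swing
    swing_dur = {}    # swing duration of the current cycle
    version = dict.fromkeys(LEG_IDS, 0)
    events: dict[str, list[tuple[float, str]]] = {leg: [] for leg in LEG_IDS}

    heap: list = []
    seq = 0

    def push(t, prio, leg, ver, payload=None):
        nonlocal seq
        heapq.heappush(heap, (t, prio, seq, leg, ver, payload))
        seq += 1

    def draw_period(leg: LegConfig) -> float:
        p = leg.period_s + rng.normal() * leg.period_jitter_sd_s
        return max(p, 0.2 * leg.period_s)

    # legs start mid-cycle at a random phase: place the virtual cycle-opening
    # touch-down in the past and replay it through the ordinary handler
    for leg_id in LEG_IDS:
        u = rng.random()
        t0 = -u * legs[leg_id].period_s
        push(t0, _P_AEP, leg_id, 0)
        phase[leg_id] = "swing"  # provisional until first AEP fires
        aep_time[leg_id] = t0

    t_stop = duration_s + 2.0 * config.max_period_s
    while heap:
        t, prio, _, leg_id, ver, payload = heapq.heappop(heap)
        if t > t_stop:
            break
        if prio == _P_RULE2:
            edge = payload
            recv = edge.receiver
            if phase[recv] == "stance" and pep_time[recv] > t:
                pep_time[recv] = t + (1.0 - edge.rule2_strength) * \
                    (pep_time[recv] - t)
                version[recv] += 1
                push(pep_time[recv], _P_PEP, recv, version[recv])
            continue
        if ver != version[leg_id]:
            continue  # stale schedule superseded by coupling
        if prio == _P_AEP:
            events[leg_id].append((t, "AEP"))
            phase[leg_id] = "stance"
            p = draw_period(legs[leg_id])
            stance = legs[leg_id].stance_fraction * p
            swing_dur[leg_id] = p - stance
            pep_time[leg_id] = t + stance
            version[leg_id] += 1
            push(pep_time[leg_id], _P_PEP, leg_id, version[leg_id])
            for edge in rule2_by_sender.get(leg_id, ()):
                push(t + edge.rule2_latency_s, _P_RULE2, leg_id, 0, edge)
        else:  # _P_PEP
            blockers = [s for s in rule1_senders.get(leg_id, ())
                        if phase[s] == "swing"]
            if blockers:
                t_release = max(aep_time[s] for s in blockers)
                pep_time[leg_id] = t_release
                version[leg_id] += 1
                push(t_release, _P_PEP, leg_id, version[leg_id])
                continue
            events[leg_id].append((t, "PEP"))
            phase[leg_id] = "swing"
            aep_time[leg_id] = t + swing_dur[leg_id]
            version[leg_id] += 1
            push(aep_time[leg_id], _P_AEP, leg_id, version[leg_id])
    return events


def _angle_timecourse(leg: LegConfig, ev: list[tuple[float, str]],
                      times: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise stance/swing angle trajectory at sample times."""
    ev_t = np.array([t for t, _ in ev])
    ev_k = np.array([k == "AEP" for _, k in ev])
    if len(ev_t) < 2 or times[0] < ev_t[0] or times[-1] >= ev_t[-1]:
        raise ValueError("event sequence does not cover the sample window")
    idx = np.searchsorted(ev_t, times, side="right") - 1
    t0, t1 = ev_t[idx], ev_t[idx + 1]
    u = (times - t0) / (t1 - t0)
    stance = ev_k[idx]  # segment starting at an AEP is stance
    span = leg.aep_deg - leg.pep_deg
    ang = np.where(stance,
                   leg.aep_deg - span * u,                       # linear
                   leg.pep_deg + span * 0.5 * (1 - np.cos(np.pi * u)))
    return ang


def _body_pose(config: WalkerConfig, times: np.ndarray):
    """Explicit-Euler integration of the commanded planar body velocity."""
    n = len(times)
    heading = np.empty(n)
    xy = np.empty((n, 2))
    heading[0] = 0.0
    xy[0] = 0.0
    dt = np.diff(times)
    for k in range(n - 1):
        h = math.radians(heading[k])
        c, s = math.cos(h), math.sin(h)
        vx, vy = config.vx_mm_s, config.vy_mm_s
        xy[k + 1, 0] = xy[k, 0] + (c * vx - s * vy) * dt[k]
        xy[k + 1, 1] = xy[k, 1] + (s * vx + c * vy) * dt[k]
        heading[k + 1] = heading[k] + config.yaw_deg_s * dt[k]
    return xy, heading


def _femur_direction_body(leg_id: str, angle_deg: np.ndarray) -> np.ndarray:
    """Unit vector of the femur chord in the body frame (x anterior, y left).

    The protraction angle is measured from the body-axis perpendicular on
    the leg's own side; +90 deg points anterior on both sides.
    """
    a = np.radians(angle_deg)
    side = 1.0 if leg_id.startswith("L") else -1.0
    return np.stack([np.sin(a), side * np.cos(a)], axis=-1)


def simulate_trial(config: WalkerConfig, duration_s: float,
                   seed: int | None = None, *, animal_id: str = "A01",
                   cohort: str | None = None) -> tuple[Trial, GroundTruth]:
    """Simulate one walking bout and return trajectories plus ground truth.

    ``duration_s`` must be at least three times the longest leg period so
    that every leg completes full cycles inside the window.
    """
    if not math.isfinite(duration_s) or duration_s < 3.0 * config.max_period_s:
        raise ValueError("duration_s must be >= 3 x the longest leg period")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    events = _simulate_events(config, duration_s, rng)

    n = int(round(duration_s * config.frame_rate_hz)) + 1
    times = np.arange(n) / config.frame_rate_hz
    angles = {}
    for leg_id in LEG_IDS:
        leg = config.legs[leg_id]
        ang = _angle_timecourse(leg, events[leg_id], times)
        if leg.angle_noise_sd_deg > 0.0:
            ang = ang + rng.normal(0.0, leg.angle_noise_sd_deg, n)
        angles[leg_id] = ang

    xy, heading = _body_pose(config, times)
    h = np.radians(heading)
    rot = np.stack([np.stack([np.cos(h), -np.sin(h)], -1),
                    np.stack([np.sin(h), np.cos(h)], -1)], -2)  # (n, 2, 2)

    markers: dict[str, np.ndarray] = {}
    for label, off in config.body.thoracic_marker_offsets.items():
        markers[label] = xy + np.einsum("nij,j->ni", rot, np.asarray(off, float))
    for leg_id in LEG_IDS:
        coxa = np.asarray(config.body.coxa_offsets[leg_id], float)
        tip = coxa + config.body.femur_length_mm * \
            _femur_direction_body(leg_id, angles[leg_id])
        markers[leg_id] = xy + np.einsum("nij,nj->ni", rot, tip)

    td_t, td_a, lo_t, lo_a = {}, {}, {}, {}
    for leg_id in LEG_IDS:
        leg = config.legs[leg_id]
        ev = [(t, k) for t, k in events[leg_id] if 0.0 <= t <= duration_s]
        td = [t for t, k in ev if k == "AEP"]
        lo = [t for t, k in ev if k == "PEP"]
        td_t[leg_id] = np.array(td)
        lo_t[leg_id] = np.array(lo)
        td_a[leg_id] = np.full(len(td), leg.aep_deg)
        lo_a[leg_id] = np.full(len(lo), leg.pep_deg)

    trial = Trial(animal_id=animal_id,
                  cohort=cohort if cohort is not None else config.lesion.site,
                  frame_rate_hz=config.frame_rate_hz, times_s=times,
                  markers=markers)
    truth = GroundTruth(touch_down_times=td_t, touch_down_angles=td_a,
                        lift_off_times=lo_t, lift_off_angles=lo_a,
                        pose_times_s=times, pose_xy_mm=xy,
                        pose_heading_deg=heading)
    return trial, truth


#: LegConfig fields that generate_cohort may perturb between animals
_ANIMAL_LEG_FIELDS = ("aep_deg", "pep_deg", "period_s")
_ANIMAL_BODY_FIELDS = ("vx_mm_s", "vy_mm_s", "yaw_deg_s")


def generate_cohort(config: WalkerConfig, n_animals: int,
                    trials_per_animal: int,
                    between_animal_sd: Mapping[str, float] | None = None,
                    seed: int = 0, *, duration_s: float = 30.0,
                    cohort: str | None = None
                    ) -> list[tuple[Trial, GroundTruth]]:
    """Simulate a cohort: per-animal parameter draws, then independent trials.

    ``between_animal_sd`` maps parameter names (``aep_deg``, ``pep_deg``,
    ``period_s`` — applied as a common additive shift to all six legs — or
    ``vx_mm_s``/``vy_mm_s``/``yaw_deg_s``) to the SD of a Normal deviate
    drawn once per animal. Deterministic under a fixed seed.
    """
    from dataclasses import replace

    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    sds = dict(between_animal_sd or {})
    for name, sd in sds.items():
        if name not in _ANIMAL_LEG_FIELDS + _ANIMAL_BODY_FIELDS:
            raise ConfigError(f"between_animal_sd: unknown field {name!r}")
        if sd < 0.0:
            raise ConfigError(f"between_animal_sd[{name!r}] must be >= 0")

    out = []
    ss = np.random.SeedSequence(seed)
    animal_seeds = ss.spawn(n_animals)
    for i, ass in enumerate(animal_seeds):
        rng = np.random.default_rng(ass)
        leg_shift = {f: rng.normal() * sds[f]
                     for f in _ANIMAL_LEG_FIELDS if f in sds}
        body_shift = {f: rng.normal() * sds[f]
                      for f in _ANIMAL_BODY_FIELDS if f in sds}
        legs = {}
        for leg_id, leg in config.legs.items():
            upd = {f: getattr(leg, f) + dv for f, dv in leg_shift.items()}
            if "period_s" in upd:
                upd["period_s"] = max(upd["period_s"], 0.2 * leg.period_s)
            legs[leg_id] = replace(leg, **upd)
        acfg = replace(config, legs=legs,
                       **{f: getattr(config, f) + dv
                          for f, dv in body_shift.items()})
        animal_id = f"A{i + 1:02d}"
        trial_seeds = rng.integers(0, 2**31 - 1, size=trials_per_animal)
        for ts in trial_seeds:
            out.append(simulate_trial(acfg, duration_s, int(ts),
                                      animal_id=animal_id, cohort=cohort))
    return out
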