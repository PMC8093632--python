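"""Walker configuration: legs, coupling topology, lesions, body plan.

The synthetic walker is a six-leg system of step-cycle oscillators coupled by
two of Cruse's behavioural coordination rules:

* rule 1 — a sender leg in swing inhibits the swing onset of its receiver;
* rule 2 — touch-down of the sender promotes swing onset in the receiver
  shortly afterwards (modelled as shortening of the receiver's remaining
  stance).

A lesion of one thoracic connective is modelled by forcing the strengths of
the coupling edges that cross the cut to zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

LEG_IDS = ("L1", "L2", "L3", "R1", "R2", "R3")
THORACIC_MARKERS = ("T1", "T2", "T3")
MARKER_LABELS = THORACIC_MARKERS + LEG_IDS
#: thoracic marker serving as the proximal end of each leg's femur chord
THORAX_OF_LEG = {"L1": "T1", "R1": "T1", "L2": "T2", "R2": "T2",
                 "L3": "T3", "R3": "T3"}

LESION_SITES = ("none", "T2_right", "T3_right")
#: edges whose neural pathway crosses the cut connective
LESION_SEVERED_EDGES = {
    "none": (),
    # cut between pro- and mesothoracic ganglia, right side: the ipsilateral
    # R2->R1 pathway and the contralateral input onto R2 are both disrupted
    "T2_right": (("R2", "R1"), ("L2", "R2")),
    # cut between meso- and metathoracic ganglia, right side
    "T3_right": (("R3", "R2"),),
}


class ConfigError(ValueError):
    """Invalid walker configuration; the message names the offending field."""


@dataclass(frozen=True)
class LegConfig:
    """Intrinsic step-cycle parameters of one leg.

    Angles follow the protraction/retraction convention: 0 deg means the
    femur is orthogonal to the body axis, positive angles point forward.
    ``aep_deg`` is the touch-down (anterior extreme) angle, ``pep_deg`` the
    lift-off (posterior extreme) angle, so step length is ``aep - pep``.
    """

    leg_id: str
    aep_deg: float
    pep_deg: float
    period_s: float
    stance_fraction: float = 0.65
    period_jitter_sd_s: float = 0.0
    angle_noise_sd_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.leg_id not in LEG_IDS:
            raise ConfigError(f"leg_id: unknown leg {self.leg_id!r}")
        if not self.aep_deg > self.pep_deg:
            raise ConfigError(
                f"{self.leg_id}: aep_deg ({self.aep_deg}) must exceed "
                f"pep_deg ({self.pep_deg})")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigError(
                f"{self.leg_id}: stance_fraction must lie in (0, 1), "
                f"got {self.stance_fraction}")
        if not self.period_s > 0.0:
            raise ConfigError(f"{self.leg_id}: period_s must be > 0")
        if self.period_jitter_sd_s < 0.0:
            raise ConfigError(f"{self.leg_id}: period_jitter_sd_s must be >= 0")
        if self.angle_noise_sd_deg < 0.0:
            raise ConfigError(f"{self.leg_id}: angle_noise_sd_deg must be >= 0")
        for name in ("aep_deg", "pep_deg", "period_s", "stance_fraction",
                     "period_jitter_sd_s", "angle_noise_sd_deg"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{self.leg_id}: {name} must be finite")


@dataclass(frozen=True)
class CouplingEdge:
    """Directed coordination influence of a sender leg on a receiver leg.

    ``rule2_strength`` is the fraction of the receiver's remaining stance
    that is cut when the sender touches down (after ``rule2_latency_s``);
    ``rule1_enabled`` defers the receiver's lift-off while the sender swings.
    """

    sender: str
    receiver: str
    rule2_strength: float = 0.0
    rule2_latency_s: float = 0.04
    rule1_enabled: bool = False

    def __post_init__(self) -> None:
        if self.sender not in LEG_IDS:
            raise ConfigError(f"sender: unknown leg {self.sender!r}")
        if self.receiver not in LEG_IDS:
            raise ConfigError(f"receiver: unknown leg {self.receiver!r}")
        if self.sender == self.receiver:
            raise ConfigError("sender and receiver must differ")
        if not 0.0 <= self.rule2_strength <= 1.0:
            raise ConfigError(
                f"rule2_strength must lie in [0, 1], got {self.rule2_strength}")
        if self.rule2_latency_s < 0.0:
            raise ConfigError("rule2_latency_s must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """Which connective (if any) is cut, and the coupling edges it severs."""

    site: str = "none"
    severed_edges: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.site not in LESION_SITES:
            raise ConfigError(
                f"site: must be one of {LESION_SITES}, got {self.site!r}")
        if self.severed_edges is None:
            object.__setattr__(self, "severed_edges",
                               LESION_SEVERED_EDGES[self.site])
        elif self.site == "none" and self.severed_edges:
            raise ConfigError("severed_edges must be empty when site='none'")


@dataclass(frozen=True)
class BodyPlan:
    """Marker geometry in the body frame (x anterior, y left, mm).

    The metathorax-root marker T3 is the body-frame origin. By default the
    femur chord of each leg is anchored at its segment's thoracic marker
    (``coxa_offsets`` equal to the segment marker positions), so that the
    protraction angle measured from the femoral-to-thoracic marker line
    equals the simulated joint angle exactly.
    """

    thoracic_marker_offsets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"T1": (25.0, 0.0), "T2": (12.0, 0.0),
                                 "T3": (0.0, 0.0)})
    coxa_offsets: Mapping[str, tuple[float, float]] | None = None
    femur_length_mm: float = 15.0

    def __post_init__(self) -> None:
        off = dict(self.thoracic_marker_offsets)
        if set(off) != set(THORACIC_MARKERS):
            raise ConfigError("thoracic_marker_offsets must name T1, T2, T3")
        if tuple(off["T3"]) != (0.0, 0.0):
            raise ConfigError("metathorax-root marker T3 must sit at the "
                              "body-frame origin")
        if not off["T1"][0] > 0.0:
            raise ConfigError("prothorax marker T1 must lie anterior to T3")
        if self.coxa_offsets is None:
            object.__setattr__(
                self, "coxa_offsets",
                {leg: tuple(off[THORAX_OF_LEG[leg]]) for leg in LEG_IDS})
        elif set(self.coxa_offsets) != set(LEG_IDS):
            raise ConfigError("coxa_offsets must name all six legs")
        if not self.femur_length_mm > 0.0:
            raise ConfigError("femur_length_mm must be > 0")


@dataclass(frozen=True)
class WalkerConfig:
    """Complete specification of one synthetic walking animal."""

    legs: Mapping[str, LegConfig]
    edges: tuple[CouplingEdge, ...]
    lesion: LesionSpec = LesionSpec()
    body: BodyPlan = BodyPlan()
    vx_mm_s: float = 30.0
    vy_mm_s: float = 0.0
    yaw_deg_s: float = 0.0
    frame_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.legs) != set(LEG_IDS):
            missing = sorted(set(LEG_IDS) - set(self.legs))
            raise ConfigError(f"legs: missing {missing}" if missing
                              else "legs: unknown leg ids present")
        for leg_id, leg in self.legs.items():
            if leg.leg_id != leg_id:
                raise ConfigError(f"legs: key {leg_id} maps to leg "
                                  f"{leg.leg_id}")
        if not self.frame_rate_hz > 0.0:
            raise ConfigError("frame_rate_hz must be > 0")
        for name in ("vx_mm_s", "vy_mm_s", "yaw_deg_s"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        # lesion forces severed edge strengths to zero
        severed = set(self.lesion.severed_edges)
        object.__setattr__(self, "edges", tuple(
            replace(e, rule2_strength=0.0, rule1_enabled=False)
            if (e.sender, e.receiver) in severed else e
            for e in self.edges))

    @property
    def max_period_s(self) -> float:
        return max(leg.period_s for leg in self.legs.values())


_DEFAULT_LEGS = {
    # AEP/PEP defaults follow the sham-cohort working ranges: front legs
    # protracted far forward with the longest steps, hind legs around the
    # perpendicular posture with the shortest ones.
    "L1": dict(aep_deg=62.0, pep_deg=10.0), "R1": dict(aep_deg=62.0, pep_deg=10.0),
    "L2": dict(aep_deg=26.0, pep_deg=-10.0), "R2": dict(aep_deg=26.0, pep_deg=-10.0),
    "L3": dict(aep_deg=0.0, pep_deg=-26.0), "R3": dict(aep_deg=0.0, pep_deg=-26.0),
}

IPSILATERAL_EDGES = (("L2", "L1"), ("L3", "L2"), ("R2", "R1"), ("R3", "R2"))
CONTRALATERAL_EDGES = (("L1", "R1"), ("L2", "R2"), ("L3", "R3"))


def default_edges(rule2_ipsi: float = 0.3, rule2_contra: float = 0.15,
                  rule2_latency_s: float = 0.04,
                  rule1_ipsi: bool = False) -> tuple[CouplingEdge, ...]:
    """Default topology: posterior->anterior ipsilateral chains plus
    left->right contralateral edges between homologous legs."""
    edges = [CouplingEdge(s, r, rule2_strength=rule2_ipsi,
                          rule2_latency_s=rule2_latency_s,
                          rule1_enabled=rule1_ipsi)
             for s, r in IPSILATERAL_EDGES]
    edges += [CouplingEdge(s, r, rule2_strength=rule2_contra,
                           rule2_latency_s=rule2_latency_s)
              for s, r in CONTRALATERAL_EDGES]
    return tuple(edges)


def default_walker_config(lesion: str = "none", *, period_s: float = 0.7,
                          period_jitter_sd_s: float = 0.05,
                          angle_noise_sd_deg: float = 1.0,
                          rule2_ipsi: float = 0.3, rule2_contra: float = 0.15,
                          seed: int = 0, **kwargs) -> WalkerConfig:
    """A plausible intact (or lesioned) walker at arena scale.

    All legs share the default 0.7 s cycle period: in steady walking the legs
    of one animal step at a common frequency, and per-leg medians in the
    source data all fall in the 0.5-1.0 s band.
    """
    legs = {leg: LegConfig(leg_id=leg, period_s=period_s,
                           period_jitter_sd_s=period_jitter_sd_s,
                           angle_noise_sd_deg=angle_noise_sd_deg,
                           **_DEFAULT_LEGS[leg])
            for leg in LEG_IDS}
    return WalkerConfig(legs=legs,
                        edges=default_edges(rule2_ipsi, rule2_contra),
                        lesion=LesionSpec(site=lesion), seed=seed, **kwargs)


def build_walker_config(raw_params: Mapping) -> WalkerConfig:
    """Build and validate a :class:`WalkerConfig` from a plain mapping.

    The mapping mirrors the YAML/JSON config layout::

        legs: {L1: {aep_deg: 62, pep_deg: 10, period_s: 0.7, ...}, ...}
        edges: [{sender: R2, receiver: R1, rule2_strength: 0.3, ...}, ...]
        lesion: {site: T2_right}
        body: {femur_length_mm: 15, ...}
        vx_mm_s: 30, vy_mm_s: 0, yaw_deg_s: 0, frame_rate_hz: 50, seed: 0

    Defaults are filled for omitted optional fields (stance_fraction 0.65,
    rule2_latency_s 0.04 s); omitted edges default to the standard topology.
    """
    raw = dict(raw_params)
    raw_legs = raw.pop("legs", None)
    if not raw_legs:
        raise ConfigError("legs: six leg configurations are required")
    legs = {}
    for leg_id in LEG_IDS:
        if leg_id not in raw_legs:
            raise ConfigError(f"legs: missing leg {leg_id}")
        legs[leg_id] = LegConfig(leg_id=leg_id, **dict(raw_legs[leg_id]))
    raw_edges = raw.pop("edges", None)
    if raw_edges is None:
        edges = default_edges()
    else:
        edges = tuple(CouplingEdge(**dict(e)) for e in raw_edges)
    lesion = raw.pop("lesion", None)
    if lesion is None:
        lesion = LesionSpec()
    elif isinstance(lesion, str):
        lesion = LesionSpec(site=lesion)
    elif not isinstance(lesion, LesionSpec):
        lesion = LesionSpec(**{k: tuple(map(tuple, v)) if k == "severed_edges"
                               else v for k, v in dict(lesion).items()})
    body = raw.pop("body", None)
    if body is None:
        body = BodyPlan()
    elif not isinstance(body, BodyPlan):
        body = BodyPlan(**dict(body))
    if "frame_rate_hz" not in raw:
        raise ConfigError("frame_rate_hz is required")
    return WalkerConfig(legs=legs, edges=edges, lesion=lesion, body=body, **raw)
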