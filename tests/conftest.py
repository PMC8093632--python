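import numpy as np
import pytest
from hypothesis import settings

from hexawalk.config import (LEG_IDS, CouplingEdge, LegConfig, LesionSpec,
                             WalkerConfig)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

_LEG_GEOM = {
    "L1": dict(aep_deg=62.0, pep_deg=10.0),
    "R1": dict(aep_deg=62.0, pep_deg=10.0),
    "L2": dict(aep_deg=26.0, pep_deg=-10.0),
    "R2": dict(aep_deg=26.0, pep_deg=-10.0),
    "L3": dict(aep_deg=0.0, pep_deg=-26.0),
    "R3": dict(aep_deg=0.0, pep_deg=-26.0),
}


def make_legs(period_s=0.7, period_jitter_sd_s=0.0, angle_noise_sd_deg=0.0):
    return {lid: LegConfig(leg_id=lid, period_s=period_s,
                           period_jitter_sd_s=period_jitter_sd_s,
                           angle_noise_sd_deg=angle_noise_sd_deg,
                           **_LEG_GEOM[lid])
            for lid in LEG_IDS}


@pytest.fixture
def uncoupled_config():
    """Deterministic six-leg walker: no coupling, no jitter, no noise."""
    return WalkerConfig(legs=make_legs(), edges=())


@pytest.fixture
def coupled_pair_config():
    """Single strongly coupled edge R2->R1 (rules 1+2) with period jitter."""
    return WalkerConfig(
        legs=make_legs(period_jitter_sd_s=0.05),
        edges=(CouplingEdge("R2", "R1", rule2_strength=0.9,
                            rule1_enabled=True),))


@pytest.fixture
def lesioned_pair_config():
    """Same walker after a right pro-to-mesothorax connective cut."""
    return WalkerConfig(
        legs=make_legs(period_jitter_sd_s=0.05),
        edges=(CouplingEdge("R2", "R1", rule2_strength=0.9,
                            rule1_enabled=True),),
        lesion=LesionSpec(site="T2_right"))
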