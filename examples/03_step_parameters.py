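"""From marker trajectories to per-leg step parameters.

Protraction/retraction angles are measured between the thoracic-to-femoral
marker line and the body-axis perpendicular (0 deg = femur orthogonal to
the body axis, positive = forward); local maxima/minima of that angle mark
touch-down (AEP) and lift-off (PEP), and consecutive AEP-PEP-AEP triples
form step cycles.
"""
import numpy as np

from hexawalk import default_walker_config, simulate_trial
from hexawalk.kinematics import body_frame, body_velocities, \
    protraction_angles
from hexawalk.stepcycle import detect_events, step_cycles

config = default_walker_config(angle_noise_sd_deg=2.0)
trial, _ = simulate_trial(config, duration_s=60.0, seed=3)

body = body_frame(trial)
vel = body_velocities(body, window_ms=60.0)
print(f"median body velocity: Tx {np.median(vel.tx_mm_s):.1f} mm/s, "
      f"Ty {np.median(vel.ty_mm_s):.1f} mm/s, "
      f"Rot {np.median(vel.rot_deg_s):.1f} deg/s")

angles = protraction_angles(trial, body)
print(f"{'leg':>4} {'cycles':>6} {'AEP':>7} {'PEP':>7} {'length':>7} "
      f"{'period':>7}")
for leg, series in angles.items():
    cycles = step_cycles(detect_events(series))
    print(f"{leg:>4} {len(cycles):>6} "
          f"{np.median([c.aep_deg for c in cycles]):>7.1f} "
          f"{np.median([c.pep_deg for c in cycles]):>7.1f} "
          f"{np.median([c.length_deg for c in cycles]):>7.1f} "
          f"{np.median([c.period_s for c in cycles]):>7.3f}")
# AEP/PEP are in degrees (angular touch-down / lift-off postures); length
# is the angular working range per step; period the AEP-to-AEP interval.
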