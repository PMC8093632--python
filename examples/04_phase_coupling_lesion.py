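"""Phase coupling of the R1-in-R2 leg pair before and after a simulated
connective lesion.

The phase of each R1 lift-off is expressed within the R2 touch-down-to-
touch-down reference cycle; the per-animal mean vector (Phi, R) summarises
direction and concentration. A right pro-to-mesothorax lesion severs the
R2->R1 and L2->R2 coupling edges: the hallmark result is a collapse of R
with little change in Phi.
"""
import warnings

import numpy as np

from hexawalk import default_walker_config, simulate_trial
from hexawalk.coordination import (mean_vector, phase_in_reference,
                                   watson_williams, kuiper_two_sample)


def cohort_pair_stats(lesion, n_animals=5, seed0=0):
    phis, rs, pooled = [], [], []
    for a in range(n_animals):
        cfg = default_walker_config(lesion=lesion, rule2_ipsi=0.9,
                                    rule2_contra=0.15)
        _, truth = simulate_trial(cfg, 60.0, seed=seed0 + a)
        res = phase_in_reference(truth.lift_off_times["R1"],
                                 truth.touch_down_times["R2"])
        mv = mean_vector(res.phases_deg)
        phis.append(mv.phi_deg)
        rs.append(mv.r)
        pooled.extend(res.phases_deg)
    return phis, rs, pooled


phi_s, r_s, pool_s = cohort_pair_stats("none", seed0=100)
phi_l, r_l, pool_l = cohort_pair_stats("T2_right", seed0=200)

print("R1-in-R2 phase coupling (5 synthetic animals per cohort):")
print(f"  sham  : Phi = {mean_vector(phi_s).phi_deg:6.1f} deg, "
      f"mean per-animal R = {np.mean(r_s):.2f}")
print(f"  lesion: Phi = {mean_vector(phi_l).phi_deg:6.1f} deg, "
      f"mean per-animal R = {np.mean(r_l):.2f}")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    f, p_ww = watson_williams(phi_s, phi_l)
v, p_k = kuiper_two_sample(pool_s, pool_l)
print(f"  Watson-Williams on per-animal means: F = {f:.2f}, p = {p_ww:.3f}")
print(f"  Kuiper on pooled samples:            V = {v:.2f}, p = {p_k:.2g}")
# Expected signature: R collapses after the lesion while the mean phase
# barely moves, so the Kuiper test (distribution shape) fires but the
# Watson-Williams test (mean direction) does not.
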