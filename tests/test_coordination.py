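import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexawalk.coordination import (PhaseSample, kuiper_two_sample,
                                   mean_vector, per_animal_phase_stats,
                                   phase_in_reference, watson_williams)


# ---------------------------------------------------------------------------
# independent oracles (plain-python, no shared code with the implementation)

def ww_oracle(groups_deg):
    """Watson-Williams F and p from the textbook formulas, written with
    scalar loops as an independent cross-check."""
    from scipy.stats import f as fdist

    ns, rs = [], []
    all_c = all_s = 0.0
    for g in groups_deg:
        c = sum(math.cos(math.radians(v)) for v in g)
        s = sum(math.sin(math.radians(v)) for v in g)
        ns.append(len(g))
        rs.append(math.hypot(c, s))
        all_c += c
        all_s += s
    n = sum(ns)
    r_all = math.hypot(all_c, all_s)
    rw = sum(rs) / n
    if rw < 0.53:
        kappa = 2 * rw + rw ** 3 + 5 * rw ** 5 / 6
    elif rw < 0.85:
        kappa = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        kappa = 1.0 / (rw ** 3 - 4 * rw ** 2 + 3 * rw)
    k = 1 + 3 / (8 * kappa)
    q = len(groups_deg)
    f = k * ((n - q) * (sum(rs) - r_all)) / ((q - 1) * (n - sum(rs)))
    f = max(f, 0.0)
    return f, float(fdist.sf(f, q - 1, n - q))


def kuiper_oracle(a_deg, b_deg):
    """Brute-force two-sample Kuiper V: scan every rotation origin, compute
    plain KS D+ and D- for the rotated samples, confirm origin invariance,
    and return the common value."""
    a = np.asarray(a_deg) % 360.0
    b = np.asarray(b_deg) % 360.0
    vs = []
    for origin in np.concatenate([a, b]):
        ar = np.sort((a - origin) % 360.0)
        br = np.sort((b - origin) % 360.0)
        grid = np.unique(np.concatenate([ar, br]))
        fa = np.searchsorted(ar, grid, side="right") / len(ar)
        fb = np.searchsorted(br, grid, side="right") / len(br)
        d_plus = max(np.max(fa - fb), 0.0)
        d_minus = max(np.max(fb - fa), 0.0)
        vs.append(d_plus + d_minus)
    assert np.ptp(vs) < 1e-9, "Kuiper V must not depend on the origin"
    return vs[0]


# ---------------------------------------------------------------------------

class TestPhaseInReference:
    def test_liftoff_at_touchdown_is_phase_zero(self):
        res = phase_in_reference([1.0], [0.0, 1.0, 2.0])
        assert res.phases_deg[0] == pytest.approx(0.0)
        assert res.n_dropped == 0

    def test_midpoint_is_180(self):
        res = phase_in_reference([0.5], [0.0, 1.0])
        assert res.phases_deg[0] == pytest.approx(180.0)

    def test_quarter_cycle_liftoffs_all_map_to_90(self):
        refs = np.array([0.0, 0.8, 2.0, 2.5])
        events = refs[:-1] + 0.25 * np.diff(refs)
        res = phase_in_reference(events, refs)
        assert np.allclose(res.phases_deg, 90.0)

    def test_events_outside_reference_are_dropped_and_counted(self):
        res = phase_in_reference([-0.5, 0.25, 7.0], [0.0, 1.0])
        assert len(res.phases_deg) == 1
        assert res.n_dropped == 2

    @settings(max_examples=30, deadline=None)
    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    def test_invariance_to_time_shift_and_scale(self, shift, scale):
        refs = np.array([0.0, 0.7, 1.5, 2.0])
        events = np.array([0.1, 0.9, 1.9])
        base = phase_in_reference(events, refs).phases_deg
        moved = phase_in_reference(events * scale + shift,
                                   refs * scale + shift).phases_deg
        assert np.allclose(base, moved, atol=1e-6)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError):
            phase_in_reference([0.5], [0.0])


class TestMeanVector:
    def test_identical_phases_give_unit_vector(self):
        s = mean_vector([60.0, 60.0, 60.0])
        assert s.phi_deg == pytest.approx(60.0)
        assert s.r == pytest.approx(1.0)

    def test_symmetric_phases_cancel(self):
        s = mean_vector([0.0, 90.0, 180.0, 270.0])
        assert s.r == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(s.phi_deg)

    def test_two_sample_closed_form(self):
        """{0, 90} -> phi 45, r = cos(45 deg), verified by vector sum."""
        s = mean_vector([0.0, 90.0])
        assert s.phi_deg == pytest.approx(45.0)
        assert s.r == pytest.approx(math.cos(math.radians(45.0)))
        brute = math.hypot((1 + 0) / 2, (0 + 1) / 2)
        assert s.r == pytest.approx(brute)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_vector([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 359.99), min_size=1, max_size=40))
    def test_r_bounded_and_unity_iff_identical(self, phases):
        s = mean_vector(phases)
        assert 0.0 <= s.r <= 1.0
        if len(set(phases)) == 1:
            assert s.r == pytest.approx(1.0)


class TestPerAnimalStats:
    def test_single_animal_matches_mean_vector(self):
        samples = [PhaseSample(("R1", "R2"), "A01", 0.0),
                   PhaseSample(("R1", "R2"), "A01", 90.0)]
        stats, counts = per_animal_phase_stats(samples)
        assert len(stats) == 1
        assert stats[0].phi_deg == pytest.approx(45.0)

    def test_identical_animals_give_identical_entries(self):
        samples = [PhaseSample(("R1", "R2"), aid, p)
                   for aid in ("A01", "A02") for p in (10.0, 40.0, 70.0)]
        stats, _ = per_animal_phase_stats(samples)
        assert stats[0].phi_deg == pytest.approx(stats[1].phi_deg)
        assert stats[0].r == pytest.approx(stats[1].r)

    def test_histogram_conserves_sample_count_in_15_deg_bins(self):
        rng = np.random.default_rng(1)
        samples = [PhaseSample(("R1", "R2"), "A01", float(p))
                   for p in rng.uniform(0, 360, 137)]
        _, counts = per_animal_phase_stats(samples)
        assert len(counts) == 24
        assert counts.sum() == 137


class TestWatsonWilliams:
    def test_identical_groups_give_f_zero_p_one(self):
        g = [10.0, 20.0, 30.0]
        f, p = watson_williams(g, list(g))
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(7)
        a = (rng.normal(0.0, 5.0, 5)) % 360.0
        b = (90.0 + rng.normal(0.0, 5.0, 5)) % 360.0
        f, p = watson_williams(a, b)
        assert p < 0.01

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        a = (20.0 + rng.normal(0, 15, 8)) % 360.0
        b = (55.0 + rng.normal(0, 15, 6)) % 360.0
        f, p = watson_williams(a, b)
        f_ref, p_ref = ww_oracle([a, b])
        assert f == pytest.approx(f_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_order_within_groups_irrelevant(self):
        a = [10.0, 50.0, 90.0, 30.0, 70.0]
        b = [100.0, 140.0, 120.0, 160.0, 180.0]
        f1, p1 = watson_williams(a, b)
        f2, p2 = watson_williams(sorted(a, reverse=True), sorted(b))
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_degenerate_ties_raise_helpfully(self):
        with pytest.raises(ValueError, match="tie"):
            watson_williams([45.0, 45.0], [45.0, 45.0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([10.0], [20.0, 30.0])

    def test_low_concentration_warns(self):
        with pytest.warns(UserWarning, match="rw"):
            watson_williams([0.0, 90.0, 180.0, 270.0],
                            [45.0, 135.0, 225.0, 315.0])


class TestKuiper:
    def test_identical_samples_v_zero_p_one(self):
        a = [10.0, 50.0, 90.0, 200.0, 300.0]
        v, p = kuiper_two_sample(a, list(a))
        assert v == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 360, 20)
        b = rng.vonmises(0.5, 2.0, 25) * 180 / np.pi % 360
        v0, _ = kuiper_two_sample(a, b)
        for shift in (33.0, 181.5, 290.0):
            v1, _ = kuiper_two_sample((a + shift) % 360, (b + shift) % 360)
            assert v1 == pytest.approx(v0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 360, 17)
        b = (rng.normal(120, 30, 23)) % 360
        v, _ = kuiper_two_sample(a, b)
        assert v == pytest.approx(kuiper_oracle(a, b), abs=1e-6)

    def test_tight_vs_uniform_highly_significant(self):
        rng = np.random.default_rng(2)
        tight = rng.normal(0.0, 5.0, 50) % 360.0
        uniform = rng.uniform(0.0, 360.0, 50)
        v, p = kuiper_two_sample(tight, uniform)
        assert p < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            kuiper_two_sample([1.0, 2.0], [3.0, 4.0, 5.0, 6.0, 7.0])
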