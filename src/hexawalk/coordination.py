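"""Circular statistics of inter-leg phase coupling.

The phase of a receiver leg's lift-off is expressed within the reference
step cycle of its sender leg, where the reference cycle is the interval
between two subsequent sender touch-downs (AEP-to-AEP). Phase 0 therefore
means the receiver lifted off exactly when the sender touched down — the
signature of Cruse's rule 2.

Per-animal statistics are mean phase vectors (direction Phi, length R);
cohort comparisons use the Watson-Williams test for equal mean directions
on the per-animal means and the two-sample Kuiper test on pooled phase
samples.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["PhaseSample", "PhaseStats", "PhaseResult", "phase_in_reference",
           "mean_vector", "per_animal_phase_stats", "watson_williams",
           "kuiper_two_sample", "HIST_BIN_DEG"]

HIST_BIN_DEG = 15.0  # rose-plot histogram resolution


@dataclass(frozen=True)
class PhaseSample:
    pair_id: tuple[str, str]  # (receiver leg, sender leg)
    animal_id: str
    phase_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_deg < 360.0:
            raise ValueError(f"phase_deg must lie in [0, 360), "
                             f"got {self.phase_deg}")


@dataclass(frozen=True)
class PhaseStats:
    """Mean phase vector: direction Phi (deg) and resultant length R."""

    animal_id: str
    phi_deg: float  # NaN when r == 0 (direction undefined)
    r: float
    n: int


class PhaseResult(NamedTuple):
    phases_deg: np.ndarray
    n_dropped: int  # lift-offs outside every reference interval


def phase_in_reference(event_times: Sequence[float],
                       reference_aeps: Sequence[float]) -> PhaseResult:
    """Phase (deg) of each event within the enclosing reference cycle.

    For an event at ``t`` with ``AEP_k <= t < AEP_{k+1}`` the phase is
    ``360 * (t - AEP_k) / (AEP_{k+1} - AEP_k)``; an event exactly on a
    touch-down gets phase 0. Events before the first or after the last
    reference touch-down are dropped and counted.
    """
    refs = np.asarray(reference_aeps, dtype=float)
    if len(refs) < 2:
        raise ValueError("need at least 2 reference touch-downs")
    if np.any(np.diff(refs) <= 0):
        raise ValueError("reference touch-downs must be strictly increasing")
    t = np.asarray(event_times, dtype=float)
    k = np.searchsorted(refs, t, side="right") - 1
    ok = (k >= 0) & (k < len(refs) - 1)
    kk = k[ok]
    phases = 360.0 * (t[ok] - refs[kk]) / (refs[kk + 1] - refs[kk])
    return PhaseResult(phases_deg=phases, n_dropped=int((~ok).sum()))


def mean_vector(phases_deg: Sequence[float],
                animal_id: str = "") -> PhaseStats:
    """Circular mean direction and resultant length of a phase sample."""
    p = np.radians(np.asarray(phases_deg, dtype=float))
    if p.size == 0:
        raise ValueError("empty phase sample")
    c, s = np.cos(p).mean(), np.sin(p).mean()
    r = float(math.hypot(c, s))
    phi = math.degrees(math.atan2(s, c)) % 360.0 if r > 1e-12 else math.nan
    return PhaseStats(animal_id=animal_id, phi_deg=phi, r=min(r, 1.0),
                      n=p.size)


def per_animal_phase_stats(samples: Sequence[PhaseSample]
                           ) -> tuple[list[PhaseStats], np.ndarray]:
    """Per-animal mean vectors plus pooled 15-deg histogram counts.

    Returns ``(stats, counts)`` where ``counts`` has 24 bins
    [0, 15), ..., [345, 360) over all retained samples.
    """
    if not samples:
        raise ValueError("need at least one phase sample")
    by_animal: dict[str, list[float]] = {}
    for s in samples:
        by_animal.setdefault(s.animal_id, []).append(s.phase_deg)
    stats = [mean_vector(ph, animal_id=aid)
             for aid, ph in sorted(by_animal.items())]
    pooled = np.array([s.phase_deg for s in samples])
    counts, _ = np.histogram(pooled, bins=int(360 / HIST_BIN_DEG),
                             range=(0.0, 360.0))
    return stats, counts


def _kappa_ml(r: float) -> float:
    """Maximum-likelihood concentration of a von Mises sample (Fisher's
    piecewise approximation)."""
    if r < 0.53:
        return 2.0 * r + r ** 3 + 5.0 * r ** 5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r ** 3 - 4.0 * r ** 2 + 3.0 * r)


def watson_williams(group_a_deg: Sequence[float],
                    group_b_deg: Sequence[float]) -> tuple[float, float]:
    """Watson-Williams one-way F test for equal mean directions.

    Uses the standard concentration-based correction factor
    ``1 + 3/(8 kappa)``. Intended for the per-animal mean phases of two
    cohorts; a warning is issued when the within-group concentration is too
    low (rw < 0.45) for the test's assumptions.
    """
    groups = [np.radians(np.asarray(g, dtype=float))
              for g in (group_a_deg, group_b_deg)]
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    n = np.array([g.size for g in groups])
    big_r = np.array([math.hypot(np.cos(g).sum(), np.sin(g).sum())
                      for g in groups])
    all_p = np.concatenate(groups)
    big_r_all = math.hypot(np.cos(all_p).sum(), np.sin(all_p).sum())
    n_tot = int(n.sum())
    rw = big_r.sum() / n_tot
    if n_tot - big_r.sum() <= 1e-12:
        raise ValueError("degenerate data: all phases identical within "
                         "groups; Watson-Williams is undefined for exact "
                         "ties — jitter the data or use an exact test")
    if rw < 0.45:
        warnings.warn("Watson-Williams assumption violated: within-group "
                      "concentration rw < 0.45; p-value unreliable",
                      stacklevel=2)
    kappa = _kappa_ml(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    q = len(groups)
    num = (big_r.sum() - big_r_all) * (n_tot - q)
    den = (n_tot - big_r.sum()) * (q - 1)
    f_stat = max(correction * num / den, 0.0)
    p = float(f_dist.sf(f_stat, q - 1, n_tot - q))
    return float(f_stat), p


def _kuiper_fpp(v: float, n_eff: float) -> float:
    """Asymptotic false-positive probability of the Kuiper statistic."""
    lam = (math.sqrt(n_eff) + 0.155 + 0.24 / math.sqrt(n_eff)) * v
    if lam < 0.4:
        return 1.0
    p = 0.0
    for k in range(1, 101):
        a = 2.0 * k * k * lam * lam
        term = 2.0 * (2.0 * a - 1.0) * math.exp(-a)
        p += term
        if abs(term) < 1e-12:
            break
    return float(min(max(p, 0.0), 1.0))


def kuiper_two_sample(samples_a_deg: Sequence[float],
                      samples_b_deg: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kuiper test on circular data.

    The statistic ``V = D+ + D-`` sums the maximal positive and negative
    excursions between the two empirical distribution functions; unlike the
    Kolmogorov-Smirnov D it is invariant to the choice of circular origin.
    The p-value uses the standard asymptotic series with the effective
    sample size ``n*m/(n+m)``.
    """
    a = np.sort(np.asarray(samples_a_deg, dtype=float) % 360.0)
    b = np.sort(np.asarray(samples_b_deg, dtype=float) % 360.0)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 values")
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    diff = fa - fb
    v = float(diff.max() - diff.min())
    n_eff = a.size * b.size / (a.size + b.size)
    return v, _kuiper_fpp(v, n_eff)
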