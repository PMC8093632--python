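"""Balanced-bootstrap cohort statistics.

Each cohort pools many step-parameter values from few (typically five)
animals with very unequal per-animal sample counts. To keep one prolific
animal from dominating the cohort estimate, resampling is *balanced*:
every animal contributes the same expected number of values to each
bootstrap replicate, while the replicate size stays at the original total
N. The cohort median and its 95%/99% percentile confidence intervals come
from 10,000 such replicates; two cohorts differ significantly when their
95% (or 99%) CIs do not overlap, and the effect size is the absolute
median difference divided by the mean of the two 95% CI widths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AnimalSamples", "CohortEstimate", "CohortComparison",
           "balanced_resample", "bootstrap_median_ci", "compare_cohorts",
           "summarize_lesion_effects"]


@dataclass(frozen=True)
class AnimalSamples:
    """All values of one scalar step parameter from one animal."""

    animal_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError(f"animal {self.animal_id}: no samples")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"animal {self.animal_id}: non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CohortEstimate:
    parameter: str
    units: str
    median: float
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    n_total: int
    n_boot: int

    def __post_init__(self) -> None:
        lo95, hi95 = self.ci95
        lo99, hi99 = self.ci99
        if not (lo95 <= self.median <= hi95):
            raise ValueError("median outside its 95% CI")
        if not (lo99 <= lo95 and hi95 <= hi99):
            raise ValueError("99% CI must contain the 95% CI")


@dataclass(frozen=True)
class CohortComparison:
    parameter: str
    estimate_a: CohortEstimate
    estimate_b: CohortEstimate
    significant_95: bool
    significant_99: bool
    effect_size: float
    direction: int  # sign of (median_b - median_a)


def balanced_resample(cohort: Sequence[AnimalSamples],
                      rng: np.random.Generator) -> np.ndarray:
    """One balanced with-replacement resample of the pooled cohort.

    With N total values over k animals, ``ceil(N/k)`` values are drawn with
    replacement from each animal; the concatenation is truncated uniformly
    at random to exactly N values, so every animal contributes equally in
    expectation regardless of its own sample size.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one animal")
    n_total = sum(a.values.size for a in cohort)
    k = len(cohort)
    m = math.ceil(n_total / k)
    draws = np.concatenate([
        a.values[rng.integers(0, a.values.size, size=m)] for a in cohort])
    if draws.size > n_total:
        keep = rng.permutation(draws.size)[:n_total]
        draws = draws[keep]
    return draws


def bootstrap_median_ci(cohort: Sequence[AnimalSamples], n_boot: int = 10000,
                        seed: int | None = None, *, parameter: str = "value",
                        units: str = "") -> CohortEstimate:
    """Balanced bootstrap of the cohort median with 95% and 99% CIs.

    The point estimate is the median of the ``n_boot`` replicate medians;
    the intervals are the 2.5/97.5 and 0.5/99.5 percentiles of the same
    replicate distribution. Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not cohort:
        raise ValueError("cohort must contain at least one animal")
    rng = np.random.default_rng(seed)
    n_total = sum(a.values.size for a in cohort)
    k = len(cohort)
    m = math.ceil(n_total / k)
    # vectorised balanced resampling: (n_boot, k, m) draws, flattened and
    # truncated uniformly at random to n_total columns per replicate
    cols = []
    for a in cohort:
        idx = rng.integers(0, a.values.size, size=(n_boot, m))
        cols.append(a.values[idx])
    pooled = np.concatenate(cols, axis=1)  # (n_boot, k*m)
    if pooled.shape[1] > n_total:
        pooled = rng.permuted(pooled, axis=1)[:, :n_total]
    medians = np.median(pooled, axis=1)
    lo95, hi95 = np.percentile(medians, [2.5, 97.5])
    lo99, hi99 = np.percentile(medians, [0.5, 99.5])
    return CohortEstimate(parameter=parameter, units=units,
                          median=float(np.median(medians)),
                          ci95=(float(lo95), float(hi95)),
                          ci99=(float(min(lo99, lo95)),
                                float(max(hi99, hi95))),
                          n_total=n_total, n_boot=n_boot)


def compare_cohorts(a: CohortEstimate, b: CohortEstimate,
                    denominator: str = "width") -> CohortComparison:
    """CI-overlap significance and CI-normalised effect size.

    Two cohorts differ at the 5% (1%) level when their 95% (99%) CIs are
    disjoint; intervals sharing an endpoint count as overlapping. The
    effect size divides |median difference| by the mean of the two 95% CI
    widths (``denominator='half_width'`` uses half-widths instead).
    """
    if a.parameter != b.parameter or a.units != b.units:
        raise ValueError(f"parameter/unit mismatch: {a.parameter} [{a.units}]"
                         f" vs {b.parameter} [{b.units}]")
    if denominator not in ("width", "half_width"):
        raise ValueError("denominator must be 'width' or 'half_width'")
    sig95 = a.ci95[1] < b.ci95[0] or b.ci95[1] < a.ci95[0]
    sig99 = a.ci99[1] < b.ci99[0] or b.ci99[1] < a.ci99[0]
    delta = b.median - a.median
    widths = (a.ci95[1] - a.ci95[0], b.ci95[1] - b.ci95[0])
    denom = (widths[0] + widths[1]) / 2.0
    if denominator == "half_width":
        denom /= 2.0
    if delta == 0.0:
        effect = 0.0
    elif denom == 0.0:
        effect = math.inf
    else:
        effect = abs(delta) / denom
    return CohortComparison(parameter=a.parameter, estimate_a=a,
                            estimate_b=b, significant_95=bool(sig95),
                            significant_99=bool(sig99), effect_size=effect,
                            direction=int(np.sign(delta)))


def _cell(comp: CohortComparison) -> str:
    if not comp.significant_95:
        return ""
    arrow = "↑" if comp.direction > 0 else "↓"
    tier = 2 if comp.significant_99 else 1
    es = f"{comp.effect_size:.2f}".rstrip("0").rstrip(".")
    return f"{arrow * tier} {es}"


def summarize_lesion_effects(comparisons: dict[tuple[str, str],
                                               CohortComparison]):
    """Effect table in the arrow/tier format of lesion summary tables.

    ``comparisons`` maps ``(parameter, leg)`` to a comparison (cohort A the
    control, cohort B the lesion). Cells read like ``"↑↑ 3.84"``: the arrow
    gives the direction of the lesion-induced change, doubled when the 99%
    CIs are disjoint (p < 0.01), single for 95% only (p < 0.05), blank when
    not significant; the number is the CI-normalised effect size.
    """
    import pandas as pd

    params, legs = [], []
    for p, leg in comparisons:
        if p not in params:
            params.append(p)
        if leg not in legs:
            legs.append(leg)
    table = pd.DataFrame("", index=params, columns=legs)
    for (p, leg), comp in comparisons.items():
        table.loc[p, leg] = _cell(comp)
    table.index.name = "parameter"
    return table
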