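"""Cohort-level statistics: exact 2x2 tests, summary-statistic t-test,
log-rank comparison and mutation bookkeeping across classified cases.

All functions are pure; nothing here touches global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import hypergeom

from .clonal import ClassificationResult, RelapseType
from .errors import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "welch_t_from_summary",
    "preserved_fraction",
    "logrank_two_groups",
    "cohort_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency table entries must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table must have a positive margin")

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the sum-of-small-probabilities rule.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is <= the observed table's probability, with a
    (1 + 1e-7) relative tolerance against floating-point ties.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    K = a + b  # row-1 total
    n = a + c  # column-1 total
    lo = max(0, n - (c + d))
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if p >= 1.0 - 1e-9:  # whole support included; absorb float accumulation error
        return 1.0
    return p


def welch_t_from_summary(
    mean1: float,
    sem1: float,
    n1: int,
    mean2: float,
    sem2: float,
    n2: int,
) -> tuple[float, float, float]:
    """Welch's unpaired t-test from group means, SEMs and sizes.

    Returns (t, df, two-sided p) with t = (mean2 - mean1)/sqrt(sem1² + sem2²)
    and Welch–Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    if sem1 <= 0 or sem2 <= 0:
        raise ValidationError("SEMs must be positive")
    v1, v2 = sem1**2, sem2**2
    tstat = (mean2 - mean1) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(tstat), df))
    return tstat, df, min(p, 1.0)


def preserved_fraction(n_preserved: int, n_total: int) -> int:
    """Percentage preserved, rounded half-away-from-zero to an integer."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not (0 <= n_preserved <= n_total):
        raise ValidationError("need 0 <= n_preserved <= n_total")
    return int(math.floor(100.0 * n_preserved / n_total + 0.5))


def logrank_two_groups(
    times1: Sequence[float],
    events1: Sequence[bool],
    times2: Sequence[float],
    events2: Sequence[bool],
) -> tuple[float, float]:
    """Standard two-group log-rank (Mantel–Cox) test; returns (chi2, p)."""
    t1 = np.asarray(times1, dtype=float)
    t2 = np.asarray(times2, dtype=float)
    e1 = np.asarray(events1, dtype=bool)
    e2 = np.asarray(events2, dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValidationError("times must be >= 0")
    if not (e1.any() or e2.any()):
        raise ValidationError("degenerate input: no events in either group")

    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    observed1 = 0.0
    expected1 = 0.0
    variance = 0.0
    for t in event_times:
        at_risk1 = float(np.sum(t1 >= t))
        at_risk2 = float(np.sum(t2 >= t))
        n_at_risk = at_risk1 + at_risk2
        d1 = float(np.sum((t1 == t) & e1))
        d2 = float(np.sum((t2 == t) & e2))
        d = d1 + d2
        if n_at_risk < 1 or d == 0:
            continue
        observed1 += d1
        expected1 += d * at_risk1 / n_at_risk
        if n_at_risk > 1:
            variance += (
                d * (at_risk1 / n_at_risk) * (at_risk2 / n_at_risk)
                * (n_at_risk - d) / (n_at_risk - 1)
            )
    if variance == 0:
        raise ValidationError("degenerate input: zero log-rank variance")
    chi2 = (observed1 - expected1) ** 2 / variance
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def cohort_summary(results: Sequence[ClassificationResult]) -> dict:
    """Aggregate classified cases into the per-type mutation bookkeeping.

    For each relapse type: case count, cohort percentage, totals of preserved /
    lost / gained variants, preserved percent, clonal/subclonal counts at both
    timepoints, and the per-case gained counts feeding the acquired-mutation
    t-test.
    """
    if not results:
        raise ValidationError("cohort_summary needs at least one classified case")
    n_cases = len(results)
    summary: dict = {"n_cases": n_cases, "types": {}}
    for rtype in RelapseType:
        group = [r for r in results if r.relapse_type is rtype]
        if not group:
            continue
        preserved = sum(len(r.preserved) for r in group)
        lost = sum(len(r.lost) for r in group)
        gained = sum(len(r.gained) for r in group)
        ini_total = preserved + lost
        summary["types"][rtype.value] = {
            "n": len(group),
            "percent_of_cohort": preserved_fraction(len(group), n_cases),
            "preserved": preserved,
            "lost": lost,
            "gained": gained,
            "preserved_percent": (
                preserved_fraction(preserved, ini_total) if ini_total else None
            ),
            "n_clonal_ini": sum(r.n_clonal_ini for r in group),
            "n_subclonal_ini": sum(r.n_subclonal_ini for r in group),
            "n_clonal_rel": sum(r.n_clonal_rel for r in group),
            "n_subclonal_rel": sum(r.n_subclonal_rel for r in group),
            "gained_per_case": [len(r.gained) for r in group],
            "hypermutators": [r.patient_id for r in group if "hypermutator" in r.flags],
        }
    return summary
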