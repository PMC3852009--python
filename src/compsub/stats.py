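"""Estimators over replicate collections: beta, pathway split, reversions, path times.

All estimators exclude censored replicates (their count is reported).
Proportions carry 95% Wilson score intervals, which stay well-behaved at
estimates near 0 or 1 — routine at the extremes of the parameter grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .model import Haplotype
from .simulate import ReplicateRecord

__all__ = [
    "ProportionEstimate",
    "ReversionSummary",
    "PathTimeComparison",
    "PathwaySummary",
    "estimate_beta",
    "estimate_p_type2",
    "reversion_summary",
    "path_time_statistic",
    "pathway_summary",
]


@dataclass
class ProportionEstimate:
    successes: int
    trials: int
    point: float
    ci_low: float
    ci_high: float
    defined: bool = True

    @classmethod
    def undefined(cls) -> "ProportionEstimate":
        return cls(0, 0, float("nan"), float("nan"), float("nan"), defined=False)

    @classmethod
    def from_counts(cls, successes: int, trials: int) -> "ProportionEstimate":
        if trials == 0:
            return cls.undefined()
        low, high = proportion_confint(successes, trials, alpha=0.05, method="wilson")
        return cls(successes, trials, successes / trials, float(low), float(high))

    @property
    def se(self) -> float:
        if not self.defined or self.trials == 0:
            return float("nan")
        p = self.point
        return math.sqrt(p * (1.0 - p) / self.trials)


def estimate_beta(records: list[ReplicateRecord]) -> ProportionEstimate:
    """Proportion of AB-departures whose next novel fixation is ab.

    Transitions are pooled across replicates and across every AB-fixed
    position in each event list (the generation-0 AB included); censored
    replicates are skipped.
    """
    num = den = 0
    for r in records:
        if r.censored:
            continue
        for prev, nxt in zip(r.events, r.events[1:]):
            if prev.haplotype == Haplotype.AB:
                den += 1
                if nxt.haplotype == Haplotype.ab:
                    num += 1
    return ProportionEstimate.from_counts(num, den)


def estimate_p_type2(records: list[ReplicateRecord]) -> ProportionEstimate:
    """Proportion of completed replicates classified Type 2."""
    n1 = sum(1 for r in records if not r.censored and r.pathway_type == 1)
    n2 = sum(1 for r in records if not r.censored and r.pathway_type == 2)
    return ProportionEstimate.from_counts(n2, n1 + n2)


@dataclass
class ReversionSummary:
    n: int
    mean: float
    variance: float
    pmf: dict[int, float]
    counts: dict[int, int]


def reversion_summary(records: list[ReplicateRecord]) -> ReversionSummary:
    """Moments and empirical pmf of the reversion counts of completed replicates."""
    rev = [r.reversion_count for r in records if not r.censored]
    if not rev:
        return ReversionSummary(0, float("nan"), float("nan"), {}, {})
    a = np.asarray(rev, dtype=float)
    counts: dict[int, int] = {}
    for k in rev:
        counts[k] = counts.get(k, 0) + 1
    pmf = {k: v / len(rev) for k, v in sorted(counts.items())}
    var = float(a.var(ddof=1)) if a.size > 1 else 0.0
    return ReversionSummary(len(rev), float(a.mean()), var, pmf, dict(sorted(counts.items())))


@dataclass
class PathTimeComparison:
    """Difference of mean final-path durations, Type 1 minus Type 2, over pooled SE."""

    z: float
    n_type1: int
    n_type2: int
    mean_type1: float
    mean_type2: float
    defined: bool = True


def path_time_statistic(records: list[ReplicateRecord], welch: bool = False) -> PathTimeComparison:
    """z = (mean1 - mean2) / sqrt(s_p^2 (1/n1 + 1/n2)) on final-path durations.

    Under equal expected durations (and approximate normality with equal
    variances) z is approximately standard normal.  ``welch=True`` replaces
    the pooled variance with the Welch standard error.  If either type group
    has fewer than 2 completed replicates, or the pooled variance vanishes
    with unequal means, the result is flagged undefined rather than raising.
    """
    g1 = np.array([r.final_path_generations for r in records
                   if not r.censored and r.pathway_type == 1], dtype=float)
    g2 = np.array([r.final_path_generations for r in records
                   if not r.censored and r.pathway_type == 2], dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        return PathTimeComparison(float("nan"), n1, n2,
                                  float(g1.mean()) if n1 else float("nan"),
                                  float(g2.mean()) if n2 else float("nan"),
                                  defined=False)
    m1, m2 = float(g1.mean()), float(g2.mean())
    v1, v2 = float(g1.var(ddof=1)), float(g2.var(ddof=1))
    if welch:
        se = math.sqrt(v1 / n1 + v2 / n2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if m1 == m2:
            return PathTimeComparison(0.0, n1, n2, m1, m2)
        return PathTimeComparison(float("nan"), n1, n2, m1, m2, defined=False)
    return PathTimeComparison((m1 - m2) / se, n1, n2, m1, m2)


@dataclass
class PathwaySummary:
    n_replicates: int
    n_type1: int
    n_type2: int
    n_censored: int
    beta_hat: ProportionEstimate
    p_type2_hat: ProportionEstimate
    reversions: ReversionSummary
    path_time: PathTimeComparison

    def to_dict(self) -> dict:
        def prop(e: ProportionEstimate) -> dict:
            return {
                "point": e.point, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "successes": e.successes, "trials": e.trials, "defined": e.defined,
            }
        return {
            "n_replicates": self.n_replicates,
            "n_type1": self.n_type1,
            "n_type2": self.n_type2,
            "n_censored": self.n_censored,
            "beta_hat": prop(self.beta_hat),
            "p_type2_hat": prop(self.p_type2_hat),
            "reversions": {
                "n": self.reversions.n,
                "mean": self.reversions.mean,
                "variance": self.reversions.variance,
                "pmf": {str(k): v for k, v in self.reversions.pmf.items()},
            },
            "path_time": {
                "z": self.path_time.z,
                "n_type1": self.path_time.n_type1,
                "n_type2": self.path_time.n_type2,
                "mean_type1": self.path_time.mean_type1,
                "mean_type2": self.path_time.mean_type2,
                "defined": self.path_time.defined,
            },
        }


def pathway_summary(records: list[ReplicateRecord]) -> PathwaySummary:
    """Bundle every estimator over one replicate collection."""
    done = [r for r in records if not r.censored]
    return PathwaySummary(
        n_replicates=len(records),
        n_type1=sum(1 for r in done if r.pathway_type == 1),
        n_type2=sum(1 for r in done if r.pathway_type == 2),
        n_censored=len(records) - len(done),
        beta_hat=estimate_beta(records),
        p_type2_hat=estimate_p_type2(records),
        reversions=reversion_summary(records),
        path_time=path_time_statistic(records),
    )
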