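"""Effect measures, analysis sets and design calculations.

The relative-risk engine is the closed-form log-RR (Woolf) estimator: the
point estimate is the ratio of arm proportions, with standard error
``sqrt(1/a - 1/n1 + 1/b - 1/n2)`` on the log scale.  For a single binary
covariate this is exactly the maximum-likelihood log-link binomial fit, so no
iterative regression is needed; it reproduces the motivating trial's printed
intervals to two decimals.  Zero event counts are reported as not calculable
("NC"), never continuity-corrected.

Analysis sets implement the trial's contamination-sensitivity logic:
intention-to-treat (all randomized, missing counted as non-abstinent),
per-protocol (started the allocated product and had any study contact),
exclusion of abstinent non-allocated-product users from numerator and
denominator, and reclassification of those participants as non-abstinent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import round_half_up

Z975 = float(stats.norm.ppf(0.975))


class AnalysisSet(str, Enum):
    ITT = "ITT"
    PER_PROTOCOL = "PER_PROTOCOL"
    EXCLUDE_ABSTINENT_SWITCHERS = "EXCLUDE_ABSTINENT_SWITCHERS"
    RECLASSIFY_SWITCHERS = "RECLASSIFY_SWITCHERS"


@dataclass
class TwoByTwoTable:
    """Events and totals per arm for one outcome under one analysis set.

    ``arm1`` is the intervention (numerator) arm, ``arm2`` the reference arm.
    """

    events_arm1: int
    total_arm1: int
    events_arm2: int
    total_arm2: int
    outcome_label: str = ""
    analysis_set: AnalysisSet = AnalysisSet.ITT
    reference_arm: str = "NRT"

    def __post_init__(self) -> None:
        if not (0 <= self.events_arm1 <= self.total_arm1):
            raise ValueError("events_arm1 outside [0, total_arm1]")
        if not (0 <= self.events_arm2 <= self.total_arm2):
            raise ValueError("events_arm2 outside [0, total_arm2]")

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.events_arm1, self.total_arm1,
                self.events_arm2, self.total_arm2)


@dataclass
class EffectEstimate:
    measure: str                 # "RR" or "OR"
    point: float
    log_se: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    not_calculable: bool = False

    def rounded(self, ndigits: int = 2) -> Tuple[float, float, float]:
        """(point, ci_low, ci_high) rounded half-up, report style."""
        return (round_half_up(self.point, ndigits),
                round_half_up(self.ci_low, ndigits),
                round_half_up(self.ci_high, ndigits))


@dataclass
class DesignCalc:
    p1: float        # reference-arm event probability
    p2: float        # intervention-arm event probability
    alpha: float
    power: float
    n_per_arm: int
    rr: float
    or_: float

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_arm


# ---------------------------------------------------------------------------
# Analysis sets
# ---------------------------------------------------------------------------

def build_table(calls: pd.DataFrame, outcome: str,
                analysis_set: AnalysisSet = AnalysisSet.ITT,
                arm1: str = "ECIG", arm2: str = "NRT") -> TwoByTwoTable:
    """Aggregate per-participant outcome calls into a 2x2 table.

    ``calls`` is the frame from :func:`pregquit.outcomes.classify_cohort`.
    Reduction outcomes have a restricted denominator (non-abstinent
    participants); other outcomes count every participant in the set, with
    missing outcomes already classified as non-events.
    """
    analysis_set = AnalysisSet(analysis_set)
    if outcome not in calls.columns:
        raise KeyError(f"unknown outcome column {outcome!r}")
    df = calls
    event = df[outcome]
    if analysis_set is AnalysisSet.PER_PROTOCOL:
        df = df[df["in_per_protocol"]]
        event = df[outcome]
    elif analysis_set is AnalysisSet.EXCLUDE_ABSTINENT_SWITCHERS:
        # drop, from numerator and denominator, participants abstinent on
        # this outcome who regularly used the non-allocated product
        keep = ~(df[outcome].fillna(False).astype(bool) & df["nonallocated_use"])
        df = df[keep]
        event = df[outcome]
    elif analysis_set is AnalysisSet.RECLASSIFY_SWITCHERS:
        # abstinent switchers stay in the denominator, reclassified as non-events
        flip = df[outcome].fillna(False).astype(bool) & df["nonallocated_use"]
        event = df[outcome].astype(object).where(~flip, False)

    counts = {}
    for arm in (arm1, arm2):
        mask = df["arm"] == arm
        ev = event[mask]
        in_denominator = ev.notna()
        counts[arm] = (int(ev[in_denominator].astype(bool).sum()),
                       int(in_denominator.sum()))
    return TwoByTwoTable(
        events_arm1=counts[arm1][0], total_arm1=counts[arm1][1],
        events_arm2=counts[arm2][0], total_arm2=counts[arm2][1],
        outcome_label=outcome, analysis_set=analysis_set, reference_arm=arm2)


# ---------------------------------------------------------------------------
# Effect measures and tests
# ---------------------------------------------------------------------------

def relative_risk(t: TwoByTwoTable) -> EffectEstimate:
    """Risk ratio with Woolf log-scale Wald interval and two-sided p value."""
    a, n1, b, n2 = t.counts
    if n1 <= 0 or n2 <= 0:
        raise ValueError("arm totals must be positive")
    if a == 0 or b == 0:
        return EffectEstimate("RR", math.nan, math.nan, math.nan, math.nan,
                              math.nan, not_calculable=True)
    point = (a / n1) / (b / n2)
    log_se = math.sqrt(max(1 / a - 1 / n1 + 1 / b - 1 / n2, 0.0))
    log_point = math.log(point)
    if log_se == 0.0:
        # both arms all-events (or all-misses): degenerate, zero-width interval
        return EffectEstimate("RR", point, 0.0, point, point,
                              1.0 if log_point == 0.0 else 0.0)
    z = abs(log_point) / log_se
    return EffectEstimate(
        measure="RR",
        point=point,
        log_se=log_se,
        ci_low=math.exp(log_point - Z975 * log_se),
        ci_high=math.exp(log_point + Z975 * log_se),
        p_two_sided=2.0 * float(stats.norm.sf(z)),
    )


def log_rr_and_se(t: TwoByTwoTable) -> Tuple[float, float]:
    """Observed log risk ratio and its Woolf standard error."""
    a, n1, b, n2 = t.counts
    if a == 0 or b == 0:
        raise ValueError("log RR undefined with a zero event count")
    return (math.log((a / n1) / (b / n2)),
            math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2))


def odds_ratio(p1: float, p2: float) -> float:
    """Odds ratio of p2 against reference p1."""
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("proportions must be in (0, 1)")
    return (p2 / (1.0 - p2)) / (p1 / (1.0 - p1))


def odds_ratio_from_table(t: TwoByTwoTable) -> float:
    a, n1, b, n2 = t.counts
    return (a * (n2 - b)) / (b * (n1 - a))


def pearson_chi2(t: TwoByTwoTable) -> Tuple[float, int, float]:
    """Uncorrected Pearson chi-square on the 2x2 table; df = 1."""
    a, n1, b, n2 = t.counts
    obs = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return statistic, 1, float(stats.chi2.sf(statistic, 1))


def bhapkar_test(paired_table: np.ndarray) -> Tuple[float, int, float]:
    """Bhapkar test of marginal homogeneity for a k x k paired table.

    Wald statistic on the first k-1 marginal differences with their
    multinomial covariance estimated under the alternative; df = k - 1.
    """
    M = np.asarray(paired_table, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("paired table must be square")
    k = M.shape[0]
    if k < 2:
        raise ValueError("paired table must be at least 2 x 2")
    n = M.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = M / n
    d = (p.sum(axis=1) - p.sum(axis=0))[: k - 1]
    S = np.empty((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                S[i, j] = (p[i, :].sum() + p[:, i].sum() - 2.0 * p[i, i]
                           - d[i] * d[i])
            else:
                S[i, j] = -(p[i, j] + p[j, i]) - d[i] * d[j]
    if np.allclose(d, 0.0):
        return 0.0, k - 1, 1.0
    statistic = float(n * d @ np.linalg.solve(S, d))
    return statistic, k - 1, float(stats.chi2.sf(statistic, k - 1))


def sample_size(p1: float, p2: float, alpha: float = 0.05,
                power: float = 0.90) -> DesignCalc:
    """Two-proportion sample size, pooled-variance normal approximation.

    Per-arm n is the ceiling of
    ``(z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2``
    with no continuity correction.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("proportions must be in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 == p2: no detectable difference")
    za = float(stats.norm.ppf(1.0 - alpha / 2.0))
    zb = float(stats.norm.ppf(power))
    pbar = (p1 + p2) / 2.0
    n = ((za * math.sqrt(2.0 * pbar * (1.0 - pbar))
          + zb * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))) ** 2
         / (p1 - p2) ** 2)
    return DesignCalc(p1=p1, p2=p2, alpha=alpha, power=power,
                      n_per_arm=math.ceil(n), rr=p2 / p1,
                      or_=odds_ratio(p1, p2))


# ---------------------------------------------------------------------------
# Contamination worked example
# ---------------------------------------------------------------------------

def contamination_example(n: int, pA: float, pB: float, fA: float, fB: float,
                          integer_bookkeeping: bool = True
                          ) -> Dict[str, Dict[str, float]]:
    """Expected quit rates per estimand in the crossover illustration.

    Failures on the allocated product switch with fractions (fA, fB) and
    succeed at the other product's true rate.  Returns quit percentages per
    arm for the true rates, intention-to-treat with crossover, exclusion of
    all switchers, and exclusion of abstinent switchers only.  With
    ``integer_bookkeeping`` the expected counts are rounded to whole
    participants, reproducing the illustration's arithmetic exactly.
    """
    from .simulate import worked_example_counts

    if integer_bookkeeping:
        cnt = worked_example_counts(n, pA, pB, fA, fB)
        qA, qB = cnt["quit_allocated"]
        swA, swB = cnt["switchers"]
        rescA, rescB = cnt["abstinent_switchers"]
        nA = nB = float(n)
    else:
        qA, qB = n * pA, n * pB
        swA, swB = fA * (n - qA), fB * (n - qB)
        rescA, rescB = pB * swA, pA * swB
        nA = nB = float(n)

    def pct(x: float, total: float) -> float:
        if total <= 0:
            return math.nan
        return 100.0 * x / total

    return {
        "true": {"A": 100.0 * pA, "B": 100.0 * pB},
        "itt": {"A": pct(qA + rescA, nA), "B": pct(qB + rescB, nB)},
        "exclude_all_switchers": {"A": pct(qA, nA - swA),
                                  "B": pct(qB, nB - swB)},
        "exclude_abstinent_switchers": {"A": pct(qA, nA - rescA),
                                        "B": pct(qB, nB - rescB)},
    }


# ---------------------------------------------------------------------------
# Cluster-robust interval for multiple births
# ---------------------------------------------------------------------------

def cluster_variance_rr(events: Sequence[int], arms: Sequence[str],
                        cluster_ids: Sequence, arm1: str = "ECIG",
                        arm2: str = "NRT", n_boot: int = 2000,
                        seed: int = 0) -> EffectEstimate:
    """Risk ratio over infant-level observations with mother-level resampling.

    The point estimate is the plain ratio of arm proportions; the interval is
    the percentile interval of the log RR over ``n_boot`` bootstrap resamples
    of whole clusters (mothers) within each arm, accommodating within-pair
    correlation for twins.  Singleton clusters recover the analytic Wald
    interval in the large-sample limit.
    """
    events = np.asarray(events, dtype=float)
    arms_arr = np.asarray(arms)
    clusters = np.asarray(cluster_ids)
    if len(events) != len(arms_arr) or len(events) != len(clusters):
        raise ValueError("events, arms, cluster_ids must align")

    per_arm = {}
    for arm in (arm1, arm2):
        mask = arms_arr == arm
        if not mask.any():
            raise ValueError(f"no observations in arm {arm!r}")
        df = pd.DataFrame({"cluster": clusters[mask], "event": events[mask]})
        g = df.groupby("cluster", sort=True)["event"].agg(["sum", "count"])
        if (g["count"] == 0).any():
            raise ValueError("cluster with zero members")
        per_arm[arm] = (g["sum"].to_numpy(), g["count"].to_numpy())

    (e1, m1), (e2, m2) = per_arm[arm1], per_arm[arm2]
    p1_hat = e1.sum() / m1.sum()
    p2_hat = e2.sum() / m2.sum()
    if p1_hat == 0 or p2_hat == 0:
        return EffectEstimate("RR", math.nan, math.nan, math.nan, math.nan,
                              math.nan, not_calculable=True)
    point = p1_hat / p2_hat

    rng = np.random.default_rng(seed)
    log_rrs = np.empty(n_boot)
    k1, k2 = len(e1), len(e2)
    # multinomial cluster weights are equivalent to resampling with replacement
    w1 = rng.multinomial(k1, np.full(k1, 1.0 / k1), size=n_boot)
    w2 = rng.multinomial(k2, np.full(k2, 1.0 / k2), size=n_boot)
    num1, den1 = w1 @ e1, w1 @ m1
    num2, den2 = w2 @ e2, w2 @ m2
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rrs = np.log((num1 / den1) / (num2 / den2))
    valid = np.isfinite(log_rrs)
    log_rrs = log_rrs[valid]
    lo, hi = np.quantile(log_rrs, [0.025, 0.975])
    se = float(log_rrs.std(ddof=1))
    z = abs(math.log(point)) / se if se > 0 else math.inf
    return EffectEstimate(
        measure="RR", point=float(point), log_se=se,
        ci_low=float(math.exp(lo)), ci_high=float(math.exp(hi)),
        p_two_sided=2.0 * float(stats.norm.sf(z)))
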