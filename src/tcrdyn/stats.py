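"""Cohort-level inference: normality gate, rank tests, BH-FDR, survival.

The inferential conventions throughout: two-sided tests, exact small-sample
null distributions where enumeration is cheap (group sizes here are 4 and
11), Benjamini-Hochberg correction applied over a registered family of
primary tests, and significance declared at p < 0.05 AND q < 0.05.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    q: Optional[float] = None
    two_sided: bool = True
    n: dict = field(default_factory=dict)
    evaluable: bool = True
    note: str = ""


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    @property
    def median(self) -> float:
        """First time at which S(t) <= 0.5; +inf if never reached."""
        below = self.survival <= 0.5
        if not below.any():
            return math.inf
        return float(self.times[np.argmax(below)])


@dataclass
class KmResult:
    curves: dict[str, SurvivalCurve]
    p: float
    test_evaluable: bool


def shapiro_gate(values: Sequence[float]) -> str:
    """Choose the test family from a Shapiro-Wilk normality check.

    Returns ``"nonparametric"`` when normality is rejected at 0.05
    (Spearman / Wilcoxon), else ``"parametric"`` (Pearson).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Shapiro-Wilk W is undefined")
    _, p = sps.shapiro(x)
    return "nonparametric" if p < 0.05 else "parametric"


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], name: str = "wilcoxon"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when there are no ties and the smaller
    group has <= 10 observations; otherwise the normal approximation with
    tie and continuity corrections (mid-ranks for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and min(x.size, y.size) <= 10
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n={"x": int(x.size), "y": int(y.size)},
    )


def _n_distinct_perms(values: np.ndarray) -> int:
    _, counts = np.unique(values, return_counts=True)
    total = math.factorial(len(values))
    for c in counts:
        total //= math.factorial(int(c))
    return total


_EXACT_PERM_CAP = 100_000


def spearman_trend(
    values: Sequence[float],
    timepoints: Sequence[float],
    name: str = "spearman",
) -> TestResult:
    """Spearman rank correlation of a metric against ordinal time points.

    rho is Pearson's correlation on mid-ranks. The p-value is exact by full
    permutation of the time-point labels when the number of distinct
    arrangements is small (n <= 10, counting multiset permutations so heavy
    time-point ties stay cheap); otherwise the t approximation.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if v.size != t.size:
        raise ValueError("values and timepoints must have equal length")
    n = v.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(v) == 0:
        raise ValueError("constant values: Spearman rho is undefined")
    if np.ptp(t) == 0:
        raise ValueError("constant timepoints: Spearman rho is undefined")
    rho = float(sps.spearmanr(v, t).statistic)

    use_exact = n <= 10 and _n_distinct_perms(t) <= _EXACT_PERM_CAP
    if use_exact:
        rv = sps.rankdata(v)
        rt = sps.rankdata(t)
        obs = abs(_pearson(rv, rt))
        hits = 0
        total = 0
        for perm in multiset_permutations(list(rt)):
            total += 1
            if abs(_pearson(rv, np.asarray(perm, dtype=float))) >= obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        # t approximation on rho with n - 2 degrees of freedom
        tt = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2 * sps.t.sf(abs(tt), df=n - 2))
    return TestResult(name=name, statistic=rho, p=min(p, 1.0), n={"n": int(n)})


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum() * (b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def response_summary(responses: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of PR / SD / PD plus the disease-control rate.

    The disease-control rate (DCR) is (PR + SD) / N. ``percent`` is exact;
    ``percent_display`` is rounded to the nearest integer for reporting.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("empty response list")
    bad = set(responses) - {"PR", "SD", "PD"}
    if bad:
        raise ValueError(f"unexpected response label(s): {sorted(bad)}")
    n = len(responses)
    rows = {}
    for label in ("PR", "SD", "PD"):
        k = responses.count(label)
        rows[label] = {"n": k, "percent": 100.0 * k / n}
    dc = responses.count("PR") + responses.count("SD")
    rows["DCR"] = {"n": dc, "percent": 100.0 * dc / n}
    df = pd.DataFrame(rows).T
    df["n"] = df["n"].astype(int)
    df["percent_display"] = df["percent"].round().astype(int)
    return df


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> KmResult:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Right censoring is encoded as ``event = 0``. When no death occurs in any
    group the log-rank statistic is undefined; the result carries a NaN p
    and ``test_evaluable=False``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size):
        raise ValueError("times, events and groups must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    labels = sorted(set(g.tolist()))
    curves: dict[str, SurvivalCurve] = {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        curves[lab] = SurvivalCurve(times=tl, survival=surv, at_risk=at_risk)
    if len(labels) != 2:
        return KmResult(curves=curves, p=math.nan, test_evaluable=False)
    if e.sum() == 0:
        return KmResult(curves=curves, p=math.nan, test_evaluable=False)
    m = g == labels[0]
    res = logrank_test(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return KmResult(curves=curves, p=float(res.p_value), test_evaluable=True)
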