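"""Cohort association statistics: rank tests, Fisher's exact, Kaplan-Meier
and the two-group log-rank test, plus expression dichotomization.

Kaplan-Meier and the log-rank test are implemented from first principles
(product-limit estimator; observed-vs-hypergeometric-expected events with
the standard variance term) so their arithmetic can be checked against
hand-tabulated oracles; established library implementations serve only as
independent cross-checks in the test suite.  Wilcoxon rank-sum and
Fisher's exact delegate to scipy with the method policy documented below.

"Low" expression is strictly below the cutoff; a value equal to the
cutoff is high.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KaplanMeier:
    """Product-limit survival curve.

    ``table`` has one row per distinct event time with columns
    time, n_risk, n_events, n_censored, survival.
    """

    table: pd.DataFrame
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function with S(0) = 1."""
        tab = self.table
        past = tab.loc[tab["time"] <= t, "survival"]
        return 1.0 if past.empty else float(past.iloc[-1])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (NaN when never reached)."""
        tab = self.table
        below = tab.loc[tab["survival"] <= 0.5, "time"]
        return float(below.iloc[0]) if not below.empty else float("nan")


def km_estimate(times, events) -> KaplanMeier:
    """Kaplan-Meier estimator; censored records leave the risk set without an event."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("at least one record required")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n_risk = len(t)
    for time in np.unique(t):
        at_t = t == time
        d = int(e[at_t].sum())
        c = int((~e[at_t]).sum())
        if d > 0:
            s *= 1.0 - d / n_risk
            rows.append({"time": time, "n_risk": n_risk, "n_events": d, "n_censored": c, "survival": s})
        n_risk -= d + c
    table = pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])
    return KaplanMeier(table=table, n=len(t))


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    observed_a: float
    expected_a: float
    variance: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Standard two-group log-rank test.

    At each distinct event time the observed events in group A are
    compared with the hypergeometric expectation d * nA / n, accumulating
    variance d (nA/n)(1 - nA/n)(n - d)/(n - 1); the statistic
    (sum O - sum E)^2 / sum V is referred to chi-squared with 1 df.  The
    statistic is symmetric under group exchange.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if (ta <= 0).any() or (tb <= 0).any():
        raise ValueError("survival times must be positive")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    if not all_e.any():
        raise ValueError("log-rank undefined with zero events")
    event_times = np.unique(all_t[all_e])
    obs = exp = var = 0.0
    for time in event_times:
        na = int((ta >= time).sum())
        nb = int((tb >= time).sum())
        n = na + nb
        if na == 0 or nb == 0:
            continue
        d = int(((all_t == time) & all_e).sum())
        da = int(((ta == time) & ea).sum())
        obs += da
        exp += d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if var == 0:
        # all events at times where one group was exhausted, or no variability
        return LogrankResult(0.0, 1.0, obs, exp, 0.0)
    stat = (obs - exp) ** 2 / var
    return LogrankResult(float(stat), float(stats.chi2.sf(stat, 1)), obs, exp, float(var))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled sample has at most 20 values and no
    ties; otherwise the normal approximation with midranks, tie correction
    and continuity correction.  Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of non-negative integers.

    Two-sided by the probability-mass rule (tables at most as probable as
    the observed one).  The odds ratio is (a d)/(b c), infinite when
    b c = 0 with a d > 0.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any():
        raise ValueError("cell counts must be non-negative")
    a, b = tab[0]
    c, d = tab[1]
    bc = b * c
    ad = a * d
    if bc == 0:
        odds = float("inf") if ad > 0 else float("nan")
    else:
        odds = ad / bc
    p = float(stats.fisher_exact(tab, alternative="two-sided").pvalue)
    return odds, p


@dataclass
class ExpressionGroups:
    """Per-case low/high labels for one gene at one cutoff."""

    gene: str
    cutoff: float
    labels: pd.Series  # values "low" | "high"


def dichotomize_expression(
    expr: pd.Series,
    cutoff_mode: str = "mean",
    fixed_cutoff: float | None = None,
    gene: str = "",
) -> ExpressionGroups:
    """Split cases into low/high expression groups.

    ``mean`` mode uses the cohort mean as cutoff; ``fixed`` mode uses
    ``fixed_cutoff``.  Low is strictly below the cutoff, so a value equal
    to the cutoff is high.
    """
    if len(expr) < 2:
        raise ValueError("dichotomization needs at least 2 cases")
    if cutoff_mode == "mean":
        cutoff = float(expr.mean())
    elif cutoff_mode == "fixed":
        if fixed_cutoff is None:
            raise ValueError("fixed cutoff_mode requires fixed_cutoff")
        cutoff = float(fixed_cutoff)
    else:
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    labels = pd.Series(np.where(expr < cutoff, "low", "high"), index=expr.index, name=gene or expr.name)
    return ExpressionGroups(gene=gene or str(expr.name), cutoff=cutoff, labels=labels)


def combined_low_group(groups_a: ExpressionGroups, groups_b: ExpressionGroups) -> pd.Series:
    """Label cases low in *both* genes as ``low/low``, the rest ``other``."""
    set_a, set_b = set(groups_a.labels.index), set(groups_b.labels.index)
    if set_a != set_b:
        only_a = sorted(set_a - set_b)[:5]
        only_b = sorted(set_b - set_a)[:5]
        raise ValueError(
            f"case sets differ between {groups_a.gene} and {groups_b.gene}: "
            f"only in first {only_a}, only in second {only_b}"
        )
    la = groups_a.labels
    lb = groups_b.labels.reindex(la.index)
    return pd.Series(np.where((la == "low") & (lb == "low"), "low/low", "other"), index=la.index)


def survival_by_group(
    times: pd.Series, events: pd.Series, labels: pd.Series, group_a: str, group_b: str
) -> dict:
    """Log-rank comparison plus per-group KM medians for a labelled cohort."""
    mask_a = labels == group_a
    mask_b = labels == group_b
    res = logrank_test(times[mask_a], events[mask_a], times[mask_b], events[mask_b])
    km_a = km_estimate(times[mask_a], events[mask_a])
    km_b = km_estimate(times[mask_b], events[mask_b])
    return {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(mask_a.sum()),
        "n_b": int(mask_b.sum()),
        "statistic": res.statistic,
        "p": res.p_value,
        "median_a": km_a.median,
        "median_b": km_b.median,
    }
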