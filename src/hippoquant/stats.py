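"""Group statistics and formatting as applied throughout the analyses.

Values are reported as mean ± SEM with group n; two-group comparisons use
the unpaired, two-tailed Student t test (pooled variance; Welch available
behind a flag) at α = 0.05; three or more groups use one-way ANOVA followed
by Tukey's post-hoc test.  Significance stars follow the 0.05 / 0.01 /
0.001 thresholds.  No multiplicity correction is applied across separate
comparisons by default (a Holm option exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import TooFewGroupsError

__all__ = ["GroupSummary", "TestResult", "stars", "ttest_unpaired",
           "anova_tukey", "summarize", "holm_correct"]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float | None
    units: str = ""

    def __str__(self) -> str:
        sem = "NA" if self.sem is None else f"{self.sem:.4g}"
        u = f" {self.units}" if self.units else ""
        return f"{self.mean:.4g} ± {sem}{u}, n = {self.n}"


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    alpha: float = 0.05
    flags: tuple = ()

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def stars(p: float) -> str:
    """Significance stars: ns, * (<0.05), ** (<0.01), *** (<0.001)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_unpaired(a, b, welch: bool = False, alpha: float = 0.05) -> TestResult:
    """Unpaired two-tailed Student t test (pooled variance by default).

    df = n_a + n_b − 2 for the pooled form.  Degenerate zero-variance
    inputs follow the documented conventions: equal means -> p = 1;
    unequal means -> p = 0, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    name = "welch_t" if welch else "student_t"
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    df = a.size + b.size - 2
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return TestResult(name, 0.0, df, 1.0, alpha)
        return TestResult(name, np.inf if a.mean() > b.mean() else -np.inf,
                          df, 0.0, alpha, flags=("zero_variance",))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(name, float(res.statistic), float(res.df),
                      float(res.pvalue), alpha)


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05
                ) -> tuple[TestResult, dict[tuple[str, str], TestResult]]:
    """One-way ANOVA with Tukey HSD pairwise post-hoc comparisons.

    ``groups`` maps label -> sample (each n ≥ 2); fewer than three groups
    raises :class:`TooFewGroupsError` (use a t test).  Identical groups
    (zero between- and within-group variance) return F = 0, p = 1.
    """
    if len(groups) < 3:
        raise TooFewGroupsError("ANOVA needs >= 3 groups; use ttest_unpaired")
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    k = len(samples)
    n_tot = sum(s.size for s in samples)
    df_between, df_within = k - 1, n_tot - k
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_between == 0.0:
        omnibus = TestResult("anova_F", 0.0, df_between, 1.0, alpha)
    elif ss_within == 0.0:
        omnibus = TestResult("anova_F", np.inf, df_between, 0.0, alpha,
                             flags=("zero_within_variance",))
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(F, df_between, df_within))
        omnibus = TestResult("anova_F", float(F), df_between, p, alpha)
    pairwise: dict[tuple[str, str], TestResult] = {}
    if ss_within > 0.0:
        hsd = sps.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                pairwise[(labels[i], labels[j])] = TestResult(
                    "tukey_hsd", float(hsd.statistic[i, j]), df_within,
                    float(hsd.pvalue[i, j]), alpha)
    else:
        for i in range(k):
            for j in range(i + 1, k):
                equal = samples[i].mean() == samples[j].mean()
                pairwise[(labels[i], labels[j])] = TestResult(
                    "tukey_hsd", 0.0 if equal else np.inf, df_within,
                    1.0 if equal else 0.0, alpha,
                    flags=() if equal else ("zero_within_variance",))
    return omnibus, pairwise


def summarize(groups: dict[str, np.ndarray], units: str = ""
              ) -> list[GroupSummary]:
    """Mean ± SEM (n) per group; a single observation has undefined SEM."""
    out = []
    for label, sample in groups.items():
        s = np.asarray(sample, dtype=float)
        if s.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else None
        out.append(GroupSummary(group=str(label), n=int(s.size),
                                mean=float(s.mean()), sem=sem, units=units))
    return out


def holm_correct(results: dict, alpha: float = 0.05) -> dict:
    """Holm step-down adjusted p-values for a family of TestResults.

    Off by default in all pipelines (comparisons mirror a per-comparison α
    convention); provided for users who want family-wise control.
    """
    items = sorted(results.items(), key=lambda kv: kv[1].p_value)
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (key, res) in enumerate(items):
        p_adj = min(1.0, (m - rank) * res.p_value)
        running = max(running, p_adj)
        adjusted[key] = TestResult(res.name + "_holm", res.statistic, res.df,
                                   running, alpha, flags=res.flags)
    return adjusted
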