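"""Univariate test battery: Kruskal-Wallis, Wilcoxon rank-sum, Spearman,
Levene, effect sizes, and the labelling/filtering conventions used throughout
the analysis.

Conventions:

* significance ladder: p < 0.05 '*', p < 0.01 '**', p < 0.001 '***', else 'ns'
* effect sizes: eta-squared for Kruskal-Wallis, eta2 = (H - k + 1) / (n - k)
  (may be negative); Cohen's d (pooled SD) for two-sample comparisons;
  Spearman's R_s for correlations.  Thresholds (>=): eta2 0.01/0.06/0.14,
  |d| 0.2/0.5/0.8, |R_s| 0.1/0.3/0.5 for small/moderate/large.
* categorical states with fewer than 5 members are reassigned to 'missing'
  and excluded from tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import MISSING

ALPHA_LADDER = (0.05, 0.01, 0.001)

EFFECT_THRESHOLDS = {
    "eta2": (0.01, 0.06, 0.14),
    "d": (0.2, 0.5, 0.8),
    "rs": (0.1, 0.3, 0.5),
}


@dataclass
class TestResult:
    test_name: str
    n: tuple[int, ...]
    statistic: float
    p: float
    effect: float
    effect_kind: str                      # 'eta2' | 'd' | 'rs' | 'none'
    p_adj: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def effect_label(self) -> str:
        if self.effect_kind == "none":
            return "none"
        return label_effect(self.effect_kind, self.effect)

    @property
    def significance_label(self) -> str:
        return label_significance(self.p_adj if self.p_adj is not None else self.p)


def label_significance(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def label_effect(kind: str, value: float) -> str:
    """Half-open threshold bins (>=) on the magnitude of the effect size."""
    small, moderate, large = EFFECT_THRESHOLDS[kind]
    v = abs(value) if kind in ("d", "rs") else value
    if v >= large:
        return "large"
    if v >= moderate:
        return "moderate"
    if v >= small:
        return "small"
    return "none"


def levene_test(*groups) -> TestResult:
    """Classic mean-centered Levene test for homoscedasticity."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    stat, p = sps.levene(*groups, center="mean")
    return TestResult("levene", tuple(len(g) for g in groups),
                      float(stat), float(p), float("nan"), "none")


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with eta-squared effect size.

    eta2 = (H - k + 1) / (n - k); negative values are possible and indicate an
    effect smaller than expected under the null.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; "
                         "use wilcoxon_two_sample for two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    h, p = sps.kruskal(*groups)
    n = sum(len(g) for g in groups)
    eta2 = (h - k + 1) / (n - k)
    return TestResult("kruskal-wallis", tuple(len(g) for g in groups),
                      float(h), float(p), float(eta2), "eta2",
                      extra={"df": k - 1})


def cohens_d(x, y) -> float:
    """Pooled-SD Cohen's d, reported as a magnitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = math.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                       / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return abs(float((x.mean() - y.mean()) / pooled))


def wilcoxon_two_sample(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test via normal
    approximation with tie-corrected variance and 0.5 continuity correction,
    plus Cohen's d on the raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical across both groups: nothing to test
        return TestResult("wilcoxon", (len(x), len(y)), 0.0, 1.0, 0.0, "d")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    d = cohens_d(x, y)
    return TestResult("wilcoxon", (len(x), len(y)),
                      float(res.statistic), float(res.pvalue), d, "d")


def pairwise_wilcoxon(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All unordered pairwise Wilcoxon tests with Benjamini-Hochberg
    adjustment over the full pair set.  Mirrors the published pairwise table
    layout: State 1, State 2, n1, n2, p, p.adj, d_c, labels."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = sorted(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        r = wilcoxon_two_sample(groups[a], groups[b])
        rows.append({"state1": a, "state2": b, "n1": len(groups[a]),
                     "n2": len(groups[b]), "p": r.p, "d_c": r.effect})
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    df["significance"] = [label_significance(p) for p in df["p_adj"]]
    df["effect_label"] = [label_effect("d", d) for d in df["d_c"]]
    return df


def benjamini_hochberg(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def spearman_corr(x, y) -> TestResult:
    """Tie-corrected Spearman rank correlation; p from the t approximation
    with n - 2 df.  NaN pairs are dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    rs, p = sps.spearmanr(x, y)
    return TestResult("spearman", (len(x),), float(rs), float(p),
                      float(rs), "rs")


def enforce_min_group_size(labels, min_n: int = 5) -> pd.Series:
    """Reassign states with fewer than ``min_n`` members to 'missing'.

    Returns the filtered label series; 'missing' is excluded from tests but
    retained for descriptive output.  Raises if fewer than 2 states survive.
    """
    s = pd.Series(labels).astype(object).copy()
    counts = s[s != MISSING].value_counts()
    small = counts[counts < min_n].index
    s[s.isin(small)] = MISSING
    surviving = s[s != MISSING].nunique()
    if surviving < 2:
        raise ValueError(
            f"fewer than 2 states with n >= {min_n} survive the group-size rule")
    return s


def groups_by_label(values, labels) -> dict[str, np.ndarray]:
    """Split values by label, dropping 'missing' and NaN values."""
    v = np.asarray(values, dtype=float)
    s = pd.Series(labels).astype(object)
    out = {}
    for lab in sorted(s.unique()):
        if lab == MISSING:
            continue
        vals = v[(s == lab).to_numpy()]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[str(lab)] = vals
    return out
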