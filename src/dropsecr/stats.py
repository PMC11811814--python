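"""Statistical comparisons and significance labeling.

Distribution comparisons use the two-sample Kolmogorov-Smirnov test,
two-group mean comparisons Welch's t-test, and more than two groups the
Welch ANOVA together with the Brown-Forsythe adjusted F test. Stars
follow the usual convention: * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatsResult:
    test: str
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    stars: str
    extra: dict | None = None


def star_label(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_distributions(a, b) -> StatsResult:
    """Two-sample Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    res = sps.ks_2samp(a, b)
    return StatsResult(
        "ks_2samp", float(res.statistic), float(res.pvalue), (a.size, b.size),
        star_label(float(res.pvalue)),
    )


def welch_ttest(a, b) -> StatsResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatsResult(
        "welch_t", float(res.statistic), float(res.pvalue), (a.size, b.size),
        star_label(float(res.pvalue)),
    )


def brown_forsythe_welch_anova(groups) -> StatsResult:
    """Welch ANOVA (primary p) plus the Brown-Forsythe adjusted F test
    for comparing the means of >2 groups with unequal variances."""
    import pingouin as pg

    groups = [np.asarray(g, dtype=float) for g in groups]
    long = pd.DataFrame(
        {
            "value": np.concatenate(groups),
            "group": np.concatenate([[i] * len(g) for i, g in enumerate(groups)]),
        }
    )
    aov = pg.welch_anova(data=long, dv="value", between="group")
    p_welch = float(aov["p_unc"].iloc[0])
    f_welch = float(aov["F"].iloc[0])

    # Brown-Forsythe F*: between-group SS over variance-weighted error
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = float(np.sum(n * (m - grand) ** 2))
    c = (1.0 - n / n.sum()) * v
    den = float(np.sum(c))
    f_star = num / den if den > 0 else np.inf
    g = c / den if den > 0 else np.full_like(c, 1.0 / len(c))
    df1 = len(groups) - 1
    df2 = 1.0 / np.sum(g**2 / (n - 1))
    p_bf = float(sps.f.sf(f_star, df1, df2)) if np.isfinite(f_star) else 0.0

    return StatsResult(
        "brown_forsythe_welch_anova", f_welch, p_welch,
        tuple(int(x) for x in n), star_label(p_welch),
        extra={"brown_forsythe_F": f_star, "brown_forsythe_p": p_bf},
    )
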