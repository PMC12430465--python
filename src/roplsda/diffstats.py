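"""Univariate comparison of marker abundances between clusters.

Cohen's d with the conventional negligible/small/medium/large bands, one-way
ANOVA with Tukey HSD post hoc adjustment (exact studentized-range CDF via
scipy), significance stars, and boxplot-ready five-number summaries. Effect
sizes are intended to be computed on logged (pre-Pareto) abundances, since
Pareto scaling distorts the per-feature standardized difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: |d| cut points for negligible / small / medium / large.
D_CUTS = (0.2, 0.5, 0.8)
#: adjusted-p cut points for ns / * / ** / *** / ****  (strict <).
STAR_CUTS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class EffectSize:
    d: float
    category: str = field(init=False)

    def __post_init__(self):
        self.category = categorize_d(self.d)


def categorize_d(d: float) -> str:
    a = abs(d)
    if a < D_CUTS[0]:
        return "negligible"
    if a < D_CUTS[1]:
        return "small"
    if a < D_CUTS[2]:
        return "medium"
    return "large"


def significance_stars(p_adj: float) -> str:
    """Star code for an adjusted p-value; boundary values are not starred."""
    if p_adj < STAR_CUTS[3]:
        return "****"
    if p_adj < STAR_CUTS[2]:
        return "***"
    if p_adj < STAR_CUTS[1]:
        return "**"
    if p_adj < STAR_CUTS[0]:
        return "*"
    return "ns"


def cohens_d(a, b) -> EffectSize:
    """Standardized mean difference (mean(a) - mean(b)) / pooled sd.

    Pooled sd uses the (n_a + n_b - 2)-denominator convention. Degenerate
    spread (pooled sd = 0) yields d = 0 for equal means and a signed infinite
    d (category "large") otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var <= 0:
        d = 0.0 if np.isclose(diff, 0.0) else float(np.sign(diff)) * np.inf
    else:
        d = float(diff / np.sqrt(pooled_var))
    return EffectSize(d)


@dataclass
class GroupComparison:
    """One feature's group-wise summary with ANOVA + Tukey adjusted p-values."""

    feature_id: str
    group_means: dict
    group_sds: dict
    anova_p: float
    tukey_p: dict          # (group_i, group_j) -> adjusted p
    effect: EffectSize | None
    stars: str


def anova_tukey(groups: dict, feature_id: str = "") -> GroupComparison:
    """One-way ANOVA over named groups with Tukey HSD pairwise adjustment.

    With exactly two groups the ANOVA p equals the pooled two-sample t-test p
    (F = t**2), and the effect size is Cohen's d of the pair (first vs second
    group in insertion order). All-zero within-group variance with equal means
    yields p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")

    within_var = sum(float(a.var(ddof=1)) for a in arrays)
    means = [float(a.mean()) for a in arrays]
    if within_var == 0 and np.allclose(means, means[0]):
        anova_p = 1.0
        tukey_p = {(names[i], names[j]): 1.0
                   for i in range(len(names)) for j in range(i + 1, len(names))}
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            anova_p = float(stats.f_oneway(*arrays).pvalue)
            res = stats.tukey_hsd(*arrays)
        tukey_p = {
            (names[i], names[j]): float(res.pvalue[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        }
    effect = cohens_d(arrays[0], arrays[1]) if len(names) == 2 else None
    return GroupComparison(
        feature_id=feature_id,
        group_means={k: float(a.mean()) for k, a in zip(names, arrays)},
        group_sds={k: float(a.std(ddof=1)) for k, a in zip(names, arrays)},
        anova_p=anova_p,
        tukey_p=tukey_p,
        effect=effect,
        stars=significance_stars(anova_p),
    )


def boxplot_summary(groups: dict) -> dict:
    """Per-group five-number summary with Tukey-fence outliers.

    Quartiles use linear interpolation (type 7); whiskers extend to the most
    extreme data point within 1.5 x IQR of the box; points beyond are listed
    as outliers.
    """
    out = {}
    for name, vals in groups.items():
        v = np.sort(np.asarray(vals, dtype=float))
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out[name] = {
            "min": float(inside.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(inside.max()),
            "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
        }
    return out
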