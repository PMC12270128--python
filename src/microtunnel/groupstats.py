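"""Group statistics: ANCOVA slope comparison with Tukey HSD, Kruskal-Wallis.

Fitted log-log CCD slopes are compared across groups (region pairs,
directions, architectures) by analysis of covariance on the pooled
``(log10 t, log10 P)`` points: the model ``y ~ x * group`` is fitted by OLS
and the interaction term tests slope homogeneity at alpha 0.05, followed by
Tukey's honest significant difference test on the per-group slope estimates.
Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
Burstiness distributions deviate strongly from normality, so they are
compared with the nonparametric Kruskal-Wallis test.

Note: treating CCD bin points as independent observations overstates the
effective sample size (adjacent bins of a cumulative curve are strongly
dependent); p-values are therefore anti-conservative and should be read as a
ranking device, not literal error rates. This mirrors the fitting domain of
the slope estimates rather than silently correcting for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "SlopeComparison",
    "BurstinessComparison",
    "ancova_slopes",
    "kruskal_wallis",
    "percent_difference",
]


@dataclass
class SlopeComparison:
    """ANCOVA slope-homogeneity result with Tukey HSD pairwise table."""

    group_slopes: dict
    interaction_f: float
    interaction_p: float
    partial_eta_squared: dict
    tukey: pd.DataFrame  # columns: group_1, group_2, slope_diff, se, q, p_adj, reject
    alpha: float
    df_resid: float


@dataclass
class BurstinessComparison:
    """Kruskal-Wallis comparison of per-group burstiness samples."""

    samples: dict
    h_statistic: float
    p_value: float


def ancova_slopes(groups, alpha: float = 0.05) -> SlopeComparison:
    """Compare regression slopes across labeled point sets.

    ``groups`` maps a label to ``(x, y)`` arrays (log10 time, log10
    probability points inside each group's fit window). Fits
    ``y ~ x * C(group)`` by OLS; the ``x:group`` interaction F tests slope
    equality; partial eta squared is reported per effect; Tukey HSD adjusts
    the pairwise slope contrasts with the studentized range distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    for label in groups:
        x, y = groups[label]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError(f"group {label!r} needs >= 3 (x, y) points")
        if np.ptp(x) == 0:
            raise ValueError(f"group {label!r} has no covariate variance (singular design)")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": str(label)}))
    df = pd.concat(frames, ignore_index=True)

    model = smf.ols("y ~ x * C(g)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    eta = {
        effect: float(row["sum_sq"] / (row["sum_sq"] + ss_resid)) if (row["sum_sq"] + ss_resid) > 0 else 0.0
        for effect, row in anova.iterrows()
        if effect != "Residual"
    }
    inter = anova.loc["x:C(g)"]
    f_stat = float(inter["F"])
    p_val = float(inter["PR(>F)"])

    labels = sorted(str(k) for k in groups)
    ref = sorted(df["g"].unique())[0]
    names = list(model.params.index)

    def slope_vec(g):
        v = np.zeros(len(names))
        v[names.index("x")] = 1.0
        term = f"x:C(g)[T.{g}]"
        if term in names:
            v[names.index(term)] = 1.0
        return v

    slopes = {g: float(slope_vec(g) @ model.params.values) for g in labels}
    cov = model.cov_params().values
    dfr = float(model.df_resid)
    k = len(labels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = slope_vec(labels[i]) - slope_vec(labels[j])
            diff = float(c @ model.params.values)
            se = float(np.sqrt(c @ cov @ c))
            if se > 0 and dfr > 0:
                q = abs(diff) / se * np.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q, k, dfr))
            else:
                q, p_adj = float("inf"), 0.0
            rows.append({"group_1": labels[i], "group_2": labels[j],
                         "slope_diff": diff, "se": se, "q": q,
                         "p_adj": p_adj, "reject": p_adj < alpha})
    tukey = pd.DataFrame(rows)
    return SlopeComparison(group_slopes=slopes, interaction_f=f_stat,
                           interaction_p=p_val, partial_eta_squared=eta,
                           tukey=tukey, alpha=alpha, df_resid=dfr)


def kruskal_wallis(samples) -> BurstinessComparison:
    """Rank-based Kruskal-Wallis H with tie correction.

    ``samples`` maps a label to a 1-D array of values. Identical constant
    samples yield H = 0, p = 1 (no rank variance to explain).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    arrays = [np.asarray(samples[k], dtype=float) for k in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty sample group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return BurstinessComparison(samples=dict(samples), h_statistic=0.0, p_value=1.0)
    h, p = stats.kruskal(*arrays)
    return BurstinessComparison(samples=dict(samples), h_statistic=float(h), p_value=float(p))


def percent_difference(m_ref: float, m_other: float) -> float:
    """Percent slope-magnitude change relative to the reference group.

    ``100 * (|m_other| - |m_ref|) / |m_ref|``: positive means the other group's
    CCD is steeper (faster spiking/bursting) than the reference.
    """
    if m_ref == 0:
        raise ValueError("reference slope must be non-zero")
    return 100.0 * (abs(m_other) - abs(m_ref)) / abs(m_ref)
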