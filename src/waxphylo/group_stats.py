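"""Group summaries, one-way ANOVA and post hoc pairwise comparisons.

Used to compare integrated fractionation entries across lineages, growth
forms and photosynthetic pathways.  The post hoc default is Tukey's HSD
(Tukey-Kramer for unbalanced groups, via scipy's studentized-range
implementation); unadjusted and Bonferroni pairwise t-tests are available
as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TUKEY = "tukey"
UNADJUSTED = "unadjusted"
BONFERRONI = "bonferroni"


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    labels = np.asarray(pd.Series(labels).astype(object).to_numpy())
    keep = np.isfinite(values) & pd.notna(labels)
    return values[keep], labels[keep]


def group_summary(values, labels) -> pd.DataFrame:
    """Per-group mean, sample sd (n-1 denominator) and count.

    Groups of size 1 report sd as NaN with ``sd_defined = False``.
    """
    values, labels = _clean(values, labels)
    if len(values) == 0:
        raise ValueError("no observations")
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        rows.append((g, float(np.mean(v)), sd, len(v), len(v) > 1))
    return pd.DataFrame(rows, columns=["group", "mean", "sd", "n", "sd_defined"])


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float
    groups: tuple

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05


def one_way_anova(values, labels) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sums-of-squares decomposition."""
    values, labels = _clean(values, labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    if n <= len(groups):
        raise ValueError("need more observations than groups")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += float(np.sum((v - v.mean()) ** 2))
    df1 = len(groups) - 1
    df2 = n - len(groups)
    if ss_within == 0.0:
        return AnovaResult(np.inf, df1, df2, 0.0, ss_between, 0.0,
                           ss_total, tuple(groups))
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p, float(ss_between),
                       float(ss_within), ss_total, tuple(groups))


def posthoc_pairwise(values, labels, method: str = TUKEY,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Symmetric pairwise p-value matrix between group means.

    Default Tukey HSD with the Tukey-Kramer unequal-n adjustment; groups of
    size 1 are excluded (no within-group variance).  The returned frame has
    groups as both index and columns, NaN on the diagonal; use
    ``significance_matrix`` to flag pairs at the given alpha.
    """
    values, labels = _clean(values, labels)
    groups = [g for g in pd.unique(labels) if np.sum(labels == g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    samples = [values[labels == g] for g in groups]
    k = len(groups)
    P = np.full((k, k), np.nan)
    if method == TUKEY:
        res = stats.tukey_hsd(*samples)
        P = res.pvalue.copy()
        np.fill_diagonal(P, np.nan)
    elif method in (UNADJUSTED, BONFERRONI):
        # pooled within-group variance, as in the ANOVA
        dfw = sum(len(s) - 1 for s in samples)
        msw = sum(np.sum((s - s.mean()) ** 2) for s in samples) / dfw
        m = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(msw * (1 / len(samples[i]) + 1 / len(samples[j])))
                t = (samples[i].mean() - samples[j].mean()) / se
                p = 2 * float(stats.t.sf(abs(t), dfw))
                if method == BONFERRONI:
                    p = min(1.0, p * m)
                P[i, j] = P[j, i] = p
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    P = np.minimum(P, 1.0)
    return pd.DataFrame(P, index=groups, columns=groups)


def significance_matrix(p_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean frame marking pairs whose means differ at the given level."""
    return p_matrix < alpha


def pathway_contrast(
    values, pathway_labels, lineage_labels,
    reference: str = "C3",
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-lineage mean difference of each pathway vs the reference pathway.

    Bootstrap percentile CIs (independent resampling within each cell);
    cells with a single member report an undefined CI.  Lineage/pathway
    cells with no members are skipped.
    """
    values = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    pathway = np.asarray(pd.Series(pathway_labels).astype(object).to_numpy())
    lineage = np.asarray(pd.Series(lineage_labels).astype(object).to_numpy())
    keep = np.isfinite(values)
    values, pathway, lineage = values[keep], pathway[keep], lineage[keep]
    rng = np.random.default_rng(seed)
    rows = []
    for lin in pd.unique(lineage):
        in_lin = lineage == lin
        ref = values[in_lin & (pathway == reference)]
        if len(ref) == 0:
            continue
        for pw in pd.unique(pathway[in_lin]):
            if pw == reference:
                continue
            alt = values[in_lin & (pathway == pw)]
            if len(alt) == 0:
                continue
            diff = float(alt.mean() - ref.mean())
            if len(alt) >= 2 and len(ref) >= 2:
                boots = np.empty(n_boot)
                for b in range(n_boot):
                    boots[b] = (
                        rng.choice(alt, size=len(alt)).mean()
                        - rng.choice(ref, size=len(ref)).mean()
                    )
                lo, hi = np.percentile(boots, [2.5, 97.5])
                ci_defined = True
            else:
                lo = hi = np.nan
                ci_defined = False
            rows.append((lin, pw, reference, diff, float(lo), float(hi),
                         len(alt), len(ref), ci_defined))
    return pd.DataFrame(
        rows,
        columns=["lineage", "pathway", "reference", "mean_diff",
                 "ci_lo", "ci_hi", "n_pathway", "n_reference", "ci_defined"],
    )
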