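"""Multi-compound integration of fractionation values via VAST scaling.

Raw per-compound fractionation series are correlated but offset from one
another (different compound classes and chain lengths carry systematic
isotopic offsets), so they cannot simply be averaged.  The integration
procedure is:

1. center each compound column on its mean;
2. autoscale (divide by the column standard deviation) and weight each
   compound by its variable-stability (VAST) weight — the mean over
   lineage classes of |class mean| / class standard deviation — so
   compounds that discriminate classes consistently count more;
3. divide every cell by one global normalizer (mean absolute value);
4. average the scaled values within each compound class to give one
   integrated acid entry and one alkane entry per plant (eps*).

Missing measurements are ignored cell-wise throughout, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import ACIDS, ALKANES, CompoundSpec
from .fractionation import FractionationMatrix

VAST_ABS = "abs_mean_over_sd"
VAST_SIGNED = "mean_over_sd"
NORM_MEAN_ABS = "mean_abs"
NORM_MEAN_RAW = "mean_raw"
NORM_NONE = "none"


@dataclass
class ScaledFractionationMatrix:
    """Centered, VAST-scaled species x compound matrix (eps*, unitless)."""

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    weights: pd.Series
    normalizer: float
    class_labels: pd.Series
    vast_mode: str
    grand_norm: str

    @property
    def n_classes(self) -> int:
        return int(self.class_labels.nunique())


def center_columns(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract the per-compound mean (over non-missing species)."""
    counts = values.notna().sum(axis=0)
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"compound(s) with no data: {', '.join(empty.index)}")
    means = values.mean(axis=0, skipna=True)
    return values - means, means


def vast_weights(
    centered: pd.DataFrame,
    classes: pd.Series,
    mode: str = VAST_ABS,
) -> pd.Series:
    """Per-compound VAST weight from class-wise stability.

    For compound c and class j, the stability is s_j = |xbar_j| / sigma_j
    (signed mean if ``mode='mean_over_sd'``) computed on the centered
    values; the weight is the mean of s_j over the classes.  The ratio is
    invariant to a global rescaling of the column, so it is identical
    whether computed before or after autoscaling.
    """
    if mode not in (VAST_ABS, VAST_SIGNED):
        raise ValueError(f"unknown vast mode {mode!r}")
    classes = classes.reindex(centered.index)
    if classes.isna().any():
        raise ValueError("every species needs a class label for VAST scaling")
    weights = {}
    for col in centered.columns:
        x = centered[col]
        stabilities = []
        for cls, grp in x.groupby(classes):
            obs = grp.dropna()
            if len(obs) < 2:
                raise ValueError(
                    f"class {cls!r} has {len(obs)} observation(s) for "
                    f"{col}; need at least 2"
                )
            sd = obs.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"class {cls!r} has zero variance for {col}; "
                    "stability undefined"
                )
            m = obs.mean()
            stabilities.append((abs(m) if mode == VAST_ABS else m) / sd)
        weights[col] = float(np.mean(stabilities))
    w = pd.Series(weights)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite VAST weight")
    return w


def grand_normalize(values: pd.DataFrame, norm: str = NORM_MEAN_ABS) -> tuple[pd.DataFrame, float]:
    """Divide every cell by one global normalizer.

    ``mean_abs`` (default) uses the mean absolute value of all non-missing
    cells; ``mean_raw`` uses the raw global mean (meaningful only for
    uncentered data); ``none`` is the identity.
    """
    flat = values.to_numpy().ravel()
    flat = flat[~np.isnan(flat)]
    if flat.size == 0:
        raise ValueError("empty matrix")
    if norm == NORM_NONE:
        return values, 1.0
    if norm == NORM_MEAN_ABS:
        normalizer = float(np.mean(np.abs(flat)))
    elif norm == NORM_MEAN_RAW:
        normalizer = float(np.mean(flat))
    else:
        raise ValueError(f"unknown grand_norm {norm!r}")
    if normalizer == 0:
        raise ValueError("zero grand normalizer")
    return values / normalizer, normalizer


def scale_matrix(
    matrix: FractionationMatrix,
    classes: pd.Series,
    vast_mode: str = VAST_ABS,
    grand_norm: str = NORM_MEAN_ABS,
) -> ScaledFractionationMatrix:
    """Full centering + autoscaling + VAST weighting + grand normalization."""
    centered, means = center_columns(matrix.values)
    sds = centered.std(axis=0, ddof=1, skipna=True)
    if (sds == 0).any():
        bad = ", ".join(sds[sds == 0].index)
        raise ValueError(f"constant compound column(s): {bad}")
    weights = vast_weights(centered, classes, mode=vast_mode)
    scaled = (centered / sds) * weights
    scaled, normalizer = grand_normalize(scaled, norm=grand_norm)
    return ScaledFractionationMatrix(
        values=scaled,
        column_means=means,
        column_sds=sds,
        weights=weights,
        normalizer=normalizer,
        class_labels=classes.reindex(matrix.values.index),
        vast_mode=vast_mode,
        grand_norm=grand_norm,
    )


def integrate_entries(
    scaled: ScaledFractionationMatrix | pd.DataFrame,
    acids: tuple[CompoundSpec, ...] = ACIDS,
    alkanes: tuple[CompoundSpec, ...] = ALKANES,
) -> pd.DataFrame:
    """Per-plant integrated entries: mean of available scaled acids / alkanes.

    Returns a DataFrame with columns ``eps_star_acid``, ``eps_star_alkane``,
    ``n_acid``, ``n_alkane``; an entry is NaN when no compound of that class
    was measured for the plant.
    """
    values = scaled.values if isinstance(scaled, ScaledFractionationMatrix) else scaled
    acid_cols = [c.id for c in acids if c.id in values.columns]
    alk_cols = [c.id for c in alkanes if c.id in values.columns]
    out = pd.DataFrame(index=values.index)
    out["eps_star_acid"] = values[acid_cols].mean(axis=1, skipna=True)
    out["eps_star_alkane"] = values[alk_cols].mean(axis=1, skipna=True)
    out["n_acid"] = values[acid_cols].notna().sum(axis=1)
    out["n_alkane"] = values[alk_cols].notna().sum(axis=1)
    return out


def compound_correlations(matrix: FractionationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise OLS fit and Pearson r between compound columns.

    Uses pairwise-complete observations; pairs with fewer than 3 shared
    points are flagged not-estimable (NaN statistics, estimable=False).
    """
    values = matrix.values if isinstance(matrix, FractionationMatrix) else matrix
    cols = list(values.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = values[[a, b]].dropna()
            n = len(pair)
            if n < 3:
                rows.append((a, b, n, np.nan, np.nan, np.nan, np.nan, False))
                continue
            res = stats.linregress(pair[a], pair[b])
            rows.append((a, b, n, res.rvalue, res.rvalue ** 2,
                         res.slope, res.intercept, True))
    return pd.DataFrame(
        rows,
        columns=["x", "y", "n", "r", "r2", "slope", "intercept", "estimable"],
    )


def pca_check(values: pd.DataFrame) -> dict:
    """PCA of the complete-case species x compound submatrix.

    Eigen-decomposition of the covariance of column-centered data.  Used to
    confirm that acids and alkanes separate on the second component, the
    rationale for averaging the two compound classes separately.
    """
    complete = values.dropna(axis=0)
    if len(complete) < 3:
        raise ValueError("need >= 3 complete-case species for PCA")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals.max(), 0) * 1e-12
    evals, evecs = evals[keep], evecs[:, keep]
    scores = X @ evecs
    return {
        "explained_variance": evals,
        "explained_variance_ratio": evals / evals.sum(),
        "loadings": pd.DataFrame(
            evecs, index=complete.columns,
            columns=[f"PC{i+1}" for i in range(evecs.shape[1])],
        ),
        "scores": pd.DataFrame(
            scores, index=complete.index,
            columns=[f"PC{i+1}" for i in range(evecs.shape[1])],
        ),
    }
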