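"""Statistical comparison of parasite and host phenotype distributions.

Covers the mimicry-fidelity toolkit: Wilcoxon rank-sum comparisons of
single traits, one-way repeatability (ICC) of traits within females,
collinearity screening, jack-knifed linear discriminant analysis with
Mahalanobis outlier filtering, Fisher's exact test on the resulting
confusion matrix, and a convenience k-means morph clustering.

The discriminant analysis is the core fidelity measure: if parasite eggs
mimic host eggs perfectly, a discriminant classifier can do no better than
chance at assigning eggs to species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-exported for users)

__all__ = [
    "RepeatabilityResult",
    "DiscriminantResult",
    "rank_sum_test",
    "icc",
    "collinearity_screen",
    "lda_jackknife",
    "confusion_exact_test",
    "morph_cluster",
]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration for small samples (n1 * n2 <= 400, no ties) and
    the tie-corrected normal approximation otherwise.  Returns (U, p).
    Degenerate all-tied data give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum test is degenerate", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RepeatabilityResult:
    """One-way ANOVA intraclass correlation of a trait within groups."""

    icc: float
    f_statistic: float
    p_value: float
    n_groups: int
    mean_group_size: float


def icc(values, groups) -> RepeatabilityResult:
    """One-way repeatability ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW).

    ``k0`` is the usual unbalanced-design effective group size
    (N - sum n_i^2 / N) / (G - 1).  The F test compares between- to
    within-group mean squares.
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float), "g": np.asarray(groups)}).dropna()
    counts = df.groupby("g")["v"].count()
    g = counts.size
    n = len(df)
    if g < 2:
        raise ValueError("repeatability needs at least 2 groups")
    if (counts < 2).all():
        raise ValueError("repeatability needs at least one group with 2+ members")
    grand = df["v"].mean()
    means = df.groupby("g")["v"].mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((df["v"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k0 = (n - float((counts**2).sum()) / n) / (g - 1)
    if msw == 0:
        icc_val, f, p = 1.0, float("inf"), 0.0
    else:
        icc_val = (msb - msw) / (msb + (k0 - 1) * msw)
        f = msb / msw
        p = float(stats.f.sf(f, g - 1, n - g))
    return RepeatabilityResult(
        icc=float(icc_val), f_statistic=float(f), p_value=p,
        n_groups=g, mean_group_size=n / g,
    )


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Greedy collinearity filter on trait columns.

    While any pair of retained traits has |r| >= threshold, drop the trait
    with the highest mean |r| against the others; ties broken
    alphabetically.  Returns the retained column names in original order.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("collinearity screen needs at least 2 traits")
    corr = table.corr().abs()
    retained = list(cols)
    while len(retained) > 1:
        sub = corr.loc[retained, retained].copy()
        np.fill_diagonal(sub.values, 0.0)
        if (sub.values < threshold).all():
            break
        mean_r = sub.mean(axis=1)
        worst = sorted(retained, key=lambda c: (-mean_r[c], c))[0]
        retained.remove(worst)
    return [c for c in cols if c in retained]


@dataclass
class DiscriminantResult:
    """Jack-knifed discriminant analysis output."""

    classes: tuple
    confusion: np.ndarray  # rows true class, cols assigned class
    correct_rates: dict
    coefficients: np.ndarray
    outliers_removed: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


def _lda_discriminant(x: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Class means, pooled covariance and linear discriminant pieces."""
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    n, p = x.shape
    pooled = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = x[y == c] - mu
        pooled += d.T @ d
    pooled /= n - len(classes)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled covariance in LDA") from err
    return means, inv


def _lda_assign(x: np.ndarray, means: np.ndarray, inv: np.ndarray) -> np.ndarray:
    # Equal priors: assign to the class with smallest Mahalanobis distance.
    d2 = np.stack([np.einsum("ij,jk,ik->i", x - mu, inv, x - mu) for mu in means], axis=1)
    return np.argmin(d2, axis=1)


def mahalanobis_outliers(x: np.ndarray, y: np.ndarray, quantile: float = 0.999) -> np.ndarray:
    """Flag observations far from their own class centroid.

    Squared Mahalanobis distances to the class mean (pooled covariance) are
    compared with a chi-square quantile at the feature dimensionality.
    Returns a boolean outlier flag per observation.
    """
    classes = np.unique(y)
    means, inv = _lda_discriminant(x, y, classes)
    cut = stats.chi2.ppf(quantile, df=x.shape[1])
    flags = np.zeros(x.shape[0], dtype=bool)
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        d = x[idx] - means[ci]
        d2 = np.einsum("ij,jk,ik->i", d, inv, d)
        flags[idx] = d2 > cut
    return flags


def lda_jackknife(
    features: pd.DataFrame | np.ndarray,
    labels,
    outlier_filter: bool = False,
    outlier_quantile: float = 0.999,
) -> DiscriminantResult:
    """Leave-one-out linear discriminant analysis with equal priors.

    Each observation is assigned by a discriminant fitted without it
    (jack-knifed prediction), removing the optimism of resubstitution and
    the influence of unequal class sizes.  Optionally pre-filters
    Mahalanobis outliers; removals are recorded in the result.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("discriminant analysis needs at least 2 classes")
    if x.shape[0] <= x.shape[1] + 2:
        raise ValueError("too few observations for the feature count")
    removed: list[int] = []
    if outlier_filter:
        flags = mahalanobis_outliers(x, y, quantile=outlier_quantile)
        removed = list(np.flatnonzero(flags))
        x, y = x[~flags], y[~flags]
    n = x.shape[0]
    assigned = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        means, inv = _lda_discriminant(x[keep], y[keep], classes)
        assigned[i] = _lda_assign(x[i : i + 1], means, inv)[0]
    true_idx = np.searchsorted(classes, y)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    np.add.at(confusion, (true_idx, assigned), 1)
    rates = {
        c: confusion[ci, ci] / confusion[ci].sum() if confusion[ci].sum() else float("nan")
        for ci, c in enumerate(classes)
    }
    means, inv = _lda_discriminant(x, y, classes)
    coef = inv @ (means[1] - means[0]) if classes.size == 2 else inv @ means.T
    return DiscriminantResult(
        classes=tuple(classes),
        confusion=confusion,
        correct_rates=rates,
        coefficients=np.asarray(coef),
        outliers_removed=removed,
    )


def confusion_exact_test(confusion: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 confusion matrix.

    Returns the conditional-MLE odds ratio and the two-sided hypergeometric
    p value.  A table with an empty margin is uninformative: p = 1 and the
    odds ratio is NaN.
    """
    t = np.asarray(confusion)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("confusion must be a non-negative integer 2x2 table")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    or_cond = _odds_ratio(t, kind="conditional").statistic
    return float(or_cond), float(res.pvalue)


def morph_cluster(traits: pd.DataFrame | np.ndarray, k: int = 4, seed: int = 0) -> np.ndarray:
    """Convenience k-means morph labelling on z-scored traits.

    A rough, seeded grouping of eggs into k phenotype clusters; useful for
    exploratory morph assignment, with no claim of matching any particular
    published clustering protocol.
    """
    x = np.asarray(traits, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of observations")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(z)
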