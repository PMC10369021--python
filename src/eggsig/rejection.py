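"""Binomial GLMs of host egg rejection.

Two model families are compared.  Model 1 ("traits") asks whether any
individual pattern trait difference between the host egg and the foreign
egg predicts rejection; model 2 ("distance") uses a single predictor, the
multidimensional pattern distance, allowing a mismatch in *any* trait to
drive rejection.  Variants append the chromatic colour contrast (in JNDs)
or all two-way interactions.  Model comparison uses AIC and likelihood
ratio tests; explanatory power is summarized by an adjusted
deviance-explained R-squared and partitioned between predictors by
hierarchical partitioning (independent contributions, %I).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from eggsig import vision
from eggsig.pattern import DistanceStandardization, pattern_distance

__all__ = [
    "SeparationError",
    "RejectionModelFit",
    "MODEL_NAMES",
    "build_design",
    "fit_rejection_glm",
    "compare_models",
    "partition_variance",
    "vif",
]

MODEL_NAMES = ("traits", "distance", "plus_colour", "interactions")

#: Individual trait-difference predictors of model 1.
TRAIT_DIFF_COLUMNS = ("pattern_coverage", "pc_energy", "n_features")


class SeparationError(RuntimeError):
    """Raised when the outcome is perfectly separated by the predictors."""


def _chromatic_jnd_column(experiments: pd.DataFrame, phenotypes: pd.DataFrame) -> np.ndarray:
    receptors = vision.violet_sensitive_tetrachromat()
    out = np.empty(len(experiments))
    for i, (_, row) in enumerate(experiments.iterrows()):
        a = phenotypes.loc[row["host_egg_id"]]
        b = phenotypes.loc[row["experimental_egg_id"]]
        ca = vision.ConeCatches(a["catch_uv"], a["catch_sw"], a["catch_mw"], a["catch_lw"], a["catch_dbl"])
        cb = vision.ConeCatches(b["catch_uv"], b["catch_sw"], b["catch_mw"], b["catch_lw"], b["catch_dbl"])
        out[i] = vision.chromatic_jnd(ca, cb, receptors)
    return out


def build_design(
    experiments: pd.DataFrame,
    phenotypes: pd.DataFrame,
    model: str = "distance",
    std: DistanceStandardization | None = None,
    composites=None,
    absolute: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the predictor matrix and outcome vector for a model family.

    ``experiments`` needs host_egg_id, experimental_egg_id and outcome
    columns; ``phenotypes`` is indexed by egg_id.  Trait differences use
    absolute values by default (rejection responds to mismatch magnitude);
    set ``absolute=False`` for signed differences.  Composite scores
    (pattern coverage, PC energy) are taken from ``composites`` when given,
    otherwise fitted on the phenotype table.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    ph = phenotypes.set_index("egg_id") if "egg_id" in phenotypes.columns else phenotypes
    y = experiments["outcome"].astype(int)
    y.index = experiments.index

    if model in ("traits", "interactions", "plus_colour"):
        from eggsig.pattern import fit_composites

        comp = composites if composites is not None else fit_composites(ph)
        scores = comp.score(ph)
        scores["n_features"] = ph["n_features"].astype(float)
        h = scores.loc[experiments["host_egg_id"]].to_numpy()
        e = scores.loc[experiments["experimental_egg_id"]].to_numpy()
        diffs = h - e
        if absolute:
            diffs = np.abs(diffs)
        X = pd.DataFrame(diffs, columns=list(TRAIT_DIFF_COLUMNS), index=experiments.index)
        if model == "interactions":
            for a, b in itertools.combinations(TRAIT_DIFF_COLUMNS, 2):
                X[f"{a}:{b}"] = X[a] * X[b]
        if model == "plus_colour":
            X["chromatic_jnd"] = _chromatic_jnd_column(experiments, ph)
        return X, y

    # distance model
    if std is None:
        std = DistanceStandardization.fit(ph)
    d = np.array(
        [
            pattern_distance(ph.loc[r["host_egg_id"]], ph.loc[r["experimental_egg_id"]], std)
            for _, r in experiments.iterrows()
        ]
    )
    X = pd.DataFrame({"pattern_distance": d}, index=experiments.index)
    return X, y


@dataclass
class RejectionModelFit:
    """Fitted binomial rejection GLM and its diagnostics."""

    predictor_names: list
    params: pd.Series  # includes the intercept ("const")
    bse: pd.Series
    llf: float
    aic: float
    adjusted_r2: float
    mcfadden_r2: float
    vifs: pd.Series | None
    n: int
    null_deviance: float
    deviance: float

    def predict(self, X: pd.DataFrame | np.ndarray | None = None) -> np.ndarray:
        """Predicted rejection probability for new predictor values."""
        if X is None or (hasattr(X, "shape") and np.asarray(X).size == 0):
            eta = np.full(1, self.params["const"])
        else:
            Xa = pd.DataFrame(X, columns=self.predictor_names)
            eta = self.params["const"] + Xa.to_numpy(dtype=float) @ self.params[
                self.predictor_names
            ].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_distance(self, d) -> np.ndarray:
        """Shortcut for single-predictor (distance) models."""
        if len(self.predictor_names) != 1:
            raise ValueError("predict_distance requires a single-predictor model")
        d = np.atleast_1d(np.asarray(d, dtype=float))
        return self.predict(pd.DataFrame({self.predictor_names[0]: d}))


def fit_rejection_glm(X: pd.DataFrame | None, y) -> RejectionModelFit:
    """Maximum-likelihood logit-link binomial GLM of rejection.

    ``X`` may be None or empty for the intercept-only (null) model.  Raises
    :class:`SeparationError` when the outcome is (quasi-)perfectly
    separated, in which case a penalized fit is the appropriate fallback.
    """
    y = pd.Series(y).astype(int)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    if X is None:
        X = pd.DataFrame(index=y.index)
    X = pd.DataFrame(X)
    names = list(X.columns)
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y.to_numpy(), design.to_numpy(), family=sm.families.Binomial())
    import warnings as _warnings

    with _warnings.catch_warnings():
        # separation is detected and raised explicitly below
        _warnings.simplefilter("ignore")
        res = model.fit(tol=1e-10, maxiter=200)
    params = pd.Series(res.params, index=design.columns)
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(params) > 50):
        raise SeparationError(
            "perfect separation detected (diverging coefficients); "
            "consider a penalized (e.g. Firth) fit"
        )
    null_fit = sm.GLM(y.to_numpy(), np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    null_dev = float(null_fit.deviance)
    k = design.shape[1]
    n = len(y)
    r2_dev = 1.0 - res.deviance / null_dev if null_dev > 0 else 0.0
    adj = 1.0 - (1.0 - r2_dev) * (n - 1) / (n - k) if n > k else float("nan")
    null_llf = null_fit.llf
    mcf = 1.0 - res.llf / null_llf if null_llf != 0 else 0.0
    vifs = vif(X) if len(names) >= 2 else None
    return RejectionModelFit(
        predictor_names=names,
        params=params,
        bse=pd.Series(res.bse, index=design.columns),
        llf=float(res.llf),
        aic=float(res.aic),
        adjusted_r2=float(adj),
        mcfadden_r2=float(mcf),
        vifs=vifs,
        n=n,
        null_deviance=null_dev,
        deviance=float(res.deviance),
    )


def compare_models(fit_a: RejectionModelFit, fit_b: RejectionModelFit) -> dict:
    """AIC difference and, for nested fits, the likelihood ratio test.

    Returns delta_aic = AIC_a - AIC_b.  The LRT is only computed when one
    predictor set is a subset of the other and both fits used the same
    observations; otherwise the LRT fields are None.
    """
    out: dict = {"delta_aic": fit_a.aic - fit_b.aic, "lrt": None, "df": None, "p": None}
    if fit_a.n != fit_b.n:
        return out
    sa, sb = set(fit_a.predictor_names), set(fit_b.predictor_names)
    if not (sa <= sb or sb <= sa):
        return out
    big, small = (fit_a, fit_b) if sb <= sa else (fit_b, fit_a)
    lrt = 2.0 * (big.llf - small.llf)
    df = len(big.predictor_names) - len(small.predictor_names)
    out["lrt"] = float(max(lrt, 0.0))
    out["df"] = df
    out["p"] = float(stats.chi2.sf(max(lrt, 0.0), df)) if df > 0 else 1.0
    return out


def _gof(X: pd.DataFrame, y: pd.Series, cols: tuple) -> float:
    design = sm.add_constant(
        X[list(cols)].astype(float) if cols else pd.DataFrame(index=X.index),
        has_constant="add",
    )
    res = sm.GLM(y.to_numpy(), design.to_numpy(), family=sm.families.Binomial()).fit()
    return float(res.deviance)


def partition_variance(X: pd.DataFrame, y) -> pd.Series:
    """Hierarchical partitioning of deviance explained between predictors.

    Fits all 2^k predictor subsets and averages, per predictor and per
    hierarchy level, the improvement in deviance explained from adding that
    predictor.  Independent contributions are normalized to percentages
    (%I) summing to 100.
    """
    X = pd.DataFrame(X)
    y = pd.Series(y).astype(int)
    cols = list(X.columns)
    k = len(cols)
    if k == 0:
        raise ValueError("no predictors to partition")
    if k > 8:
        raise ValueError("hierarchical partitioning limited to 8 predictors (2^k fits)")
    dev = {
        tuple(sorted(s)): _gof(X, y, s)
        for r in range(k + 1)
        for s in itertools.combinations(cols, r)
    }
    null_dev = dev[()]
    gof = {s: 1.0 - d / null_dev if null_dev > 0 else 0.0 for s, d in dev.items()}
    contributions = {}
    for c in cols:
        level_means = []
        for r in range(k):
            gains = [
                gof[tuple(sorted(s + (c,)))] - gof[tuple(sorted(s))]
                for s in itertools.combinations([o for o in cols if o != c], r)
            ]
            level_means.append(np.mean(gains))
        contributions[c] = float(np.mean(level_means))
    total = sum(contributions.values())
    if total <= 0:
        raise ValueError("total independent contribution is non-positive")
    return pd.Series({c: 100.0 * v / total for c, v in contributions.items()})


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R2_j).

    R2_j comes from the OLS regression of predictor j on all others (with
    intercept).  Exact collinearity yields an infinite VIF.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
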