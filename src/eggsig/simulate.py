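"""Monte-Carlo parasitism simulation and fecundity projection.

Given a fitted distance-based rejection model and phenotype tables for the
host and parasite populations, the simulator resamples host-parasite egg
pairings (with replacement, one egg per female), computes the
multidimensional pattern distance for each pairing, and predicts the fate
of the parasitic egg.  The monomorphic counterfactual collapses each
species to its centroid in the standardized pattern space, isolating the
contribution of between-female signature diversity to the population
rejection rate.  The fecundity projection converts a rejection rate into
expected eggs accepted, fledglings per season and lifetime fledglings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from eggsig.pattern import DISTANCE_TRAITS, DistanceStandardization, pattern_distance
from eggsig.rejection import RejectionModelFit

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FecundityParams",
    "simulate_parasitism",
    "simulate_experiment_set",
    "monomorphic_counterfactual",
    "fecundity_projection",
]


@dataclass
class SimulationConfig:
    """Monte-Carlo settings for the parasitism simulation."""

    n_iterations: int = 1000
    mode: str = "bernoulli"  # "bernoulli" draws outcomes; "expected" averages p
    seed: int = 0
    resample: bool = True  # with replacement
    one_egg_per_female: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mode not in ("bernoulli", "expected"):
            raise ValueError("mode must be 'bernoulli' or 'expected'")


@dataclass
class SimulationResult:
    """Predicted population rejection rate with uncertainty."""

    rejection_rate: float
    ci_low: float
    ci_high: float
    distances: np.ndarray
    probabilities: np.ndarray
    mode: str
    seed: int
    n_iterations: int
    config: SimulationConfig = field(repr=False, default=None)


def _one_egg_per_female(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    idx = [
        rng.choice(g.index.to_numpy())
        for _, g in table.groupby("female_id", sort=True)
    ]
    return table.loc[idx]


def _impute(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    im = (out["prop_pattern"] <= 0) & out["dispersion"].isna()
    out.loc[im, "dispersion"] = 1.0
    return out


def simulate_parasitism(
    hosts: pd.DataFrame,
    parasites: pd.DataFrame,
    fit: RejectionModelFit,
    cfg: SimulationConfig,
    std: DistanceStandardization | None = None,
) -> SimulationResult:
    """Resample host-parasite pairings and predict egg rejection.

    Each iteration draws (with replacement) one host egg and one parasite
    egg -- one egg per female when ``one_egg_per_female`` is set -- and
    predicts p(reject) from the fitted distance model.  In ``bernoulli``
    mode an outcome is drawn per iteration and the rate gets a
    Clopper-Pearson interval; in ``expected`` mode probabilities are
    averaged and the interval is a normal (delta-method) one on the mean.
    """
    if len(hosts) == 0 or len(parasites) == 0:
        raise ValueError("host and parasite tables must be non-empty")
    if len(fit.predictor_names) != 1:
        raise ValueError("simulation requires a single-predictor (distance) model")
    rng = np.random.default_rng(cfg.seed)
    if cfg.one_egg_per_female:
        hosts = _one_egg_per_female(hosts, rng)
        parasites = _one_egg_per_female(parasites, rng)
    hosts = _impute(hosts).reset_index(drop=True)
    parasites = _impute(parasites).reset_index(drop=True)
    if std is None:
        std = DistanceStandardization.fit(pd.concat([hosts, parasites], ignore_index=True))
    zh = np.vstack([std.transform(r[list(DISTANCE_TRAITS)]) for _, r in hosts.iterrows()])
    zp = np.vstack([std.transform(r[list(DISTANCE_TRAITS)]) for _, r in parasites.iterrows()])
    hi = rng.integers(len(hosts), size=cfg.n_iterations)
    pi = rng.integers(len(parasites), size=cfg.n_iterations)
    d = np.linalg.norm(zh[hi] - zp[pi], axis=1)
    p = fit.predict_distance(d)
    if cfg.mode == "bernoulli":
        outcomes = rng.uniform(size=cfg.n_iterations) < p
        k, n = int(outcomes.sum()), cfg.n_iterations
        rate = k / n
        lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi_ci = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    else:
        rate = float(p.mean())
        se = float(p.std(ddof=1) / np.sqrt(cfg.n_iterations))
        lo, hi_ci = max(rate - 1.96 * se, 0.0), min(rate + 1.96 * se, 1.0)
    return SimulationResult(
        rejection_rate=float(rate),
        ci_low=float(lo),
        ci_high=float(hi_ci),
        distances=d,
        probabilities=p,
        mode=cfg.mode,
        seed=cfg.seed,
        n_iterations=cfg.n_iterations,
        config=cfg,
    )


def simulate_experiment_set(
    pairs: pd.DataFrame,
    fit: RejectionModelFit,
    phenotypes: pd.DataFrame | None = None,
    std: DistanceStandardization | None = None,
    threshold: float = 0.5,
) -> dict:
    """Predict the fate of an actual set of host/foreign egg pairings.

    ``pairs`` either carries a precomputed ``distance`` column or
    host_egg_id/experimental_egg_id columns resolved against
    ``phenotypes``.  Returns the expected number of acceptances
    (sum of 1 - p_i) and the count of pairs predicted accepted under the
    probability ``threshold``.
    """
    if len(pairs) == 0:
        raise ValueError("no experimental pairs supplied")
    if "distance" in pairs.columns:
        d = pairs["distance"].to_numpy(dtype=float)
    else:
        if phenotypes is None:
            raise ValueError("phenotypes table required when pairs lack distances")
        ph = phenotypes.set_index("egg_id") if "egg_id" in phenotypes.columns else phenotypes
        if std is None:
            std = DistanceStandardization.fit(ph)
        d = np.array(
            [
                pattern_distance(ph.loc[r["host_egg_id"]], ph.loc[r["experimental_egg_id"]], std)
                for _, r in pairs.iterrows()
            ]
        )
    p = fit.predict_distance(d)
    return {
        "n": len(d),
        "expected_accepted": float(np.sum(1.0 - p)),
        "thresholded_accepted": int(np.sum(p < threshold)),
        "probabilities": p,
    }


def monomorphic_counterfactual(
    hosts: pd.DataFrame,
    parasites: pd.DataFrame,
    fit: RejectionModelFit,
    std: DistanceStandardization | None = None,
) -> tuple[float, float]:
    """Rejection probability if both species were monomorphic.

    Each species is collapsed to its centroid in the standardized 5-D
    pattern space; returns the centroid-to-centroid distance and the
    model-predicted rejection probability at that distance.  The
    standardization must match the one used when fitting the model.
    """
    if len(hosts) == 0 or len(parasites) == 0:
        raise ValueError("host and parasite tables must be non-empty")
    hosts = _impute(hosts)
    parasites = _impute(parasites)
    if std is None:
        std = DistanceStandardization.fit(pd.concat([hosts, parasites], ignore_index=True))
    zh = np.vstack([std.transform(r[list(DISTANCE_TRAITS)]) for _, r in hosts.iterrows()])
    zp = np.vstack([std.transform(r[list(DISTANCE_TRAITS)]) for _, r in parasites.iterrows()])
    d = float(np.linalg.norm(zh.mean(axis=0) - zp.mean(axis=0)))
    p = float(fit.predict_distance(d)[0])
    return d, p


@dataclass
class FecundityParams:
    """Inputs of the fecundity projection."""

    eggs_per_year: float = 20.0
    rejection_rate: float = 0.937
    nest_survival: float = 0.202
    lifespan_years: float = 8.0
    alt_success_rate: float = 0.27  # laying-to-fledging success of a comparator cuckoo

    def __post_init__(self) -> None:
        for name in ("rejection_rate", "nest_survival", "alt_success_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.eggs_per_year < 0 or self.lifespan_years < 0:
            raise ValueError("counts must be non-negative")


def fecundity_projection(params: FecundityParams) -> dict:
    """Annual and lifetime reproductive output implied by a rejection rate.

    accepted = eggs_per_year * (1 - rejection_rate);
    fledglings = accepted * nest_survival;
    lifetime = fledglings * lifespan;
    alt_fledglings = eggs_per_year * alt_success_rate (comparator species).

    Values are returned at full precision with 2-significant-figure display
    strings alongside.
    """
    accepted = params.eggs_per_year * (1.0 - params.rejection_rate)
    fledglings = accepted * params.nest_survival
    lifetime = fledglings * params.lifespan_years
    alt = params.eggs_per_year * params.alt_success_rate

    def _disp(x: float) -> str:
        return f"{x:.2g}"

    return {
        "accepted_eggs_per_year": accepted,
        "fledglings_per_year": fledglings,
        "lifetime_fledglings": lifetime,
        "alt_fledglings_per_year": alt,
        "display": {
            "accepted_eggs_per_year": _disp(accepted),
            "fledglings_per_year": _disp(fledglings),
            "lifetime_fledglings": _disp(lifetime),
            "alt_fledglings_per_year": _disp(alt),
        },
    }
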